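"""Core data types for photothermal response-surface analysis.

The experiment these types describe is a split-plot greenhouse study:
whole plots are greenhouse compartments held at a mean daily temperature
(MDT, °C), subplots are shade treatments producing distinct daily light
integrals (DLI, mol·m⁻²·d⁻¹), and the atoms of every analysis are
per-plant trait measurements taken in one (MDT, DLI) treatment cell.

Every fitted model is a quadratic response surface

    f(MDT, DLI) = y0 + a·MDT + b·DLI + c·MDT² + d·DLI² + e·MDT·DLI

in which any subset of the six terms may be structurally absent
(reduced and univariate models are the same object with a smaller
``term_mask``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import DomainError

#: Canonical order of the six surface terms.
TERM_NAMES: tuple[str, ...] = ("y0", "a", "b", "c", "d", "e")

#: Mask with every term present.
FULL_MASK: frozenset[str] = frozenset(TERM_NAMES)

#: Species handled by the reference coefficient table.
SPECIES: tuple[str, ...] = ("purple_basil", "sage", "spearmint", "sweet_basil")

#: Trait names that denote masses or counts (simulated draws are
#: truncated at zero; counts additionally rounded to integers).
COUNT_TRAITS: frozenset[str] = frozenset({"branch_no", "node_no"})
NONNEGATIVE_TRAITS: frozenset[str] = frozenset({
    "branch_no", "node_no", "height_cm", "leaf_area_cm2", "fresh_mass_g",
    "dry_mass_g", "leaf_fresh_mass_g", "stem_fresh_mass_g",
    "dmc_g_per_kg", "chroma",
})
UNIT_INTERVAL_TRAITS: frozenset[str] = frozenset({"fvfm", "leaf_mass_fraction"})


@dataclass(frozen=True)
class TreatmentEnvironment:
    """One realized treatment cell: its MDT, DLI and replication label."""

    mdt: float
    dli: float
    replication: int = 1
    shade_level: Optional[float] = None  # fraction of light removed, e.g. 0.3

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mdt) and self.mdt > 0):
            raise DomainError(f"mdt must be finite and > 0, got {self.mdt}")
        if not (math.isfinite(self.dli) and self.dli > 0):
            raise DomainError(f"dli must be finite and > 0, got {self.dli}")


@dataclass(frozen=True)
class PlantObservation:
    """A single plant's trait measurements in one treatment cell.

    ``traits`` maps trait name to value; absent traits are simply not
    present (color was not necessarily measured on every plant).
    """

    plant_id: str
    species: str
    environment: TreatmentEnvironment
    traits: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DomainError(
                f"unknown species {self.species!r}; expected one of {SPECIES}")
        for name, value in self.traits.items():
            if not math.isfinite(value):
                raise DomainError(f"trait {name!r} is not finite: {value}")
            if name in NONNEGATIVE_TRAITS and value < 0:
                raise DomainError(f"trait {name!r} must be >= 0, got {value}")
            if name in UNIT_INTERVAL_TRAITS and not (0.0 <= value <= 1.0):
                raise DomainError(
                    f"trait {name!r} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SurfaceCoefficients:
    """The sextet (y0, a, b, c, d, e) parameterizing f(MDT, DLI).

    ``term_mask`` records which terms are structurally present;
    structurally-absent terms must be exactly zero, so evaluation is
    always defined for the full polynomial.
    """

    y0: float = 0.0
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0
    term_mask: frozenset[str] = FULL_MASK

    def __post_init__(self) -> None:
        unknown = set(self.term_mask) - set(TERM_NAMES)
        if unknown:
            raise DomainError(f"unknown terms in mask: {sorted(unknown)}")
        for name in TERM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"coefficient {name} is not finite: {v}")
            if name not in self.term_mask and v != 0.0:
                raise DomainError(
                    f"structurally-absent term {name!r} must be 0, got {v}")

    @classmethod
    def from_terms(cls, **terms: float) -> "SurfaceCoefficients":
        """Build coefficients whose mask is exactly the keywords given."""
        unknown = set(terms) - set(TERM_NAMES)
        if unknown:
            raise DomainError(f"unknown terms: {sorted(unknown)}")
        return cls(term_mask=frozenset(terms), **terms)

    def __getitem__(self, name: str) -> float:
        if name not in TERM_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self, present_only: bool = False) -> dict[str, float]:
        names = [t for t in TERM_NAMES if not present_only or t in self.term_mask]
        return {t: getattr(self, t) for t in names}


@dataclass(frozen=True)
class CoefficientTableRow:
    """One species × trait row of a coefficient table: the surface, the
    per-term standard errors of the retained terms, and R²."""

    species: str
    trait: str
    coefficients: SurfaceCoefficients
    standard_errors: Mapping[str, float]
    r_squared: float

    def __post_init__(self) -> None:
        extra = set(self.standard_errors) - set(self.coefficients.term_mask)
        if extra:
            raise DomainError(
                "standard errors given for structurally-zero terms: "
                f"{sorted(extra)}")
        if not (0.0 <= self.r_squared <= 1.0):
            raise DomainError(f"r_squared must be in [0, 1], got {self.r_squared}")


@dataclass(frozen=True)
class FitResult:
    """A fitted surface: coefficients, their standard errors and p-values,
    R² = 1 − SSE/SST, and residual standard deviation."""

    coefficients: SurfaceCoefficients
    standard_errors: Mapping[str, float]
    p_values: Mapping[str, float]
    r_squared: float
    n_obs: int
    residual_sd: float
    pooled: Optional[bool] = None

    def to_table_row(self, species: str, trait: str) -> CoefficientTableRow:
        return CoefficientTableRow(
            species=species, trait=trait, coefficients=self.coefficients,
            standard_errors=dict(self.standard_errors),
            r_squared=max(0.0, min(1.0, self.r_squared)))


@dataclass(frozen=True)
class ExperimentalRange:
    """Observed MDT and DLI ranges; optima outside them are extrapolations."""

    mdt_min: float
    mdt_max: float
    dli_min: float
    dli_max: float

    def __post_init__(self) -> None:
        if not self.mdt_min < self.mdt_max:
            raise DomainError("mdt_min must be < mdt_max")
        if not self.dli_min < self.dli_max:
            raise DomainError("dli_min must be < dli_max")


@dataclass(frozen=True)
class PoolingDecision:
    """Outcome of the replication × treatment-cell interaction F-test."""

    poolable: bool
    p_value: Optional[float]
    f_statistic: Optional[float]
    applicable: bool = True


@dataclass(frozen=True)
class OptimumCurve:
    """An optimum-environment curve MDT_opt(DLI) or DLI_opt(MDT).

    ``predictor`` holds the evaluation points of the *other* factor,
    ``values`` the corresponding optimum, and ``extrapolated`` flags the
    points whose optimum exits the experimental range.
    """

    kind: str  # "mdt_opt_of_dli" | "dli_opt_of_mdt"
    coefficients: SurfaceCoefficients
    predictor: tuple[float, ...]
    values: tuple[float, ...]
    is_maximum: bool
    extrapolated: tuple[bool, ...]
    stationary_kind: str = "none"
    experimental_range: Optional[ExperimentalRange] = None

    def __post_init__(self) -> None:
        if self.kind not in ("mdt_opt_of_dli", "dli_opt_of_mdt"):
            raise DomainError(f"unknown curve kind {self.kind!r}")
        if not (len(self.predictor) == len(self.values) == len(self.extrapolated)):
            raise DomainError("predictor/values/extrapolated length mismatch")
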
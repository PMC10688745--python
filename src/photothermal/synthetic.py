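"""Synthetic split-plot study generator.

Emulates the structure of the greenhouse study behind the reference
surfaces: five temperature compartments (MDT set points 23–35 °C), each
with three shade-imposed DLI levels, repeated in two replications over
time, with ten plants per treatment cell — 5 × 3 × 2 × 10 = 300
observations per trait and species.

Environmental noise acts at the treatment-cell level (every plant in a
cell shares one realized MDT/DLI, mirroring temperature being a
whole-plot factor); plant-level trait noise is Gaussian around the
quadratic surface mean, truncated at physical bounds (masses and counts
at 0, fractions to [0, 1]) and rounded for count traits.

Per-trait residual standard deviations are calibrated from each
reference model's published R²: sd_res = sd_signal · sqrt((1 − R²)/R²),
where sd_signal is the spread of surface means over the default design.
Simulated studies therefore reproduce the published signal-to-noise
ratio, not independently measured plant variances (which were never
published).

Randomness is hierarchical: a single study seed feeds one substream per
trait × replication, so adding a trait or replication never perturbs
the draws of the others.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .colorimetry import LabColor
from .datamodel import (
    COUNT_TRAITS,
    NONNEGATIVE_TRAITS,
    UNIT_INTERVAL_TRAITS,
    PlantObservation,
    SurfaceCoefficients,
    TreatmentEnvironment,
)
from .errors import DomainError, TruncationWarning
from .reference import COLOR_TRAITS, preferred_rows
from .surface import evaluate_surface

_MIN_DLI = 0.5  # floor for realized DLI; a negative light integral is unphysical


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a synthetic study.

    Defaults reproduce the reference study's conditions: MDT set points
    23–35 °C in 3 °C steps; DLI targets 14/10/7 mol·m⁻²·d⁻¹ for the
    0/30/50 % shade levels; two replications of ten plants per cell;
    cell-level environment noise sd of 0.8 °C and 2.0 mol·m⁻²·d⁻¹
    (the spread of realized versus set-point environments).
    """

    mdt_setpoints: tuple[float, ...] = (23.0, 26.0, 29.0, 32.0, 35.0)
    dli_targets: tuple[float, ...] = (14.0, 10.0, 7.0)
    n_replications: int = 2
    plants_per_cell: int = 10
    env_noise_sd: tuple[float, float] = (0.8, 2.0)  # (mdt_sd, dli_sd)

    def __post_init__(self) -> None:
        if len(self.mdt_setpoints) < 2 or len(self.dli_targets) < 2:
            raise DomainError("need >= 2 MDT levels and >= 2 DLI levels")
        if self.n_replications < 1 or self.plants_per_cell < 1:
            raise DomainError("n_replications and plants_per_cell must be >= 1")
        if any(sd < 0 for sd in self.env_noise_sd):
            raise DomainError("environment noise sd must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.mdt_setpoints) * len(self.dli_targets) * self.n_replications

    @property
    def n_observations(self) -> int:
        return self.n_cells * self.plants_per_cell


@dataclass(frozen=True)
class TraitTruth:
    """Generating surface and plant-level residual sd for one trait."""

    coefficients: SurfaceCoefficients
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise DomainError("residual sd must be >= 0")


@dataclass(frozen=True)
class GeneratorTruth:
    """Per-trait generating surfaces for one species."""

    species: str
    traits: Mapping[str, TraitTruth]


def _rng(seed: int, label: str, replication: int) -> np.random.Generator:
    """Deterministic substream keyed by (seed, label, replication)."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key, replication]))


def generate_design(spec: DesignSpec, seed: int) -> list[TreatmentEnvironment]:
    """Realize one environment per treatment cell per replication:
    set point + Normal(0, env_noise_sd). Deterministic under ``seed``;
    order is replication-major, then MDT, then DLI."""
    mdt_sd, dli_sd = spec.env_noise_sd
    shade_by_target = dict(zip(sorted(spec.dli_targets, reverse=True),
                               (0.0, 0.3, 0.5)))
    cells: list[TreatmentEnvironment] = []
    for rep in range(1, spec.n_replications + 1):
        rng = _rng(seed, "__design__", rep)
        for mdt0 in spec.mdt_setpoints:
            for dli0 in spec.dli_targets:
                mdt = mdt0 + rng.normal(0.0, mdt_sd) if mdt_sd else mdt0
                dli = dli0 + rng.normal(0.0, dli_sd) if dli_sd else dli0
                cells.append(TreatmentEnvironment(
                    mdt=mdt, dli=max(dli, _MIN_DLI), replication=rep,
                    shade_level=shade_by_target.get(dli0)))
    return cells


def _plant_id(cell_index: int, env: TreatmentEnvironment, plant: int) -> str:
    return f"r{env.replication}_c{cell_index:02d}_p{plant:02d}"


def _apply_bounds(trait: str, draws: np.ndarray) -> tuple[np.ndarray, int]:
    """Truncate/round draws to the trait's physical support."""
    clipped = draws
    n_trunc = 0
    if trait in NONNEGATIVE_TRAITS:
        n_trunc = int(np.sum(draws < 0))
        clipped = np.maximum(draws, 0.0)
    elif trait in UNIT_INTERVAL_TRAITS:
        n_trunc = int(np.sum((draws < 0) | (draws > 1)))
        clipped = np.clip(draws, 0.0, 1.0)
    if trait in COUNT_TRAITS:
        clipped = np.round(clipped)
    return clipped, n_trunc


def simulate_trait(environments: Sequence[TreatmentEnvironment],
                   truth: GeneratorTruth, trait: str,
                   plants_per_cell: int, seed: int) -> list[PlantObservation]:
    """Draw ``plants_per_cell`` plants per cell for one trait:
    surface mean at the cell's realized environment plus Gaussian noise,
    truncated/rounded to the trait's support."""
    if trait not in truth.traits:
        raise DomainError(
            f"trait {trait!r} not in truth (has {sorted(truth.traits)})")
    tt = truth.traits[trait]
    rngs: dict[int, np.random.Generator] = {}
    observations: list[PlantObservation] = []
    total_trunc = 0
    for idx, env in enumerate(environments):
        rng = rngs.setdefault(env.replication, _rng(seed, trait, env.replication))
        mean = evaluate_surface(tt.coefficients, env.mdt, env.dli)
        draws = mean + rng.normal(0.0, tt.residual_sd, size=plants_per_cell)
        draws, n_trunc = _apply_bounds(trait, draws)
        total_trunc += n_trunc
        for j, value in enumerate(draws):
            observations.append(PlantObservation(
                plant_id=_plant_id(idx, env, j), species=truth.species,
                environment=env, traits={trait: float(value)}))
    if total_trunc:
        warnings.warn(
            f"{total_trunc} draw(s) of {trait!r} truncated to the trait's "
            "physical support", TruncationWarning, stacklevel=2)
    return observations


def simulate_color(environments: Sequence[TreatmentEnvironment],
                   hue_truth: TraitTruth, chroma_truth: TraitTruth,
                   L_truth: TraitTruth, plants_per_cell: int,
                   seed: int) -> list[tuple[str, TreatmentEnvironment, LabColor]]:
    """Inverse-construct Lab triplets from hue/chroma/L* surfaces.

    Per plant, the transformed hue h (degrees) and chroma C are drawn
    from their surfaces plus noise, then a* = C·cos(h), b* = C·sin(h),
    so converting the emitted Lab back through the colorimetry module
    recovers the generating hue and chroma exactly in the noise-free
    case. Negative chroma draws are truncated at 0 with a warning;
    L* draws are clipped to [0, 100].
    """
    rngs: dict[int, dict[str, np.random.Generator]] = {}
    out: list[tuple[str, TreatmentEnvironment, LabColor]] = []
    n_trunc = 0
    for idx, env in enumerate(environments):
        streams = rngs.setdefault(env.replication, {
            name: _rng(seed, name, env.replication)
            for name in ("hue_transformed_deg", "chroma", "L_star")})
        h_mean = evaluate_surface(hue_truth.coefficients, env.mdt, env.dli)
        c_mean = evaluate_surface(chroma_truth.coefficients, env.mdt, env.dli)
        l_mean = evaluate_surface(L_truth.coefficients, env.mdt, env.dli)
        h = h_mean + streams["hue_transformed_deg"].normal(
            0.0, hue_truth.residual_sd, plants_per_cell)
        c = c_mean + streams["chroma"].normal(
            0.0, chroma_truth.residual_sd, plants_per_cell)
        L = l_mean + streams["L_star"].normal(
            0.0, L_truth.residual_sd, plants_per_cell)
        n_trunc += int(np.sum(c < 0))
        c = np.maximum(c, 0.0)
        L = np.clip(L, 0.0, 100.0)
        for j in range(plants_per_cell):
            rad = math.radians(h[j])
            out.append((
                _plant_id(idx, env, j), env,
                LabColor(L_star=float(L[j]),
                         a_star=float(c[j] * math.cos(rad)),
                         b_star=float(c[j] * math.sin(rad)))))
    if n_trunc:
        warnings.warn(f"{n_trunc} chroma draw(s) truncated at 0",
                      TruncationWarning, stacklevel=2)
    return out


def study_truth(species: str,
                spec: Optional[DesignSpec] = None) -> GeneratorTruth:
    """Build the default generating truth for a species from the
    packaged reference surfaces, with residual sd calibrated from each
    model's published R² over the design grid."""
    spec = spec or DesignSpec()
    grid_m, grid_l = np.meshgrid(spec.mdt_setpoints, spec.dli_targets)
    traits: dict[str, TraitTruth] = {}
    for trait, row in preferred_rows(species).items():
        signal = evaluate_surface(row.coefficients, grid_m.ravel(), grid_l.ravel())
        sd_signal = float(np.std(signal))
        r2 = min(max(row.r_squared, 1e-3), 1.0 - 1e-9)
        residual_sd = sd_signal * math.sqrt((1.0 - r2) / r2)
        traits[trait] = TraitTruth(row.coefficients, residual_sd)
    return GeneratorTruth(species=species, traits=traits)


def simulate_study(species: str, spec: Optional[DesignSpec] = None,
                   seed: int = 0,
                   truth: Optional[GeneratorTruth] = None
                   ) -> list[PlantObservation]:
    """Generate a complete study for one species: realized design,
    every growth trait in the truth, and (when the truth carries color
    surfaces) per-plant Lab triplets stored as L*/a*/b* traits."""
    spec = spec or DesignSpec()
    truth = truth or study_truth(species, spec)
    environments = generate_design(spec, seed)

    merged: dict[str, dict[str, float]] = {}
    envs_by_plant: dict[str, TreatmentEnvironment] = {}
    growth_traits = [t for t in truth.traits if t not in COLOR_TRAITS]
    for trait in growth_traits:
        for obs in simulate_trait(environments, truth, trait,
                                  spec.plants_per_cell, seed):
            merged.setdefault(obs.plant_id, {}).update(obs.traits)
            envs_by_plant[obs.plant_id] = obs.environment

    if all(t in truth.traits for t in COLOR_TRAITS):
        colors = simulate_color(
            environments, truth.traits["hue_transformed_deg"],
            truth.traits["chroma"], truth.traits["L_star"],
            spec.plants_per_cell, seed)
        for pid, env, lab in colors:
            merged.setdefault(pid, {}).update(
                L_star=lab.L_star, a_star=lab.a_star, b_star=lab.b_star)
            envs_by_plant[pid] = env

    return [PlantObservation(plant_id=pid, species=species,
                             environment=envs_by_plant[pid], traits=traits)
            for pid, traits in merged.items()]
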
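"""Pipeline orchestration: config, stages, and report outputs.

``run_pipeline`` ties the stages together for each selected species and
trait: observations (loaded from CSV or simulated) → color metric
derivation → replication-pooling decision → term selection → surface
fit → optimum curves → prediction grids. Outputs are plain CSVs (a
coefficient table in the published layout, one optimum-curve CSV and
one prediction-grid CSV per eligible trait) plus a JSON run log
recording the seed, library versions, and every pooling/selection
decision and warning — enough to reproduce a run exactly.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colorimetry import DEFAULT_HUE_THRESHOLD, annotate_color_metrics
from .datamodel import (
    SPECIES,
    CoefficientTableRow,
    ExperimentalRange,
    SurfaceCoefficients,
)
from .errors import ConfigError, PipelineStageError
from .io import observations_to_frame, read_observations, write_coefficient_table
from .optima import optimum_curve
from .reference import COLOR_TRAITS, EXPERIMENTAL_RANGES
from .surface import evaluate_surface, fit_surface, replications_poolable, select_terms
from .synthetic import DesignSpec, simulate_study, study_truth

logger = logging.getLogger(__name__)


def make_prediction_grid(coeffs: SurfaceCoefficients,
                         mdt_range: tuple[float, float],
                         dli_range: tuple[float, float],
                         n_mdt: int, n_dli: int) -> pd.DataFrame:
    """Regular n_mdt × n_dli grid of surface predictions, suitable for
    surface plotting."""
    if n_mdt < 2 or n_dli < 2:
        raise ConfigError("n_mdt and n_dli must be >= 2")
    if mdt_range[0] >= mdt_range[1] or dli_range[0] >= dli_range[1]:
        raise ConfigError("ranges must satisfy lo < hi")
    mdt = np.linspace(*mdt_range, n_mdt)
    dli = np.linspace(*dli_range, n_dli)
    mm, ll = np.meshgrid(mdt, dli, indexing="ij")
    return pd.DataFrame({
        "mdt": mm.ravel(), "dli": ll.ravel(),
        "predicted": evaluate_surface(coeffs, mm.ravel(), ll.ravel()),
    })


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    output_dir: Path
    species: Sequence[str] = field(default_factory=lambda: list(SPECIES))
    traits: Optional[Sequence[str]] = None  # None = every trait in the truth
    input_path: Optional[Path] = None       # None = simulate
    terms: object = "auto"  # "auto" | "full" | explicit term list
    alpha: float = 0.05
    hue_threshold: float = DEFAULT_HUE_THRESHOLD
    seed: int = 0
    n_grid: int = 25
    n_curve_points: int = 50
    design: DesignSpec = field(default_factory=DesignSpec)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        unknown = set(self.species) - set(SPECIES)
        if unknown:
            raise ConfigError(f"unknown species: {sorted(unknown)}")
        if isinstance(self.terms, str):
            if self.terms not in ("auto", "full"):
                raise ConfigError(
                    f"terms must be 'auto', 'full' or a term list, got {self.terms!r}")
        else:
            from .datamodel import TERM_NAMES
            bad = set(self.terms) - set(TERM_NAMES)
            if bad:
                raise ConfigError(f"unknown term(s): {sorted(bad)}")
            self.terms = frozenset(self.terms)
        if self.input_path is not None:
            self.input_path = Path(self.input_path)
            if not self.input_path.exists():
                raise ConfigError(f"input path not found: {self.input_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "output_dir" not in raw:
            raise ConfigError("config must be a mapping with an output_dir")
        design = DesignSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("design", {}).items()})
        known = {"output_dir", "species", "traits", "input_path", "terms",
                 "alpha", "hue_threshold", "seed", "n_grid", "n_curve_points"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(design=design, **raw)


def _observation_frame(config: PipelineConfig, species: str) -> pd.DataFrame:
    if config.input_path is not None:
        observations = [o for o in read_observations(config.input_path)
                        if o.species == species]
    else:
        observations = simulate_study(species, config.design, config.seed)
    frame = observations_to_frame(observations)
    if {"a_star", "b_star"} <= set(frame.columns):
        frame = annotate_color_metrics(frame, threshold=config.hue_threshold)
    return frame


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written to
    ``run_log.json``). On stage failure, partial outputs are removed
    and :class:`PipelineStageError` is raised."""
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "hue_threshold": config.hue_threshold,
        "versions": {
            "photothermal": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "design": {
            "mdt_setpoints": list(config.design.mdt_setpoints),
            "dli_targets": list(config.design.dli_targets),
            "n_replications": config.design.n_replications,
            "plants_per_cell": config.design.plants_per_cell,
            "env_noise_sd": list(config.design.env_noise_sd),
        },
        "species": {},
        "warnings": [],
    }

    stage = "setup"
    current: tuple[Optional[str], Optional[str]] = (None, None)
    try:
        coefficient_rows: list[CoefficientTableRow] = []
        for species in config.species:
            stage = "observations"
            current = (species, None)
            t0 = time.perf_counter()
            frame = _observation_frame(config, species)
            truth_traits = list(study_truth(species, config.design).traits)
            traits = [t for t in (config.traits or truth_traits)
                      if t in frame.columns]
            sp_report: dict = {"n_observations": int(len(frame)), "traits": {}}
            exp_range = _frame_range(frame, species)

            for trait in traits:
                current = (species, trait)
                sub = frame.dropna(subset=[trait])
                mdt = sub["mdt"].to_numpy()
                dli = sub["dli"].to_numpy()
                y = sub[trait].to_numpy(dtype=float)

                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    stage = "pooling"
                    cells = (sub["mdt"].round(6).astype(str) + "|"
                             + sub["dli"].round(6).astype(str))
                    pooling = replications_poolable(
                        cells.to_numpy(), sub["replication"].to_numpy(), y,
                        alpha=config.alpha)

                    stage = "term_selection"
                    if config.terms == "auto":
                        mask = select_terms(mdt, dli, y, alpha=config.alpha)
                    elif config.terms == "full":
                        from .datamodel import FULL_MASK
                        mask = FULL_MASK
                    else:  # explicit model form, as a published analysis may pin
                        mask = frozenset(config.terms)

                    stage = "fit"
                    fit = fit_surface(mdt, dli, y, mask)

                report["warnings"].extend(
                    {"species": species, "trait": trait,
                     "message": str(w.message)} for w in caught)
                coefficient_rows.append(fit.to_table_row(species, trait))

                trait_report = {
                    "n": fit.n_obs,
                    "pooled": pooling.poolable,
                    "pooling_p_value": pooling.p_value,
                    "selected_terms": sorted(mask),
                    "r_squared": fit.r_squared,
                    "residual_sd": fit.residual_sd,
                }

                stage = "optima"
                for kind, quad in (("mdt_opt_of_dli", "c"), ("dli_opt_of_mdt", "d")):
                    coeffs = fit.coefficients
                    if quad not in coeffs.term_mask or coeffs[quad] == 0.0:
                        continue
                    curve = optimum_curve(coeffs, kind, exp_range,
                                          config.n_curve_points)
                    path = outdir / f"{species}_{trait}_{kind}.csv"
                    written.append(path)
                    pd.DataFrame({
                        "predictor": curve.predictor,
                        "optimum": curve.values,
                        "extrapolated": curve.extrapolated,
                    }).to_csv(path, index=False)
                    trait_report[kind] = {
                        "is_maximum": curve.is_maximum,
                        "stationary_kind": curve.stationary_kind,
                        "any_extrapolated": any(curve.extrapolated),
                    }

                stage = "prediction_grid"
                grid = make_prediction_grid(
                    fit.coefficients,
                    (exp_range.mdt_min, exp_range.mdt_max),
                    (exp_range.dli_min, exp_range.dli_max),
                    config.n_grid, config.n_grid)
                path = outdir / f"{species}_{trait}_grid.csv"
                written.append(path)
                grid.to_csv(path, index=False)

                sp_report["traits"][trait] = trait_report
                logger.info("%s/%s fitted in %.2fs", species, trait,
                            time.perf_counter() - t0)

            report["species"][species] = sp_report

        stage = "report"
        current = (None, None)
        coef_path = outdir / "coefficients.csv"
        written.append(coef_path)  # register first so cleanup sees partial writes
        write_coefficient_table(coefficient_rows, coef_path)
        log_path = outdir / "run_log.json"
        written.append(log_path)
        log_path.write_text(json.dumps(report, indent=2, default=str))
    except Exception as exc:  # remove partial outputs, then re-raise
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineStageError(stage, current[0], current[1], exc) from exc
    return report


def _frame_range(frame: pd.DataFrame, species: str) -> ExperimentalRange:
    """Observed range of the data, falling back to the species' published
    range when the frame is degenerate on an axis."""
    try:
        return ExperimentalRange(
            float(frame["mdt"].min()), float(frame["mdt"].max()),
            float(frame["dli"].min()), float(frame["dli"].max()))
    except Exception:
        return EXPERIMENTAL_RANGES[species]
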
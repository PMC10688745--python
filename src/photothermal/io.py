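"""CSV I/O for observation tables and coefficient tables.

Observation tables are long/tidy: one row per plant, mandatory columns
``plant_id, species, replication, mdt, dli`` (plus optional
``shade_level``), and one column per trait. Empty trait cells mean the
trait was not measured on that plant.

Coefficient tables mirror the published layout: one row per
species × trait with columns ``y0, a, b, c, d, e``, per-term standard
errors ``se_*`` and ``r_squared``. Structurally-zero terms are written
as empty cells (blank = term absent), and E-notation (e.g. ``-2.80E1``)
is accepted on input.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .datamodel import (
    TERM_NAMES,
    CoefficientTableRow,
    PlantObservation,
    SurfaceCoefficients,
    TreatmentEnvironment,
)
from .errors import SchemaError, TableParseError

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("plant_id", "species", "replication", "mdt", "dli")
_META_COLUMNS = set(MANDATORY_COLUMNS) | {"shade_level"}


def read_observations(path: str | Path,
                      schema: Optional[Sequence[str]] = None
                      ) -> list[PlantObservation]:
    """Read a tidy observation CSV into a list of :class:`PlantObservation`.

    ``schema`` optionally names the expected trait columns; any other
    non-mandatory column is then ignored with a logged warning. Without
    a schema, every extra column that parses as numeric is treated as a
    trait; entirely non-numeric columns are ignored with a warning, and
    a stray non-numeric cell in an otherwise numeric column raises
    :class:`TableParseError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    extra = [c for c in frame.columns if c not in _META_COLUMNS]
    if schema is not None:
        unknown = [c for c in extra if c not in schema]
        for col in unknown:
            logger.warning("ignoring unexpected column %r", col)
        trait_cols = [c for c in extra if c in schema]
        absent = [c for c in schema if c not in frame.columns]
        if absent:
            raise SchemaError(
                f"schema trait column(s) missing: {', '.join(absent)}")
    else:
        trait_cols = []
        for col in extra:
            numeric = pd.to_numeric(frame[col], errors="coerce")
            bad = numeric.isna() & frame[col].notna()
            if bad.all() and frame[col].notna().any():
                logger.warning("ignoring non-numeric column %r", col)
            else:
                trait_cols.append(col)

    def _num(col: str, row_label: int, raw: str) -> float:
        try:
            return float(raw)
        except ValueError:
            raise TableParseError(
                f"non-numeric value {raw!r} in column {col!r}, "
                f"data row {row_label}") from None

    observations: list[PlantObservation] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(frame.columns, row))
        env = TreatmentEnvironment(
            mdt=_num("mdt", i, record["mdt"]),
            dli=_num("dli", i, record["dli"]),
            replication=int(_num("replication", i, record["replication"])),
            shade_level=(
                _num("shade_level", i, record["shade_level"])
                if record.get("shade_level") is not None
                and pd.notna(record.get("shade_level")) else None),
        )
        traits = {}
        for col in trait_cols:
            raw = record[col]
            if raw is None or pd.isna(raw):
                continue
            traits[col] = _num(col, i, raw)
        observations.append(PlantObservation(
            plant_id=str(record["plant_id"]),
            species=str(record["species"]),
            environment=env, traits=traits))
    return observations


def observations_to_frame(observations: Iterable[PlantObservation]) -> pd.DataFrame:
    """Flatten observations into the tidy table layout (one trait per column)."""
    observations = list(observations)
    trait_cols: list[str] = []
    for obs in observations:
        for t in obs.traits:
            if t not in trait_cols:
                trait_cols.append(t)
    rows = []
    for obs in observations:
        row: dict[str, object] = {
            "plant_id": obs.plant_id,
            "species": obs.species,
            "replication": obs.environment.replication,
            "mdt": obs.environment.mdt,
            "dli": obs.environment.dli,
        }
        if obs.environment.shade_level is not None:
            row["shade_level"] = obs.environment.shade_level
        for t in trait_cols:
            row[t] = obs.traits.get(t)
        rows.append(row)
    return pd.DataFrame(rows)


def write_observations(observations: Iterable[PlantObservation],
                       path: str | Path) -> None:
    """Write observations as a tidy CSV (inverse of :func:`read_observations`)."""
    frame = observations_to_frame(observations)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Coefficient tables

_COEF_COLUMNS = (
    ["species", "trait"] + list(TERM_NAMES)
    + [f"se_{t}" for t in TERM_NAMES] + ["r_squared"]
)


def write_coefficient_table(rows: Sequence[CoefficientTableRow],
                            path: str | Path) -> None:
    """Write coefficient rows as CSV; structurally-zero terms become
    empty cells (blank = 0 convention)."""
    if not rows:
        raise ValueError("coefficient table must contain at least one row")
    records = []
    for row in rows:
        rec: dict[str, object] = {"species": row.species, "trait": row.trait}
        for t in TERM_NAMES:
            present = t in row.coefficients.term_mask
            rec[t] = getattr(row.coefficients, t) if present else None
            rec[f"se_{t}"] = row.standard_errors.get(t) if present else None
        rec["r_squared"] = row.r_squared
        records.append(rec)
    pd.DataFrame(records, columns=_COEF_COLUMNS).to_csv(path, index=False)


def read_coefficient_table(path: str | Path) -> list[CoefficientTableRow]:
    """Read a coefficient CSV; blank coefficient cells are structural zeros."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    for col in ("species", "trait"):
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    rows: list[CoefficientTableRow] = []
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        terms: dict[str, float] = {}
        ses: dict[str, float] = {}
        for t in TERM_NAMES:
            raw = rec.get(t)
            if raw is None or pd.isna(raw):
                continue
            try:
                terms[t] = float(raw)
            except (TypeError, ValueError):
                raise TableParseError(
                    f"non-numeric coefficient {raw!r} for term {t!r}, "
                    f"data row {i}") from None
            se_raw = rec.get(f"se_{t}")
            if se_raw is not None and pd.notna(se_raw):
                ses[t] = float(se_raw)
        r2_raw = rec.get("r_squared")
        r2 = float(r2_raw) if r2_raw is not None and pd.notna(r2_raw) else 0.0
        rows.append(CoefficientTableRow(
            species=str(rec["species"]), trait=str(rec["trait"]),
            coefficients=SurfaceCoefficients.from_terms(**terms),
            standard_errors=ses, r_squared=r2))
    return rows
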
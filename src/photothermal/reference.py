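"""Published reference surfaces and experimental ranges.

The package ships a coefficient table (``data/reference_surfaces.csv``)
holding the published quadratic response-surface models for purple basil
'Dark Opal', sage 'Extrakta', spearmint 'Spanish' and sweet basil
'Nufar': branch and node number, height, F_v/F_m, leaf area, dry matter
concentration, leaf mass fraction, fresh mass, and (purple basil only)
the CIELAB color metrics. Some species × trait combinations carry more
than one published model (e.g. separate MDT-only and DLI-only reduced
fits); :func:`preferred_rows` selects one model per trait for use as
simulation truth.

``EXPERIMENTAL_RANGES`` records the realized MDT/DLI ranges of the
underlying greenhouse study per species; optima computed outside these
ranges are extrapolations and are flagged as such downstream.
"""

from __future__ import annotations

from importlib.resources import files

from .datamodel import CoefficientTableRow, ExperimentalRange
from . import io

#: Realized environment ranges per species (°C, mol·m⁻²·d⁻¹).
EXPERIMENTAL_RANGES: dict[str, ExperimentalRange] = {
    "purple_basil": ExperimentalRange(22.9, 35.0, 5.0, 18.7),
    "sage": ExperimentalRange(22.8, 35.1, 4.9, 18.3),
    "spearmint": ExperimentalRange(23.0, 35.1, 5.0, 19.4),
    "sweet_basil": ExperimentalRange(23.0, 35.7, 5.5, 13.2),
}

#: Color traits only measured/modeled for purple basil.
COLOR_TRAITS = ("hue_transformed_deg", "chroma", "L_star")

#: Alternative univariate color-axis models, not used as generator truth
#: (the Lab triplet is generated from hue/chroma/L* instead).
_EXCLUDED_TRUTH_TRAITS = ("a_star", "b_star")


def load_reference_surfaces() -> list[CoefficientTableRow]:
    """Load every published coefficient row (including alternative
    reduced models for the same trait)."""
    path = files("photothermal").joinpath("data/reference_surfaces.csv")
    return io.read_coefficient_table(str(path))


def rows_for(species: str,
             rows: list[CoefficientTableRow] | None = None
             ) -> list[CoefficientTableRow]:
    rows = load_reference_surfaces() if rows is None else rows
    return [r for r in rows if r.species == species]


def preferred_rows(species: str) -> dict[str, CoefficientTableRow]:
    """One model per trait: the row with the most retained terms,
    ties broken by higher R².

    This reproduces the models the study's narrative leans on — e.g.
    purple basil fresh mass as the MDT quadratic (which yields the
    extrapolated optimum) and its DMC as the DLI quadratic.
    """
    best: dict[str, CoefficientTableRow] = {}
    for row in rows_for(species):
        if row.trait in _EXCLUDED_TRUTH_TRAITS:
            continue
        cur = best.get(row.trait)
        if cur is None:
            best[row.trait] = row
            continue
        key = (len(row.coefficients.term_mask), row.r_squared)
        cur_key = (len(cur.coefficients.term_mask), cur.r_squared)
        if key > cur_key:
            best[row.trait] = row
    return best
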
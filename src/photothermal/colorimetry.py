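"""CIELAB colorimetry: hue angle, chroma, and the circular-scale transform.

Foliage color is recorded as CIELAB (L*, a*, b*) triplets: L* is
lightness in [0, 100]; a* runs red (+) to green (−); b* yellow (+) to
blue (−). Because a* and b* are not interpretable independently they are
converted to polar form:

* hue angle h° — the angle on the a*b* color wheel (0°/360° red,
  90° yellow, 120° green, 270° blue), computed by quadrant-aware
  piecewise arctangent;
* chroma C* = sqrt(a*² + b*²) — colorfulness, the hypotenuse of the
  a*b* plot.

Purple foliage sits astride the 0°/360° cut (observed hues fall in
[0°, 127°] ∪ [300°, 360°)), so for modeling the scale is circularized:
hues above a threshold (default 300°) have 360° subtracted, placing the
purple→green arc on the continuous interval (−60°, 127°].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedHueError

DEFAULT_HUE_THRESHOLD = 300.0


@dataclass(frozen=True)
class LabColor:
    """A CIELAB triplet."""

    L_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        for v in (self.L_star, self.a_star, self.b_star):
            if not math.isfinite(v):
                raise DomainError(f"Lab components must be finite, got {v}")
        if not (0.0 <= self.L_star <= 100.0):
            raise DomainError(f"L* must be in [0, 100], got {self.L_star}")


@dataclass(frozen=True)
class HueChroma:
    """Derived polar color metrics; ``undefined`` marks achromatic gray."""

    hue_deg: float
    hue_transformed_deg: float
    chroma: float
    undefined: bool = False


def hue_angle(a_star: float, b_star: float) -> float:
    """Quadrant-aware hue angle in degrees, in [0, 360).

    Piecewise by quadrant of (a*, b*): first quadrant uses arctan(b*/a*)
    directly, the fourth adds 360°, and both left half-plane quadrants
    add 180°. On the a* = 0 axis the continuous limit is used (90° for
    b* > 0, 270° for b* < 0). Undefined at the achromatic point (0, 0).
    """
    if not (math.isfinite(a_star) and math.isfinite(b_star)):
        raise DomainError("a* and b* must be finite")
    if a_star == 0.0 and b_star == 0.0:
        raise UndefinedHueError("hue is undefined at a* = b* = 0 (chroma 0)")
    if a_star == 0.0:
        return 90.0 if b_star > 0 else 270.0
    base = math.degrees(math.atan(b_star / a_star))
    if a_star > 0 and b_star >= 0:
        h = base
    elif a_star > 0:  # b* < 0
        h = 360.0 + base
    else:  # a* < 0, either sign of b*
        h = 180.0 + base
    return h % 360.0


def chroma(a_star: float, b_star: float) -> float:
    """Chroma C* = sqrt(a*² + b*²), the radial distance from gray."""
    if not (math.isfinite(a_star) and math.isfinite(b_star)):
        raise DomainError("a* and b* must be finite")
    return math.hypot(a_star, b_star)


def circularize_hue(hue_deg: float, threshold: float = DEFAULT_HUE_THRESHOLD) -> float:
    """Map hue onto the continuous modeling scale: subtract 360° above
    ``threshold``, leave sub-threshold values unchanged.

    E.g. with the default threshold, 333° → −27° while 98° passes
    through, so the purple→green arc is monotone on one interval.
    """
    if not (0.0 <= hue_deg < 360.0):
        raise DomainError(f"hue must lie in [0, 360), got {hue_deg}")
    return hue_deg - 360.0 if hue_deg > threshold else hue_deg


def uncircularize_hue(hue_transformed_deg: float) -> float:
    """Inverse of :func:`circularize_hue` for reporting: back to [0, 360)."""
    return hue_transformed_deg % 360.0


def lab_to_metrics(color: LabColor,
                   threshold: float = DEFAULT_HUE_THRESHOLD) -> HueChroma:
    """Convert one Lab triplet to (h°, transformed h°, C*).

    At the achromatic point the chroma is 0 and the hue is flagged
    ``undefined`` (hue fields are NaN) instead of raising, so batch
    conversion never aborts on a gray pixel.
    """
    c = chroma(color.a_star, color.b_star)
    if c == 0.0:
        return HueChroma(math.nan, math.nan, 0.0, undefined=True)
    h = hue_angle(color.a_star, color.b_star)
    return HueChroma(h, circularize_hue(h, threshold), c)


def annotate_color_metrics(frame: pd.DataFrame,
                           threshold: float = DEFAULT_HUE_THRESHOLD,
                           l_col: str = "L_star", a_col: str = "a_star",
                           b_col: str = "b_star") -> pd.DataFrame:
    """Return ``frame`` with hue_deg, hue_transformed_deg and chroma columns
    appended, computed row-wise from the a*/b* columns.

    Rows with a* = b* = 0 get chroma 0 and NaN hues.
    """
    for col in (a_col, b_col):
        if col not in frame.columns:
            raise DomainError(f"missing column {col!r}")
    a = frame[a_col].to_numpy(dtype=float)
    b = frame[b_col].to_numpy(dtype=float)
    defined = (a != 0.0) | (b != 0.0)
    hue = np.full(len(frame), np.nan)
    hue[defined] = [hue_angle(ai, bi) for ai, bi in zip(a[defined], b[defined])]
    transformed = np.where(hue > threshold, hue - 360.0, hue)
    out = frame.copy()
    out["hue_deg"] = hue
    out["hue_transformed_deg"] = transformed
    out["chroma"] = np.hypot(a, b)
    return out
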
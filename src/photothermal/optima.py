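"""Analytic optimum-environment curves from a fitted surface.

Setting the partial derivatives of the quadratic surface to zero gives
the environment maximizing (or minimizing) a trait as a function of the
other factor:

    ∂f/∂MDT = a + 2c·MDT + e·DLI = 0  ⇒  MDT_opt(DLI) = −(a + e·DLI)/(2c)
    ∂f/∂DLI = b + 2d·DLI + e·MDT = 0  ⇒  DLI_opt(MDT) = −(b + e·MDT)/(2d)

Both curves are affine in the conditioning factor, with slope −e/(2c)
(resp. −e/(2d)): the sign of the interaction decides whether the
optimum temperature rises or falls with light. The stationary point is
a maximum only when the curvature matrix [[2c, e], [e, 2d]] is negative
definite; :func:`classify_stationary` guards against reporting a
minimum or saddle as an optimum. Optima beyond the experimental
MDT/DLI range are flagged as extrapolations — the quadratic is a local
approximation around the optimum, not a global growth law.
"""

from __future__ import annotations

import numpy as np

from .datamodel import ExperimentalRange, OptimumCurve, SurfaceCoefficients
from .errors import NoOptimumError


def mdt_opt(coeffs: SurfaceCoefficients, dli):
    """Temperature zeroing ∂f/∂MDT at the given DLI: −(a + e·DLI)/(2c).

    Requires the MDT² term c to be present and nonzero (a surface
    linear in MDT has no interior optimum).
    """
    if "c" not in coeffs.term_mask or coeffs.c == 0.0:
        raise NoOptimumError(
            "surface is linear in MDT (c absent or 0): no MDT optimum")
    d = np.asarray(dli, dtype=float)
    out = -(coeffs.a + coeffs.e * d) / (2.0 * coeffs.c)
    return float(out) if out.ndim == 0 else out


def dli_opt(coeffs: SurfaceCoefficients, mdt):
    """Light integral zeroing ∂f/∂DLI at the given MDT: −(b + e·MDT)/(2d)."""
    if "d" not in coeffs.term_mask or coeffs.d == 0.0:
        raise NoOptimumError(
            "surface is linear in DLI (d absent or 0): no DLI optimum")
    m = np.asarray(mdt, dtype=float)
    out = -(coeffs.b + coeffs.e * m) / (2.0 * coeffs.d)
    return float(out) if out.ndim == 0 else out


def classify_stationary(coeffs: SurfaceCoefficients) -> str:
    """Classify the joint stationary point from the curvature matrix
    [[2c, e], [e, 2d]]: ``maximum``, ``minimum``, ``saddle``, or
    ``none`` when the matrix is singular or a quadratic term is absent.
    """
    if "c" not in coeffs.term_mask and "d" not in coeffs.term_mask:
        raise NoOptimumError("no quadratic term present: nothing to classify")
    if "c" not in coeffs.term_mask or "d" not in coeffs.term_mask:
        return "none"
    det = 4.0 * coeffs.c * coeffs.d - coeffs.e ** 2
    if det > 0.0:
        return "maximum" if coeffs.c < 0.0 else "minimum"
    if det < 0.0:
        return "saddle"
    return "none"


def optimum_curve(coeffs: SurfaceCoefficients, kind: str,
                  experimental_range: ExperimentalRange,
                  n_points: int = 50) -> OptimumCurve:
    """Evaluate MDT_opt (kind ``mdt_opt_of_dli``) or DLI_opt
    (``dli_opt_of_mdt``) across the conditioning factor's experimental
    range, flagging points whose optimum exits the observed range.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    r = experimental_range
    if kind == "mdt_opt_of_dli":
        predictor = np.linspace(r.dli_min, r.dli_max, n_points)
        values = np.asarray(mdt_opt(coeffs, predictor))
        lo, hi = r.mdt_min, r.mdt_max
        is_max = coeffs.c < 0.0
    elif kind == "dli_opt_of_mdt":
        predictor = np.linspace(r.mdt_min, r.mdt_max, n_points)
        values = np.asarray(dli_opt(coeffs, predictor))
        lo, hi = r.dli_min, r.dli_max
        is_max = coeffs.d < 0.0
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    try:
        stationary = classify_stationary(coeffs)
    except NoOptimumError:
        stationary = "none"
    extrapolated = (values < lo) | (values > hi)
    return OptimumCurve(
        kind=kind, coefficients=coeffs,
        predictor=tuple(float(x) for x in predictor),
        values=tuple(float(v) for v in values),
        is_maximum=bool(is_max),
        extrapolated=tuple(bool(x) for x in extrapolated),
        stationary_kind=stationary,
        experimental_range=experimental_range,
    )
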
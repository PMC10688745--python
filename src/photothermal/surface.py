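"""Quadratic response-surface fitting on (MDT, DLI).

Every trait is modeled as

    f(MDT, DLI) = y0 + a·MDT + b·DLI + c·MDT² + d·DLI² + e·MDT·DLI

on raw (uncentered) predictors, so fitted coefficients are directly
comparable to published ones. Reduced and univariate models are the
same family with some terms structurally absent.

Fitting is ordinary least squares on per-plant observations at the
*realized* treatment environments; standard errors and p-values come
from the usual OLS covariance. Term selection is backward elimination
under the marginality constraint (a main effect is never dropped while
its quadratic or the interaction survives). Replications are pooled
when the replication × treatment-cell interaction is not significant in
a two-way ANOVA.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import (
    FULL_MASK,
    TERM_NAMES,
    FitResult,
    PoolingDecision,
    SurfaceCoefficients,
)
from .errors import (
    DegenerateVarianceWarning,
    DomainError,
    InsufficientDataError,
    SingularDesignError,
)

#: Term → function of (mdt, dli) producing its regressor column.
_TERM_COLUMNS = {
    "y0": lambda m, l: np.ones_like(m),
    "a": lambda m, l: m,
    "b": lambda m, l: l,
    "c": lambda m, l: m * m,
    "d": lambda m, l: l * l,
    "e": lambda m, l: m * l,
}

#: Marginality: term → the higher-order terms that depend on it.
_DEPENDENTS = {"a": ("c", "e"), "b": ("d", "e")}


def evaluate_surface(coeffs: SurfaceCoefficients, mdt, dli):
    """Evaluate the polynomial at (mdt, dli); accepts scalars or arrays.

    Structurally-absent terms are exactly zero, so evaluation never
    needs the mask.
    """
    m = np.asarray(mdt, dtype=float)
    l = np.asarray(dli, dtype=float)
    out = (coeffs.y0 + coeffs.a * m + coeffs.b * l
           + coeffs.c * m * m + coeffs.d * l * l + coeffs.e * m * l)
    return float(out) if out.ndim == 0 else out


def design_matrix(mdt, dli, term_mask: Iterable[str] = FULL_MASK
                  ) -> tuple[np.ndarray, list[str]]:
    """Regressor matrix with columns in canonical term order."""
    m = np.asarray(mdt, dtype=float)
    l = np.asarray(dli, dtype=float)
    terms = [t for t in TERM_NAMES if t in set(term_mask)]
    X = np.column_stack([_TERM_COLUMNS[t](m, l) for t in terms])
    return X, terms


def _check_design(mdt: np.ndarray, dli: np.ndarray, terms: Sequence[str]) -> None:
    if any(t in terms for t in ("a", "c", "e")) and len(np.unique(mdt)) < 2:
        raise SingularDesignError(
            "MDT terms requested but the design has < 2 distinct MDT levels",
            tuple(t for t in terms if t in ("a", "c", "e")))
    if any(t in terms for t in ("b", "d", "e")) and len(np.unique(dli)) < 2:
        raise SingularDesignError(
            "DLI terms requested but the design has < 2 distinct DLI levels",
            tuple(t for t in terms if t in ("b", "d", "e")))


def fit_surface(mdt, dli, values,
                term_mask: Iterable[str] = FULL_MASK) -> FitResult:
    """OLS fit of the retained terms; returns coefficients, standard
    errors, p-values, R² = 1 − SSE/SST and residual sd.

    Raises :class:`SingularDesignError` on rank-deficient designs
    (naming the collinear columns) and :class:`InsufficientDataError`
    when n ≤ number of retained terms. A constant response has
    undefined SST; R² is then reported as 0 with a
    :class:`DegenerateVarianceWarning`.
    """
    m = np.asarray(mdt, dtype=float).ravel()
    l = np.asarray(dli, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if not (len(m) == len(l) == len(y)):
        raise DomainError("mdt, dli and values must have equal length")
    X, terms = design_matrix(m, l, term_mask)
    if len(y) <= len(terms):
        raise InsufficientDataError(
            f"{len(y)} observations cannot identify {len(terms)} terms")
    _check_design(m, l, terms)

    rank = np.linalg.matrix_rank(X)
    if rank < len(terms):
        # name columns entering last in a pivoted QR as the collinear ones
        from scipy.linalg import qr
        _, _, piv = qr(X, pivoting=True, mode="economic")
        collinear = tuple(terms[j] for j in piv[rank:])
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {len(terms)}); "
            f"collinear term(s): {', '.join(collinear)}", collinear)

    res = sm.OLS(y, X).fit()
    beta = dict(zip(terms, res.params))
    coeffs = SurfaceCoefficients.from_terms(**beta)
    sse = float(np.sum(res.resid ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    # degenerate SST: compare against the response's scale, not exact zero
    if sst <= 1e-12 * len(y) * max(1.0, float(np.mean(y ** 2))):
        warnings.warn(
            "constant response: total sum of squares is 0; reporting R^2 = 0",
            DegenerateVarianceWarning, stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - sse / sst
    dof = len(y) - len(terms)
    return FitResult(
        coefficients=coeffs,
        standard_errors=dict(zip(terms, res.bse)),
        p_values=dict(zip(terms, res.pvalues)),
        r_squared=r2,
        n_obs=len(y),
        residual_sd=float(np.sqrt(sse / dof)) if dof > 0 else 0.0,
    )


def select_terms(mdt, dli, values, alpha: float = 0.05,
                 start_mask: Iterable[str] = FULL_MASK) -> frozenset[str]:
    """Backward elimination from the full model at level ``alpha``.

    At each step the least-significant *removable* term (largest
    p-value above ``alpha``) is dropped. The intercept is never removed
    and marginality is respected: a main effect (a or b) is only
    removable once every higher-order term involving it (c/d/e) has
    been removed.
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    mask = set(start_mask)
    while True:
        fit = fit_surface(mdt, dli, values, mask)
        removable = [
            t for t in mask
            if t != "y0"
            and not any(dep in mask for dep in _DEPENDENTS.get(t, ()))
        ]
        if not removable:
            return frozenset(mask)
        worst = max(removable, key=lambda t: fit.p_values[t])
        if fit.p_values[worst] > alpha:
            mask.remove(worst)
        else:
            return frozenset(mask)


def replications_poolable(cells, replications, values,
                          alpha: float = 0.05) -> PoolingDecision:
    """Decide whether replications may be pooled.

    Tests the replication × treatment-cell interaction with an F-test
    in the two-way ANOVA of ``values`` on cell and replication labels;
    replications are poolable iff the interaction is not significant
    (p > ``alpha``). With a single replication the question does not
    arise and the data are pooled trivially (``applicable=False``).
    """
    frame = pd.DataFrame({
        "cell": pd.Categorical(cells),
        "rep": pd.Categorical(replications),
        "value": np.asarray(values, dtype=float),
    })
    n_reps = frame["rep"].nunique()
    if n_reps < 2:
        return PoolingDecision(True, None, None, applicable=False)
    if frame["cell"].nunique() < 2:
        raise DomainError("need >= 2 treatment cells to test the interaction")

    import statsmodels.formula.api as smf
    model = smf.ols("value ~ C(cell) * C(rep)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = table.loc["C(cell):C(rep)"]
    ss_int = float(inter["sum_sq"])
    total_ss = float(np.sum((frame["value"] - frame["value"].mean()) ** 2))
    f_stat = float(inter["F"]) if np.isfinite(inter["F"]) else None
    p = float(inter["PR(>F)"]) if np.isfinite(inter["PR(>F)"]) else None
    if p is None:
        # zero residual variance: identical replicates ⇒ interaction SS 0
        poolable = ss_int <= 1e-10 * max(total_ss, 1.0)
        return PoolingDecision(poolable, None, f_stat)
    return PoolingDecision(p > alpha, p, f_stat)
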
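"""Surface evaluation, OLS fitting, term selection, replication pooling."""

import numpy as np
import pytest

from photothermal import (
    FULL_MASK,
    SurfaceCoefficients,
    evaluate_surface,
    fit_surface,
    replications_poolable,
    select_terms,
)
from photothermal.errors import (
    DegenerateVarianceWarning,
    InsufficientDataError,
    SingularDesignError,
)
from conftest import ref_row


def _grid(mdts=(23, 26, 29, 32, 35), dlis=(7, 10, 14), reps=3):
    m, l = np.meshgrid(mdts, dlis)
    return np.tile(m.ravel(), reps).astype(float), np.tile(l.ravel(), reps).astype(float)


# ---------------------------------------------------------------------------
# evaluation


def test_evaluate_univariate_dli_model_reproduces_published_span(reference_rows):
    row = ref_row(reference_rows, "purple_basil", "fresh_mass_g", has="b")
    assert evaluate_surface(row.coefficients, 29.0, 18.7) == pytest.approx(97.4, abs=0.05)
    assert evaluate_surface(row.coefficients, 29.0, 5.0) == pytest.approx(21.8, abs=0.05)


def test_evaluate_full_surface_direct_arithmetic(reference_rows):
    row = ref_row(reference_rows, "sage", "fresh_mass_g")
    assert evaluate_surface(row.coefficients, 22.8, 18.3) == pytest.approx(59.45, abs=0.05)


def test_constant_surface_is_constant():
    coeffs = SurfaceCoefficients.from_terms(y0=7.0)
    for mdt, dli in [(0.0, 0.0), (23.0, 5.0), (35.0, 19.0)]:
        assert evaluate_surface(coeffs, mdt, dli) == 7.0


def test_evaluation_is_linear_in_coefficients(rng):
    mdt, dli = rng.uniform(20, 36, 10), rng.uniform(5, 19, 10)
    t1 = dict(zip("yabcde", rng.normal(size=6)))
    t2 = dict(zip("yabcde", rng.normal(size=6)))
    mk = lambda t: SurfaceCoefficients(t["y"], t["a"], t["b"], t["c"], t["d"], t["e"])
    sum_coeffs = mk({k: t1[k] + t2[k] for k in t1})
    np.testing.assert_allclose(
        evaluate_surface(sum_coeffs, mdt, dli),
        evaluate_surface(mk(t1), mdt, dli) + evaluate_surface(mk(t2), mdt, dli),
        rtol=1e-12)


# ---------------------------------------------------------------------------
# fitting


def test_noiseless_polynomial_data_is_interpolated_exactly():
    truth = SurfaceCoefficients(1.0, 2.0, 3.0, -0.1, -0.2, 0.05)
    mdt, dli = _grid()
    y = evaluate_surface(truth, mdt, dli)
    fit = fit_surface(mdt, dli, y)
    for t in FULL_MASK:
        assert fit.coefficients[t] == pytest.approx(truth[t], abs=1e-8)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)


def test_fit_agrees_with_normal_equations_oracle(rng):
    from photothermal.surface import design_matrix
    mdt = rng.uniform(20, 36, 60)
    dli = rng.uniform(5, 19, 60)
    y = rng.normal(40, 12, 60)
    fit = fit_surface(mdt, dli, y)
    X, terms = design_matrix(mdt, dli)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    for t, b in zip(terms, beta):
        assert fit.coefficients[t] == pytest.approx(b, abs=1e-8)
    # R² definition holds on the fitting data
    sse = np.sum((y - evaluate_surface(fit.coefficients, mdt, dli)) ** 2)
    sst = np.sum((y - y.mean()) ** 2)
    assert fit.r_squared == pytest.approx(1 - sse / sst, abs=1e-10)


def test_constant_response_degenerates_gracefully():
    mdt, dli = _grid()
    with pytest.warns(DegenerateVarianceWarning):
        fit = fit_surface(mdt, dli, np.full(mdt.size, 4.2))
    assert fit.coefficients.y0 == pytest.approx(4.2, abs=1e-10)
    for t in "abcde":
        assert fit.coefficients[t] == pytest.approx(0.0, abs=1e-10)
    assert fit.r_squared == 0.0


def test_rank_deficient_design_names_collinear_terms(rng):
    mdt = rng.uniform(20, 36, 40)
    dli = mdt.copy()  # DLI perfectly collinear with MDT
    with pytest.raises(SingularDesignError) as err:
        fit_surface(mdt, dli, rng.normal(size=40))
    assert err.value.collinear_terms


def test_too_few_observations_raise():
    with pytest.raises(InsufficientDataError):
        fit_surface([23, 26, 29], [7, 10, 14], [1.0, 2.0, 3.0])


def test_single_mdt_level_cannot_identify_mdt_terms():
    with pytest.raises(SingularDesignError):
        fit_surface(np.full(20, 26.0), np.linspace(5, 19, 20),
                    np.arange(20.0), {"y0", "a", "b"})


# ---------------------------------------------------------------------------
# term selection


def test_noiseless_full_truth_retains_all_terms():
    truth = SurfaceCoefficients(-255, 17.0, 12.6, -0.287, -0.221, -0.193)
    mdt, dli = _grid(reps=4)
    mask = select_terms(mdt, dli, evaluate_surface(truth, mdt, dli))
    assert mask == FULL_MASK


def test_pure_mdt_linear_truth_selects_mdt_only():
    truth = SurfaceCoefficients.from_terms(y0=-28.0, a=1.46)
    mdt, dli = _grid(reps=10)
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y = evaluate_surface(truth, mdt, dli) + rng.normal(0, 2.0, mdt.size)
        if select_terms(mdt, dli, y) == frozenset({"y0", "a"}):
            hits += 1
    assert hits >= 15  # large majority of seeded runs


def test_pure_noise_keeps_only_intercept_at_type_one_rate():
    mdt, dli = _grid(reps=10)
    hits = 0
    n_runs = 60
    for seed in range(n_runs):
        rng = np.random.default_rng(1000 + seed)
        y = rng.normal(0, 1, mdt.size)
        if select_terms(mdt, dli, y) == frozenset({"y0"}):
            hits += 1
    # stepwise type-I behavior: about (1 - alpha) per removable term, so
    # familywise retention of the bare intercept sits near 0.95^5 ≈ 0.77
    # minus the collinearity of raw polynomial terms
    assert hits / n_runs > 0.55


def test_marginality_keeps_main_effects_under_interaction():
    """A strong pure-interaction truth must not strip the a/b main effects."""
    truth = SurfaceCoefficients.from_terms(y0=1.0, e=0.5)
    mdt, dli = _grid(reps=10)
    rng = np.random.default_rng(3)
    y = evaluate_surface(truth, mdt, dli) + rng.normal(0, 1.0, mdt.size)
    mask = select_terms(mdt, dli, y)
    assert "e" in mask
    assert {"a", "b"} <= mask  # marginality constraint


# ---------------------------------------------------------------------------
# replication pooling


def _two_rep_layout(shift_cells=(), offset=0.0, sd=1.0, seed=0, n_per_cell=8):
    rng = np.random.default_rng(seed)
    cells, reps, values = [], [], []
    base = {c: 10.0 + 3.0 * i for i, c in enumerate("ABCDEF")}
    rep1 = {c: rng.normal(base[c], sd, n_per_cell) for c in base}
    for rep in (1, 2):
        for c in base:
            vals = rep1[c].copy()
            if rep == 2:
                vals = vals + offset + (10.0 * sd if c in shift_cells else 0.0)
            cells += [c] * n_per_cell
            reps += [rep] * n_per_cell
            values += list(vals)
    return cells, reps, np.array(values)


def test_identical_replicates_are_poolable():
    cells, reps, values = _two_rep_layout()
    decision = replications_poolable(cells, reps, values)
    assert decision.poolable
    assert decision.p_value is None or decision.p_value > 0.999


def test_treatment_dependent_shift_blocks_pooling_and_matches_f_oracle():
    cells, reps, values = _two_rep_layout(shift_cells=("A", "B"))
    decision = replications_poolable(cells, reps, values)
    assert not decision.poolable

    # brute-force balanced two-way interaction F statistic
    import pandas as pd
    frame = pd.DataFrame({"cell": cells, "rep": reps, "y": values})
    grand = frame["y"].mean()
    cell_mean = frame.groupby("cell")["y"].transform("mean")
    rep_mean = frame.groupby("rep")["y"].transform("mean")
    cell_rep_mean = frame.groupby(["cell", "rep"])["y"].transform("mean")
    ss_int = np.sum((cell_rep_mean - cell_mean - rep_mean + grand) ** 2)
    ss_res = np.sum((frame["y"] - cell_rep_mean) ** 2)
    df_int = (frame["cell"].nunique() - 1) * (frame["rep"].nunique() - 1)
    df_res = len(frame) - frame["cell"].nunique() * frame["rep"].nunique()
    f_oracle = (ss_int / df_int) / (ss_res / df_res)
    assert decision.f_statistic == pytest.approx(f_oracle, rel=1e-6)


def test_constant_rep_offset_is_a_main_effect_not_interaction():
    hits = 0
    for seed in range(10):
        cells, reps, values = _two_rep_layout(offset=5.0, seed=seed)
        if replications_poolable(cells, reps, values).poolable:
            hits += 1
    assert hits >= 8


def test_single_replication_pools_trivially():
    decision = replications_poolable(["A", "A", "B", "B"], [1, 1, 1, 1],
                                     [1.0, 2.0, 3.0, 4.0])
    assert decision.poolable and not decision.applicable
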
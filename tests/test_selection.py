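"""OLS engine and variable-selection algorithms against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest

import biacomp as bc
from biacomp.linreg import RankDeficientError, SubsetOLS, ols_fit
from biacomp.selection import (backward_path_indices, best_subsets_engine,
                               choose_size, information_criterion,
                               rcv_select_engine, rcv_size_curve)


def _instance(seed, n=40, p=5, sd=1.0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = rng.normal(size=p)
    y = X @ beta + rng.normal(0, sd, n)
    return X, y, [f"x{i}" for i in range(p)]


def test_noise_free_line():
    x = np.linspace(0, 10, 30)[:, None]
    fit = ols_fit(x, 2.0 * x[:, 0] + 3.0, ["x1"])
    np.testing.assert_allclose(fit.params, [3.0, 2.0], atol=1e-10)
    assert fit.rsquared == pytest.approx(1.0, abs=1e-12)


def test_residuals_orthogonal_to_regressors():
    X, y, names = _instance(0, n=10, p=3)
    fit = ols_fit(X, y, names)
    resid = y - fit.linear_predictor(X)
    scale = np.abs(X).max() * np.abs(y).max()
    assert np.all(np.abs(X.T @ resid) <= 1e-8 * scale)
    assert abs(resid.sum()) <= 1e-8 * scale


def test_ols_matches_normal_equation_oracle():
    """Coefficients agree with an explicit normal-equation solve."""
    X, y, names = _instance(1, n=10, p=3)
    fit = ols_fit(X, y, names)
    Z = np.column_stack([np.ones(len(y)), X])
    oracle = np.linalg.solve(Z.T @ Z, Z.T @ y)
    np.testing.assert_allclose(fit.params, oracle, atol=1e-8)


def test_ols_matches_statsmodels(study_table):
    """Full inference (SEs, t, p, r²) cross-checked against statsmodels
    on study-sized data."""
    sm = pytest.importorskip("statsmodels.api")
    vars_ = ["ri_50", "height_m", "bmi", "sex"]
    X = study_table[vars_].to_numpy()
    y = study_table["tbw_pct"].to_numpy()
    fit = ols_fit(X, y, vars_)
    ref = sm.OLS(y, sm.add_constant(X)).fit()
    np.testing.assert_allclose(fit.params, ref.params, rtol=1e-8)
    np.testing.assert_allclose(fit.bse, ref.bse, rtol=1e-7)
    np.testing.assert_allclose(fit.pvalues, ref.pvalues, atol=1e-10)
    assert fit.rsquared == pytest.approx(ref.rsquared, rel=1e-10)
    assert fit.max_p == pytest.approx(ref.pvalues[1:].max(), abs=1e-12)


def test_rank_deficiency_names_columns():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 3))
    X = np.column_stack([X, X[:, 0] + X[:, 1]])
    with pytest.raises(RankDeficientError, match="x3"):
        ols_fit(X, X @ np.ones(4), ["x0", "x1", "x2", "x3"])


def test_information_criterion_penalties():
    X, y, names = _instance(3, n=100, p=6)
    engine = SubsetOLS(X, y, names)
    small = engine.full_fit([0, 1, 2])
    # equal RSS at different sizes: the smaller model wins both criteria
    for which in ("aic", "bic"):
        penalty = 2.0 if which == "aic" else math.log(100)
        score_small = information_criterion(small, which)
        score_big_same_rss = (100 * math.log(small.rss / 100)
                              + (5 + 2) * penalty)
        assert score_small < score_big_same_rss
    # adding a column never increases RSS
    _, rss3 = engine.slopes(np.array([0, 1, 2]))
    _, rss4 = engine.slopes(np.array([0, 1, 2, 3]))
    assert rss4 <= rss3 + 1e-12


def test_aic_never_selects_fewer_than_bic():
    """Exhaustive enumeration over 6-candidate instances: the AIC
    optimum is never smaller than the BIC optimum (ln n > 2)."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 6))
        beta = rng.normal(size=6) * (rng.random(6) < 0.5)
        y = X @ beta + rng.normal(0, 1.0, 60)
        engine = SubsetOLS(X, y, [f"x{i}" for i in range(6)])
        idx_aic, _ = best_subsets_engine(engine, "aic")
        idx_bic, _ = best_subsets_engine(engine, "bic")
        assert len(idx_aic) >= len(idx_bic)


def test_best_subsets_recovers_true_support():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(80, 6))
    y = 1.5 * X[:, 1] - 2.0 * X[:, 4] + rng.normal(0, 0.01, 80)
    engine = SubsetOLS(X, y, [f"x{i}" for i in range(6)])
    idx, _ = best_subsets_engine(engine, "bic")
    assert set(idx) == {1, 4}


def test_best_subsets_single_candidate_and_bound():
    X, y, names = _instance(5, n=30, p=1)
    engine = SubsetOLS(X, y, names)
    idx, _ = best_subsets_engine(engine, "aic")
    assert idx == (0,)
    rng = np.random.default_rng(6)
    Xbig = rng.normal(size=(40, 30))
    big = SubsetOLS(Xbig, rng.normal(size=40), [f"x{i}" for i in range(30)])
    with pytest.raises(ValueError, match="backward"):
        best_subsets_engine(big)


def test_best_subsets_matches_enumeration_oracle():
    """Selected set and score equal an independent lstsq enumeration."""
    rng = np.random.default_rng(7)
    n, p = 50, 10
    X = rng.normal(size=(n, p))
    y = X[:, 0] - X[:, 3] + 0.5 * X[:, 7] + rng.normal(0, 0.5, n)
    names = [f"x{i}" for i in range(p)]
    engine = SubsetOLS(X, y, names)
    for which, penalty in (("aic", 2.0), ("bic", math.log(n))):
        best_score, best_set = math.inf, None
        for size in range(1, p + 1):
            for idx in combinations(range(p), size):
                Z = np.column_stack([np.ones(n), X[:, idx]])
                beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
                rss = float(np.sum((y - Z @ beta) ** 2))
                score = n * math.log(rss / n) + (size + 2) * penalty
                if score < best_score:
                    best_score, best_set = score, idx
        got_idx, got_score = best_subsets_engine(engine, which)
        assert got_idx == best_set
        assert got_score == pytest.approx(best_score, abs=1e-8)


def test_backward_path_structure():
    X, y, names = _instance(8, n=60, p=6)
    engine = SubsetOLS(X, y, names)
    path = backward_path_indices(engine)
    assert [len(p) for p in path] == [6, 5, 4, 3, 2, 1]
    for bigger, smaller in zip(path, path[1:]):
        assert set(smaller) < set(bigger)


def test_backward_path_drops_noise_first():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(100, 2))
    y = 3.0 * X[:, 0] + rng.normal(0, 0.01, 100)
    engine = SubsetOLS(X, y, ["strong", "noise"])
    path = backward_path_indices(engine)
    assert [list(p) for p in path] == [[0, 1], [0]]


def test_best_subsets_never_worse_than_path_models():
    X, y, names = _instance(10, n=60, p=6)
    engine = SubsetOLS(X, y, names)
    idx_best, score_best = best_subsets_engine(engine, "bic")
    for idx in backward_path_indices(engine):
        fit = engine.full_fit(idx)
        assert score_best <= information_criterion(fit, "bic") + 1e-9


def test_rcv_select_determinism_and_one_se_parsimony():
    X, y, names = _instance(11, n=120, p=8, sd=1.0,
                            beta=np.array([2, 1, 0, 0, 0, 0, 0, 0.2]))
    a, _ = rcv_select_engine(X, y, names, rng=np.random.default_rng(5))
    b, _ = rcv_select_engine(X, y, names, rng=np.random.default_rng(5))
    assert np.array_equal(a, b)
    for seed in range(5):
        rng1 = np.random.default_rng(seed)
        rng2 = np.random.default_rng(seed)
        _, with_rule = rcv_select_engine(X, y, names, rng=rng1, one_se=True)
        _, without = rcv_select_engine(X, y, names, rng=rng2, one_se=False)
        assert with_rule["chosen_size"] <= without["chosen_size"]


def test_rcv_select_recovers_support_at_low_noise():
    hits = 0
    names = [f"x{i}" for i in range(8)]
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(178, 8))
        y = 2 * X[:, 0] + X[:, 1] + rng.normal(0, 0.1, 178)
        idx, _ = rcv_select_engine(X, y, names,
                                   rng=np.random.default_rng(seed + 1000))
        assert {0, 1} <= set(idx)  # the true support is always included
        hits += set(idx) == {0, 1}
    assert hits >= 8


def test_cv_preconditions():
    X, y, names = _instance(12, n=15, p=3)
    with pytest.raises(ValueError, match="too small"):
        rcv_size_curve(X, y, names, k=10, repeats=1,
                       rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="at least 2"):
        rcv_size_curve(X, y, names, k=1, repeats=1,
                       rng=np.random.default_rng(0))


def test_choose_size_one_se_rule():
    # minimum mean RMSE 0.98 at size 3; size 2's mean 1.0 is within one
    # SE (0.05/sqrt(3) ≈ 0.029) of it, so the rule prefers size 2
    mat = np.array([[2.0, 1.05, 0.98, 1.02],
                    [2.2, 0.95, 0.93, 0.98],
                    [1.8, 1.00, 1.03, 1.00]])
    assert choose_size(mat, one_se=False) == 3
    assert choose_size(mat, one_se=True) == 2
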
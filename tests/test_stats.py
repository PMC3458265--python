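"""Correlation, partial correlation, FDR, VIF, KS screen, stepwise OLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor

from geotrend.errors import CollinearityError, DegenerateInputError
from geotrend.stats import (
    StepwiseOLS,
    bh_fdr,
    ks_normality,
    partial_correlation,
    pearson,
    stepwise_select,
    vif,
)


def vectors_with_gram(R, n=30, seed=0):
    """Centered unit vectors whose exact sample correlation matrix is R."""
    g = np.random.default_rng(seed)
    k = R.shape[0]
    basis = g.standard_normal((n, k))
    basis -= basis.mean(axis=0)
    q, _ = np.linalg.qr(basis)
    L = np.linalg.cholesky(R)
    return (q[:, :k] @ L.T).T  # rows are the variables


# -- pearson -----------------------------------------------------------


def test_pearson_self_and_antisymmetry():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = pearson(x, x)
    assert res.r == pytest.approx(1.0)
    assert res.p < 1e-12
    assert pearson(x, -x).r == pytest.approx(-1.0)


def test_pearson_direct_formula_oracle():
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 6])
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    expected = cov / (x.std() * y.std())
    res = pearson(x, y)
    assert res.r == pytest.approx(expected, abs=1e-12)
    r_sp, p_sp = sps.pearsonr(x, y)
    assert res.r == pytest.approx(r_sp, abs=1e-12)
    assert res.p == pytest.approx(p_sp, rel=1e-9)


def test_pearson_rejects_constant():
    with pytest.raises(DegenerateInputError):
        pearson([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


@settings(deadline=None, max_examples=40)
@given(
    slope=st.floats(min_value=0.01, max_value=100),
    offset=st.floats(min_value=-50, max_value=50),
    seed=st.integers(0, 1000),
)
def test_pearson_affine_invariance(slope, offset, seed):
    g = np.random.default_rng(seed)
    x, y = g.standard_normal(15), g.standard_normal(15)
    base = pearson(x, y).r
    assert pearson(slope * x + offset, y).r == pytest.approx(base, abs=1e-9)
    assert pearson(-slope * x + offset, y).r == pytest.approx(-base, abs=1e-9)


# -- partial correlation ----------------------------------------------


def test_partial_reduces_to_pearson_without_controls():
    g = np.random.default_rng(1)
    x, y = g.standard_normal(20), g.standard_normal(20)
    assert partial_correlation(x, y).r == pytest.approx(pearson(x, y).r)


def test_partial_first_order_recursion_oracle():
    R = np.array([[1.0, 0.8, 0.5], [0.8, 1.0, 0.5], [0.5, 0.5, 1.0]])
    x, y, z = vectors_with_gram(R, n=30, seed=3)
    res = partial_correlation(x, y, [z])
    expected = (0.8 - 0.5 * 0.5) / np.sqrt((1 - 0.25) * (1 - 0.25))
    assert res.r == pytest.approx(expected, abs=1e-10)
    assert res.df == 30 - 3


def test_partial_residual_annihilation():
    g = np.random.default_rng(2)
    z = g.standard_normal(25)
    x = g.standard_normal(25)
    y = 3.0 * z - 1.0  # exact linear function of the control
    assert partial_correlation(x, y, [z]).r == pytest.approx(0.0, abs=1e-10)


def test_partial_matches_inverse_correlation_matrix():
    g = np.random.default_rng(9)
    for _ in range(25):
        n, k = 30, int(g.integers(1, 4))
        data = g.standard_normal((n, 2 + k))
        res = partial_correlation(data[:, 0], data[:, 1], data[:, 2:].T)
        P = np.linalg.inv(np.corrcoef(data, rowvar=False))
        expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert res.r == pytest.approx(expected, abs=1e-8)


def test_partial_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    g = np.random.default_rng(5)
    df = pd.DataFrame(g.standard_normal((40, 4)), columns=list("xyzw"))
    res = partial_correlation(df.x, df.y, [df.z, df.w], control_names=("z", "w"))
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
    pcol = "p_val" if "p_val" in ref.columns else "p-val"
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
    assert res.p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)


def test_partial_rank_deficient_controls_raise():
    g = np.random.default_rng(0)
    x, y, z = (g.standard_normal(20) for _ in range(3))
    with pytest.raises(CollinearityError):
        partial_correlation(x, y, [z, 2 * z])


# -- BH FDR ------------------------------------------------------------


def brute_force_bh(p, q):
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    if k_star == 0:
        return np.array([], dtype=int)
    return np.sort(np.flatnonzero(p <= p[order[k_star - 1]]))


def test_bh_fdr_examples():
    accepted = bh_fdr([0.01, 0.02, 0.04, 0.20], q=0.05)
    assert accepted.tolist() == [0, 1]
    assert bh_fdr([0.0, 0.0, 0.0], q=0.05).tolist() == [0, 1, 2]
    assert bh_fdr([1.0, 1.0], q=0.05).size == 0


def test_bh_fdr_matches_brute_force_and_statsmodels():
    g = np.random.default_rng(11)
    for _ in range(50):
        p = g.uniform(size=int(g.integers(1, 20)))
        q = float(g.uniform(0.01, 0.2))
        ours = bh_fdr(p, q)
        assert ours.tolist() == brute_force_bh(p, q).tolist()
        reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
        assert ours.tolist() == np.flatnonzero(reject).tolist()


def test_bh_fdr_monotone_in_q():
    g = np.random.default_rng(13)
    p = g.uniform(size=15)
    prev: set = set()
    for q in (0.01, 0.05, 0.1, 0.2, 0.5):
        cur = set(bh_fdr(p, q).tolist())
        assert prev <= cur
        prev = cur


# -- VIF ---------------------------------------------------------------


def test_vif_orthogonal_predictors():
    R = np.eye(2)
    x1, x2 = vectors_with_gram(R, n=20, seed=7)
    out = vif(pd.DataFrame({"a": x1, "b": x2}))
    assert out["a"] == pytest.approx(1.0, abs=1e-10)
    assert out["b"] == pytest.approx(1.0, abs=1e-10)


def test_vif_closed_form_two_predictors():
    R = np.array([[1.0, 0.8], [0.8, 1.0]])
    x1, x2 = vectors_with_gram(R, n=25, seed=8)
    out = vif(pd.DataFrame({"a": x1, "b": x2}))
    assert out["a"] == pytest.approx(1 / (1 - 0.64), abs=1e-8)


def test_vif_matches_statsmodels():
    g = np.random.default_rng(17)
    X = pd.DataFrame(g.standard_normal((30, 3)), columns=list("abc"))
    X["c"] += 0.7 * X["a"]
    ours = vif(X)
    design = np.column_stack([np.ones(30), X.to_numpy()])
    for j, col in enumerate(X.columns):
        ref = variance_inflation_factor(design, j + 1)
        assert ours[col] == pytest.approx(ref, rel=1e-8)


def test_vif_exact_collinearity_names_offender():
    g = np.random.default_rng(3)
    x = g.standard_normal(15)
    with pytest.raises(CollinearityError, match="collinear"):
        vif(pd.DataFrame({"a": x, "b": 3 * x}))


# -- KS normality ------------------------------------------------------


def test_ks_normal_sample_retained():
    g = np.random.default_rng(4)
    res = ks_normality(g.standard_normal(23), alpha=0.001)
    assert res.retained


def test_ks_heavy_outlier_rejected():
    vals = np.zeros(23)
    vals[:-1] += np.linspace(-0.01, 0.01, 22)  # tiny spread, one huge outlier
    vals[-1] = 1000.0
    assert not ks_normality(vals, alpha=0.001).retained


def test_ks_constant_not_normal_by_convention():
    res = ks_normality(np.ones(10))
    assert not res.retained
    assert res.p == 0.0


# -- stepwise ----------------------------------------------------------


def test_stepwise_recovers_single_true_predictor():
    g = np.random.default_rng(21)
    x1 = g.standard_normal(50)
    x2 = g.standard_normal(50)
    y = 2.0 * x1 + 0.05 * g.standard_normal(50)
    model = stepwise_select(y, {"x1": x1, "x2": x2})
    assert model.predictors == ("x1",)
    assert model.coefficients[0] == pytest.approx(2.0, rel=0.05)
    assert model.r_squared > 0.99


def test_stepwise_dominant_candidate_wins():
    # two candidates both correlated with y, one dominant -> single-predictor model
    g = np.random.default_rng(22)
    ct = g.standard_normal(50)
    mp = 0.6 * ct + 0.8 * g.standard_normal(50)
    y = 3.0 * ct + 0.5 * g.standard_normal(50)
    model = stepwise_select(y, {"CT": ct, "MP": mp})
    assert model.predictors == ("CT",)


def test_stepwise_intercept_only_when_nothing_passes():
    g = np.random.default_rng(23)
    y = g.standard_normal(40)
    X = {"a": np.linspace(0, 1, 40)}
    model = stepwise_select(y, X, alpha_enter=1e-6)
    assert model.is_intercept_only
    assert model.r_squared == 0.0
    assert model.intercept == pytest.approx(float(np.mean(y)))


def test_stepwise_r2_non_decreasing_and_coefficient_stage():
    g = np.random.default_rng(24)
    n = 60
    X = pd.DataFrame(g.standard_normal((n, 4)), columns=list("abcd"))
    y = 1.5 * X["a"] + 1.0 * X["b"] + g.standard_normal(n)
    for stage in ("screen", "coefficients"):
        est = StepwiseOLS(fdr_stage=stage).fit(X, y)
        assert set(est.predictors_) >= {"a", "b"} - set()  # both true effects found
        # nesting: model R2 at least each single-predictor R2
        for p in est.predictors_:
            single = StepwiseOLS().fit(X[[p]], y)
            assert est.r_squared_ >= single.r_squared_ - 1e-12


def test_stepwise_warns_on_high_vif():
    # both predictors carry independent signal but correlate at 0.9 (VIF ~ 5)
    g = np.random.default_rng(25)
    a = g.standard_normal(60)
    b = 0.9 * a + np.sqrt(0.19) * g.standard_normal(60)
    y = a + b + 0.3 * g.standard_normal(60)
    with pytest.warns(UserWarning, match="collinearity"):
        est = StepwiseOLS().fit(pd.DataFrame({"a": a, "b": b}), y)
    assert set(est.predictors_) == {"a", "b"}
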
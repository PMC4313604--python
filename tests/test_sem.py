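"""Tests of the path-model engine: implied moments, discrepancy functions,
FIML, degrees of freedom, fit indices, and multi-group machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spiral_alt.sem import (
    PathModelSpec,
    chi_square_difference,
    fiml_loglik,
    fit_indices,
    fit_model,
    fit_multigroup,
    implied_moments,
    ml_discrepancy,
    model_df,
    mvn_mle,
    rmsea_ci,
)

from conftest import exact_cov_sample


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------


def test_implied_single_indicator_variance_sums():
    spec = PathModelSpec(["y"], ["eta"])
    spec.path("eta", "y", free=False, value=1.0)
    spec.var("eta", free=False, value=2.0)
    spec.var("y", free=False, value=1.0)
    spec.mean("eta", free=False, value=0.0)
    spec.mean("y", free=False, value=0.0)
    Sigma, mu = implied_moments(spec, {})
    assert Sigma[0, 0] == pytest.approx(3.0)
    assert mu[0] == pytest.approx(0.0)


def test_implied_chain_path_tracing():
    spec = PathModelSpec(["y1", "y2"])
    spec.path("y1", "y2", free=False, value=0.5)
    spec.var("y1", free=False, value=4.0)
    spec.var("y2", free=False, value=1.0)
    spec.mean("y1", free=False, value=1.0)
    spec.mean("y2", free=False, value=0.0)
    Sigma, mu = implied_moments(spec, {})
    assert Sigma[0, 1] == pytest.approx(2.0)  # 0.5 * var(y1)
    assert Sigma[1, 1] == pytest.approx(2.0)  # 0.25 * 4 + 1
    assert mu[1] == pytest.approx(0.5)  # propagated mean


def test_implied_moments_requires_all_values():
    spec = PathModelSpec(["y1", "y2"])
    spec.path("y1", "y2")
    spec.var("y1", free=False, value=1.0)
    spec.var("y2", free=False, value=1.0)
    with pytest.raises(ValueError, match="no value"):
        implied_moments(spec, {})


# ---------------------------------------------------------------------------
# discrepancy and likelihoods
# ---------------------------------------------------------------------------


def test_ml_discrepancy_saturated_is_zero():
    S = np.array([[2.0, 0.5], [0.5, 1.0]])
    assert ml_discrepancy(S, [1.0, 2.0], S, [1.0, 2.0]) == pytest.approx(0.0)


def test_ml_discrepancy_univariate_closed_form():
    # p=1, S=2, Sigma=1: F = ln 1 - ln 2 + 2 - 1 = 1 - ln 2
    assert ml_discrepancy([[2.0]], [0.0], [[1.0]], [0.0]) == pytest.approx(1 - np.log(2))


def test_ml_discrepancy_matches_elementwise_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 4 * np.eye(4)
        B = rng.normal(size=(4, 4))
        Sig = B @ B.T + 4 * np.eye(4)
        xbar, mu = rng.normal(size=4), rng.normal(size=4)
        d = xbar - mu
        oracle = (
            np.log(np.linalg.det(Sig))
            - np.log(np.linalg.det(S))
            + np.trace(S @ np.linalg.inv(Sig))
            - 4
            + d @ np.linalg.inv(Sig) @ d
        )
        assert ml_discrepancy(S, xbar, Sig, mu) == pytest.approx(oracle, abs=1e-10)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_ml_discrepancy_nonnegative(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    S = A @ A.T + 3 * np.eye(3)
    B = rng.normal(size=(3, 3))
    Sig = B @ B.T + 3 * np.eye(3)
    assert ml_discrepancy(S, rng.normal(size=3), Sig, rng.normal(size=3)) >= 0


def _small_spec():
    spec = PathModelSpec(["y1", "y2", "y3"])
    for v in ("y1", "y2", "y3"):
        spec.var(v)
        spec.mean(v)
    spec.cov("y1", "y2")
    spec.cov("y1", "y3")
    spec.cov("y2", "y3")
    return spec


def test_fiml_single_standard_normal_case():
    spec = PathModelSpec(["y"])
    spec.var("y", free=False, value=1.0)
    spec.mean("y", free=False, value=0.0)
    ll = fiml_loglik(spec, {}, np.array([[0.0]]))
    assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))


def test_fiml_no_missing_equals_complete_data_loglik():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(40, 3)) @ np.diag([1.0, 2.0, 0.5]) + [0.0, 1.0, -1.0]
    spec = _small_spec()
    vals = {}
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=0)
    for i, v in enumerate(("y1", "y2", "y3")):
        vals[f"mean:{v}"] = mu[i]
        vals[f"{v}~~{v}"] = S[i, i]
    vals["y1~~y2"], vals["y1~~y3"], vals["y2~~y3"] = S[0, 1], S[0, 2], S[1, 2]
    ll = fiml_loglik(spec, vals, X)
    oracle = stats.multivariate_normal.logpdf(X, mean=mu, cov=S).sum()
    assert ll == pytest.approx(oracle, abs=1e-10)


def test_fiml_mcar_matches_casewise_oracle():
    rng = np.random.default_rng(6)
    A = rng.normal(size=(3, 3))
    Sig = A @ A.T + 2 * np.eye(3)
    mu = np.array([0.5, -0.2, 1.0])
    X = rng.multivariate_normal(mu, Sig, size=120)
    X[rng.random(X.shape) < 0.3] = np.nan
    X = X[~np.isnan(X).all(axis=1)]
    spec = _small_spec()
    vals = {
        "mean:y1": mu[0], "mean:y2": mu[1], "mean:y3": mu[2],
        "y1~~y1": Sig[0, 0], "y2~~y2": Sig[1, 1], "y3~~y3": Sig[2, 2],
        "y1~~y2": Sig[0, 1], "y1~~y3": Sig[0, 2], "y2~~y3": Sig[1, 2],
    }
    ll = fiml_loglik(spec, vals, X)
    # independent casewise oracle: marginal normal density per case
    oracle = 0.0
    for row in X:
        o = ~np.isnan(row)
        oracle += stats.multivariate_normal.logpdf(
            row[o], mean=mu[o], cov=Sig[np.ix_(o, o)]
        )
    assert ll == pytest.approx(oracle, rel=1e-10)


def test_mvn_mle_em_recovers_saturated_loglik():
    rng = np.random.default_rng(7)
    Sig = np.array([[1.0, 0.6], [0.6, 2.0]])
    mu = np.array([0.0, 1.0])
    X = rng.multivariate_normal(mu, Sig, size=300)
    X[rng.random(X.shape) < 0.25] = np.nan
    X = X[~np.isnan(X).all(axis=1)]
    mu_hat, Sig_hat, ll = mvn_mle(X)
    # the EM solution must beat (or at least match) the generating values
    spec = PathModelSpec(["y1", "y2"])
    spec.var("y1", free=False, value=Sig[0, 0])
    spec.var("y2", free=False, value=Sig[1, 1])
    spec.cov("y1", "y2", free=False, value=Sig[0, 1])
    spec.mean("y1", free=False, value=mu[0])
    spec.mean("y2", free=False, value=mu[1])
    ll_truth = fiml_loglik(spec, {}, X)
    assert ll >= ll_truth - 1e-6
    assert np.linalg.eigvalsh(Sig_hat).min() > 0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_saturated_fit_has_zero_chisq_and_df():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(60, 3)) + [1.0, 2.0, 3.0]
    spec = _small_spec()
    for estimator in ("ml", "fiml"):
        fit = fit_model(spec, X, estimator=estimator)
        assert fit.df == 0
        assert fit.chisq < 1e-6
        assert fit.converged


def test_equality_constraint_shares_one_estimate():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(200, 2)) * [1.0, 1.3]
    spec = PathModelSpec(["y1", "y2"])
    spec.var("y1", label="v")
    spec.var("y2", label="v")
    spec.mean("y1")
    spec.mean("y2")
    spec.cov("y1", "y2")
    fit = fit_model(spec, X, estimator="ml")
    assert fit.df == 1
    assert len(fit.param_table.loc[fit.param_table["id"] == "v"]) == 1


def test_fiml_equals_ml_chisq_without_missing_data():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(500, 3)) @ np.array([[1, 0.4, 0.2], [0, 1, 0.4], [0, 0, 1.0]])
    spec = PathModelSpec(["y1", "y2", "y3"])
    for v in ("y1", "y2", "y3"):
        spec.var(v)
        spec.mean(v)
    spec.cov("y1", "y2")  # y1~~y3 and y2~~y3 constrained to zero -> df = 2
    f_ml = fit_model(spec, X, estimator="ml", ddof=0)
    f_fi = fit_model(spec, X, estimator="fiml")
    assert f_ml.df == f_fi.df == 2
    assert abs(f_ml.chisq - f_fi.chisq) < 0.01


def test_nested_chisq_monotone_and_difference_test():
    rng = np.random.default_rng(11)
    X = rng.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 1.0]], size=300)
    free = PathModelSpec(["y1", "y2"])
    for v in ("y1", "y2"):
        free.var(v)
        free.mean(v)
    free.cov("y1", "y2")
    constrained = PathModelSpec(["y1", "y2"])
    for v in ("y1", "y2"):
        constrained.var(v)
        constrained.mean(v)
    constrained.cov("y1", "y2", free=False, value=0.0)
    f1 = fit_model(free, X, estimator="ml")
    f0 = fit_model(constrained, X, estimator="ml")
    assert f0.chisq >= f1.chisq - 1e-6
    cmp = chi_square_difference(f0, f1)
    assert cmp.ddf == 1
    assert cmp.dchisq == pytest.approx(f0.chisq - f1.chisq)
    with pytest.raises(ValueError):
        chi_square_difference(f1, f1)


def test_spec_json_roundtrip(tmp_path):
    spec = _small_spec()
    p = tmp_path / "spec.json"
    spec.to_json(p)
    back = PathModelSpec.from_json(p)
    assert back.observed == spec.observed
    assert back.free_param_ids() == spec.free_param_ids()
    assert model_df(back) == model_df(spec)


# ---------------------------------------------------------------------------
# degrees of freedom
# ---------------------------------------------------------------------------


def test_model_df_saturated_three_variables_is_zero():
    assert model_df(_small_spec()) == 0


def test_model_df_matches_bruteforce_on_randomized_specs():
    # build random factor specs while counting distinct free parameters by
    # hand; model_df must agree exactly
    rng = np.random.default_rng(12)
    for trial in range(20):
        p = int(rng.integers(2, 6))
        obs = [f"y{i}" for i in range(p)]
        spec = PathModelSpec(obs, ["eta"])
        spec.var("eta")
        spec.mean("eta", free=False, value=0.0)
        n_free = 1
        for v in obs:
            spec.path("eta", v, free=bool(rng.random() < 0.5))
            n_free += spec.entries[-1].free
            spec.var(v)
            spec.mean(v)
            n_free += 2
        if p >= 3 and rng.random() < 0.5:
            # two covariances tied by one shared label count once
            spec.cov(obs[0], obs[1], label="c")
            spec.cov(obs[1], obs[2], label="c")
            n_free += 1
        moments = p * (p + 3) // 2
        assert model_df(spec) == moments - n_free


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def test_rmsea_zero_when_chisq_below_df():
    idx = fit_indices(10.0, 12, 100.0, 15, 126)
    assert idx.rmsea == 0.0
    lo, hi = rmsea_ci(5.0, 12, 126)
    assert lo == 0.0


def test_cfi_ifi_direct_formula():
    idx = fit_indices(20.0, 10, 100.0, 15, 200)
    assert idx.cfi == pytest.approx(1 - 10 / 85)  # 0.882
    assert idx.ifi == pytest.approx(80 / 90)  # 0.889
    assert idx.ratio == pytest.approx(2.0)


@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_fit_indices_ranges(seed):
    rng = np.random.default_rng(seed)
    df = int(rng.integers(1, 30))
    chisq = float(rng.gamma(df / 2, 2))
    df_b = df + int(rng.integers(1, 10))
    chisq_b = chisq + float(rng.gamma(5, 10))
    idx = fit_indices(chisq, df, chisq_b, df_b, 100)
    assert 0.0 <= idx.cfi <= 1.0
    assert idx.rmsea >= 0.0


def test_rmsea_ci_matches_bisection_oracle():
    rng = np.random.default_rng(13)
    for _ in range(10):
        df = int(rng.integers(2, 40))
        chisq = df * float(rng.uniform(0.8, 3.0))
        n = int(rng.integers(50, 500))
        lo, hi = rmsea_ci(chisq, df, n)

        def bisect(target):
            a, b = 0.0, 1e5
            if stats.chi2.cdf(chisq, df) <= target:
                return None
            for _ in range(200):
                mid = 0.5 * (a + b)
                if stats.ncx2.cdf(chisq, df, mid) > target:
                    a = mid
                else:
                    b = mid
            return 0.5 * (a + b)

        for bound, target in ((lo, 0.95), (hi, 0.05)):
            lam = bisect(target)
            expected = 0.0 if lam is None else np.sqrt(lam / ((n - 1) * df))
            assert bound == pytest.approx(expected, abs=1e-5)


# ---------------------------------------------------------------------------
# multi-group
# ---------------------------------------------------------------------------


def _two_var_spec(label_all=None, group=None):
    spec = PathModelSpec(["y1", "y2"], group=group)
    for v in ("y1", "y2"):
        spec.var(v, label=None if label_all is None else f"{label_all}v{v}")
        spec.mean(v, label=None if label_all is None else f"{label_all}m{v}")
    spec.cov("y1", "y2", label=None if label_all is None else f"{label_all}c")
    return spec


def test_multigroup_duplication_identity():
    rng = np.random.default_rng(14)
    X = rng.multivariate_normal([0, 1], [[1.0, 0.4], [0.4, 2.0]], size=150)
    single = fit_model(_two_var_spec(), X, estimator="ml")
    specs = [_two_var_spec(label_all="s", group="a"), _two_var_spec(label_all="s", group="b")]
    double = fit_multigroup(specs, [X, X.copy()], estimator="ml")
    # shared labels -> same estimates as the single-group fit
    assert double.estimate("sc") == pytest.approx(single.estimate("y1~~y2"), abs=1e-5)
    assert double.estimate("svy1") == pytest.approx(single.estimate("y1~~y1"), abs=1e-5)


def test_multigroup_equality_constraints_raise_df_by_k():
    base = [ _two_var_spec(group="a"), _two_var_spec(group="b") ]
    assert model_df(base) == 0
    # k = 2 cross-group constraints (shared variance labels)
    con = [_two_var_spec(group="a"), _two_var_spec(group="b")]
    for s in con:
        s.entries = [
            e.__class__(e.kind, e.a, e.b, e.free, e.value, "vshare" if (e.kind == "cov" and e.a == e.b == "y1") else e.label)
            for e in s.entries
        ]
    assert model_df(con) == 1
    con2 = [_two_var_spec(label_all="q", group="a"), _two_var_spec(label_all="q", group="b")]
    assert model_df(con2) - model_df(base) == 5


def test_multigroup_empty_group_errors():
    X = np.random.default_rng(15).normal(size=(50, 2))
    with pytest.raises(ValueError, match="empty"):
        fit_multigroup([_two_var_spec(), _two_var_spec()], [X, X[:0]], estimator="ml")
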
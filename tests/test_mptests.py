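"""The four multi-parameter pooled tests against independent oracles."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mipool.errors import InvalidArgument, SingularMatrixError
from mipool.glm import fit_logistic
from mipool.mptests import (
    ChiSquareStack,
    DfPolicy,
    MultiParamEstimates,
    NestedModelPair,
    PValueStack,
    analyse_stack,
    d1_var_pooling,
    d2_chi_pooling,
    d3_meng_rubin,
    mpr_median_p,
    per_imputation_overall_test,
)
from mipool.schema import design_matrix

from conftest import make_small_data

UNBOUNDED = DfPolicy(unbounded=True)


# ---------------------------------------------------------------------------
# independent term-by-term oracles (deliberately naive transcriptions)
# ---------------------------------------------------------------------------

def oracle_d1(thetas, covs, theta0):
    m = len(thetas)
    k = len(thetas[0])
    tb = np.zeros(k)
    for th in thetas:
        tb = tb + np.asarray(th) / m
    Ubar = np.zeros((k, k))
    for U in covs:
        Ubar = Ubar + np.asarray(U) / m
    B = np.zeros((k, k))
    for th in thetas:
        d = np.asarray(th) - tb
        B = B + np.outer(d, d) / (m - 1)
    Uinv = np.linalg.inv(Ubar)
    r1 = (1 + 1 / m) * np.trace(B @ Uinv) / k
    diff = tb - np.asarray(theta0)
    return float(diff @ Uinv @ diff) / (k * (1 + r1)), r1


def oracle_d2(chi2, k):
    m = len(chi2)
    roots = [np.sqrt(c) for c in chi2]
    rbar = sum(roots) / m
    s2 = sum((r - rbar) ** 2 for r in roots) / (m - 1)
    r2 = (1 + 1 / m) * s2
    stat = (sum(chi2) / m / k - (m + 1) / (m - 1) * r2) / (1 + r2)
    return max(stat, 0.0), r2


def oracle_d3_via_statsmodels(y_list, Xf_list, Xr_list):
    """Literal enumeration of the Meng–Rubin construction with statsmodels."""
    m = len(y_list)
    k = Xf_list[0].shape[1] - Xr_list[0].shape[1]
    fits_f = [sm.Logit(y, X).fit(disp=0) for y, X in zip(y_list, Xf_list)]
    fits_r = [sm.Logit(y, X).fit(disp=0) for y, X in zip(y_list, Xr_list)]
    d_L = [2 * (ff.llf - fr.llf) for ff, fr in zip(fits_f, fits_r)]
    bf = np.mean([f.params for f in fits_f], axis=0)
    br = np.mean([f.params for f in fits_r], axis=0)
    d_m = [
        2
        * (
            sm.Logit(y_list[j], Xf_list[j]).loglike(bf)
            - sm.Logit(y_list[j], Xr_list[j]).loglike(br)
        )
        for j in range(m)
    ]
    dL, dm = np.mean(d_L), np.mean(d_m)
    r3 = max((m + 1) / (k * (m - 1)) * (dL - dm), 0.0)
    return dm / (k * (1 + r3)), r3


def random_estimates(rng, m=5, k=3):
    thetas = rng.normal(0, 1, (m, k))
    covs = []
    for _ in range(m):
        A = rng.normal(0, 1, (k, k))
        covs.append(A @ A.T / k + 0.5 * np.eye(k))
    return thetas, np.asarray(covs)


# ---------------------------------------------------------------------------
# D1
# ---------------------------------------------------------------------------

class TestD1:
    def test_null_attained_with_identical_imputations(self, rng):
        th = rng.normal(0, 1, 3)
        cov = np.eye(3) * 0.2
        est = MultiParamEstimates(np.tile(th, (4, 1)), np.tile(cov, (4, 1, 1)))
        res = d1_var_pooling(est, theta0=th)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_identical_imputations_reduce_to_complete_data_wald(self, rng):
        th = np.array([0.8, -0.4, 0.3])
        cov = np.array([[0.05, 0.01, 0.0], [0.01, 0.04, 0.005], [0.0, 0.005, 0.06]])
        est = MultiParamEstimates(np.tile(th, (6, 1)), np.tile(cov, (6, 1, 1)))
        res = d1_var_pooling(est, df_policy=UNBOUNDED)
        wald = float(th @ np.linalg.inv(cov) @ th)
        assert res.statistic == pytest.approx(wald / 3, rel=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(wald, 3), rel=1e-8)

    def test_matches_brute_force_oracle(self, rng):
        thetas, covs = random_estimates(rng, m=5, k=3)
        res = d1_var_pooling(MultiParamEstimates(thetas, covs))
        stat, _ = oracle_d1(list(thetas), list(covs), np.zeros(3))
        assert res.statistic == pytest.approx(stat, rel=1e-10)

    def test_singular_within_covariance_raises(self, rng):
        thetas = rng.normal(0, 1, (4, 2))
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank 1
        with pytest.raises(SingularMatrixError):
            d1_var_pooling(MultiParamEstimates(thetas, np.tile(cov, (4, 1, 1))))

    def test_permutation_invariance(self, rng):
        thetas, covs = random_estimates(rng, m=6, k=2)
        a = d1_var_pooling(MultiParamEstimates(thetas, covs))
        order = rng.permutation(6)
        b = d1_var_pooling(MultiParamEstimates(thetas[order], covs[order]))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)


# ---------------------------------------------------------------------------
# D2
# ---------------------------------------------------------------------------

class TestD2:
    def test_equal_statistics_have_no_between_spread(self):
        res = d2_chi_pooling(ChiSquareStack([7.0, 7.0, 7.0, 7.0], 3),
                             df_policy=UNBOUNDED)
        assert res.statistic == pytest.approx(7.0 / 3)
        assert res.p_value == pytest.approx(stats.chi2.sf(7.0, 3), rel=1e-10)

    def test_all_zero_statistics_give_p_one(self):
        res = d2_chi_pooling(ChiSquareStack([0.0, 0.0, 0.0], 2))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_brute_force_oracle_on_fixed_stack(self):
        chi2 = [3.1, 4.5, 2.2, 6.0, 3.8]
        res = d2_chi_pooling(ChiSquareStack(chi2, 3))
        stat, r2 = oracle_d2(chi2, 3)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        nu = 3 ** (-3 / 5) * 4 * (1 + 1 / r2) ** 2
        assert res.p_value == pytest.approx(float(stats.f.sf(stat, 3, nu)), rel=1e-10)

    def test_matches_oracle_on_many_random_stacks(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 20))
            k = int(rng.integers(1, 6))
            chi2 = rng.chisquare(k, m)
            res = d2_chi_pooling(ChiSquareStack(chi2, k))
            stat, _ = oracle_d2(list(chi2), k)
            assert res.statistic == pytest.approx(stat, rel=1e-10, abs=1e-12)

    def test_single_imputation_rejected(self):
        with pytest.raises(InvalidArgument):
            ChiSquareStack([3.0], 2)


# ---------------------------------------------------------------------------
# D3
# ---------------------------------------------------------------------------

def _nested_pair(rng, m, n=200, identical=False):
    dfs = []
    base = make_small_data(rng, n=n)
    for _ in range(m):
        dfs.append(base.copy() if identical else make_small_data(rng, n=n))
    from mipool.schema import CATEGORICAL, CONTINUOUS, BINARY, ColumnSpec, DataSchema

    schema = DataSchema(
        (
            ColumnSpec("grp", "covariate", CATEGORICAL, ("a", "b", "c")),
            ColumnSpec("x1", "covariate", CONTINUOUS),
            ColumnSpec("x2", "covariate", CONTINUOUS),
            ColumnSpec("y", "outcome", BINARY, (0, 1)),
        )
    )
    return NestedModelPair.from_datasets(dfs, schema, "grp"), dfs, schema


class TestD3:
    def test_identical_datasets_reduce_to_complete_data_lrt(self, rng):
        pair, dfs, schema = _nested_pair(rng, m=3, identical=True)
        res = d3_meng_rubin(pair, df_policy=UNBOUNDED)
        X, y, _ = design_matrix(dfs[0], schema)
        Xr, _, _ = design_matrix(dfs[0], schema, drop=("grp",))
        lrt = 2 * (fit_logistic(X, y).loglik - fit_logistic(Xr, y).loglik)
        assert res.statistic == pytest.approx(lrt / 2, rel=1e-8)
        assert res.p_value == pytest.approx(stats.chi2.sf(lrt, 2), abs=1e-6)

    def test_k1_identical_datasets_match_single_parameter_lrt(self, rng):
        base = make_small_data(rng, n=250)
        from mipool.schema import BINARY, CONTINUOUS, ColumnSpec, DataSchema

        schema = DataSchema(
            (
                ColumnSpec("x1", "covariate", CONTINUOUS),
                ColumnSpec("x2", "covariate", CONTINUOUS),
                ColumnSpec("y", "outcome", BINARY, (0, 1)),
            )
        )
        pair = NestedModelPair.from_datasets([base, base, base], schema, "x1")
        res = d3_meng_rubin(pair, df_policy=UNBOUNDED)
        X, y, _ = design_matrix(base, schema)
        Xr, _, _ = design_matrix(base, schema, drop=("x1",))
        lrt = 2 * (fit_logistic(X, y).loglik - fit_logistic(Xr, y).loglik)
        assert res.p_value == pytest.approx(stats.chi2.sf(lrt, 1), abs=1e-8)

    def test_matches_literal_statsmodels_enumeration(self, rng):
        pair, _, _ = _nested_pair(rng, m=2)
        res = d3_meng_rubin(pair)
        stat, _ = oracle_d3_via_statsmodels(
            list(pair.y), list(pair.X_full), list(pair.X_restricted)
        )
        assert res.statistic == pytest.approx(stat, rel=1e-8)

    def test_restricted_model_must_be_smaller(self, rng):
        pair, dfs, schema = _nested_pair(rng, m=2)
        with pytest.raises(InvalidArgument):
            NestedModelPair(pair.y, pair.X_restricted, pair.X_full)


# ---------------------------------------------------------------------------
# MPR
# ---------------------------------------------------------------------------

class TestMedianPRule:
    def test_odd_m_median(self):
        assert mpr_median_p(PValueStack([0.01, 0.03, 0.05])).p_value == 0.03

    def test_even_m_median_and_strict_rule(self):
        res = mpr_median_p(PValueStack([0.02, 0.04, 0.06, 0.08]), alpha=0.05)
        assert res.p_value == pytest.approx(0.05)
        from mipool.mptests import mpr_rejects

        assert not mpr_rejects(res, alpha=0.05)  # strict inequality

    def test_single_p_is_identity(self):
        assert mpr_median_p(PValueStack([0.7])).p_value == 0.7

    def test_out_of_range_p_rejected(self):
        with pytest.raises(InvalidArgument):
            PValueStack([0.2, 1.4])

    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15),
        idx=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_raising_one_p_never_lowers_the_median(self, ps, idx):
        i = idx.draw(st.integers(0, len(ps) - 1))
        bump = idx.draw(st.floats(0.0, 1.0))
        base = mpr_median_p(PValueStack(ps)).p_value
        raised = list(ps)
        raised[i] = min(1.0, raised[i] + bump)
        assert mpr_median_p(PValueStack(raised)).p_value >= base


# ---------------------------------------------------------------------------
# per-imputation overall test
# ---------------------------------------------------------------------------

class TestPerImputationTest:
    def test_lrt_equals_independent_loglik_summation(self):
        from mipool.io import thirty_row_fixture

        df, schema = thirty_row_fixture()
        chi2, p = per_imputation_overall_test(df, schema, "grp")
        # independent oracle: explicit Bernoulli log-likelihood sums at the
        # statsmodels MLEs of both nested models
        X, y, _ = design_matrix(df, schema)
        Xr, _, _ = design_matrix(df, schema, drop=("grp",))
        bf = sm.Logit(y, X).fit(disp=0).params
        br = sm.Logit(y, Xr).fit(disp=0).params

        def ll(X_, b):
            pr = 1 / (1 + np.exp(-(X_ @ b)))
            return float(np.sum(y * np.log(pr) + (1 - y) * np.log1p(-pr)))

        assert chi2 == pytest.approx(2 * (ll(X, bf) - ll(Xr, br)), rel=1e-8)
        assert p == pytest.approx(stats.chi2.sf(chi2, 2), rel=1e-10)

    def test_zero_column_covariate_gives_p_one(self, rng, small_schema):
        df = make_small_data(rng)
        df["x2"] = 0.0
        chi2, p = per_imputation_overall_test(df, small_schema, "x2")
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_null_pvalues_uniform(self, rng, small_schema):
        """Under a zero coefficient the overall-test p-value is uniform."""
        pvals = []
        for _ in range(500):
            df = make_small_data(rng, n=500, beta_grp=(0.5, -0.5), beta_x=(0.4, 0.0))
            _, p = per_imputation_overall_test(df, small_schema, "x2")
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_wald_and_lrt_agree_asymptotically(self, rng, small_schema):
        df = make_small_data(rng, n=4000)
        c_l, _ = per_imputation_overall_test(df, small_schema, "grp", statistic="lrt")
        c_w, _ = per_imputation_overall_test(df, small_schema, "grp", statistic="wald")
        assert c_l == pytest.approx(c_w, rel=0.1)


# ---------------------------------------------------------------------------
# degenerate stack through the orchestration layer
# ---------------------------------------------------------------------------

def test_identical_stack_reduces_every_method_to_complete_data(rng, small_schema):
    df = make_small_data(rng, n=250)
    datasets = [df.copy() for _ in range(5)]
    res = analyse_stack(datasets, small_schema, ["grp", "x1"], df_policy=UNBOUNDED)

    X, y, info = design_matrix(df, small_schema)
    fit = fit_logistic(X, y)
    Xr, _, _ = design_matrix(df, small_schema, drop=("grp",))
    lrt = 2 * (fit_logistic(X, y).loglik - fit_logistic(Xr, y).loglik)
    sl = info.slices["grp"]
    wald = float(
        fit.beta[sl] @ np.linalg.inv(fit.cov[sl, sl]) @ fit.beta[sl]
    )

    assert res["grp"]["D1"].statistic == pytest.approx(wald / 2, rel=1e-8)
    assert res["grp"]["D2"].statistic == pytest.approx(lrt / 2, rel=1e-8)
    assert res["grp"]["D3"].statistic == pytest.approx(lrt / 2, rel=1e-8)
    assert res["grp"]["D1"].p_value == pytest.approx(stats.chi2.sf(wald, 2), abs=1e-6)
    assert res["grp"]["D2"].p_value == pytest.approx(stats.chi2.sf(lrt, 2), abs=1e-6)
    assert res["grp"]["D3"].p_value == pytest.approx(stats.chi2.sf(lrt, 2), abs=1e-6)
    # MPR reproduces the complete-data p (to solver convergence precision)
    assert res["grp"]["MPR"].p_value == pytest.approx(
        float(stats.chi2.sf(lrt, 2)), rel=1e-12
    )
    # continuous covariate: RR equals complete-data Wald
    w1 = fit.beta[info.slices["x1"].start] ** 2 / fit.cov[
        info.slices["x1"].start, info.slices["x1"].start
    ]
    assert res["x1"]["RR"].p_value == pytest.approx(stats.chi2.sf(w1, 1), abs=1e-10)
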
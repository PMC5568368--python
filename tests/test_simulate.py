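"""Simulation engine: data generation, MAR mechanism, tabulation."""
import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mipool.errors import InvalidArgument
from mipool.simulate import (
    SimulationCondition,
    generate_complete_data,
    induce_mar,
    mc_se,
    quartile_factor,
    run_condition,
    simulation_schema,
)


class TestMcSe:
    def test_paper_scale_values(self):
        assert mc_se(0.05, 1000) == pytest.approx(0.0068920, abs=1e-6)
        assert round(mc_se(0.05, 1000), 3) == 0.007
        assert mc_se(0.5, 1000) == pytest.approx(0.0158114, abs=1e-6)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_proportions(self, p):
        assert mc_se(p, 500) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgument):
            mc_se(1.2, 100)
        with pytest.raises(InvalidArgument):
            mc_se(0.3, 0)


class TestGeneration:
    def test_quartile_cut_gives_near_equal_quarters(self, rng):
        cond = SimulationCondition(n=250, seed=1)
        df, _ = generate_complete_data(cond, rng)
        counts = sorted(df["Factor1"].value_counts().tolist())
        assert counts == [62, 62, 63, 63]

    def test_quartile_codes_are_ordered(self, rng):
        z = rng.standard_normal(1000)
        codes = quartile_factor(z)
        assert set(codes) == {0, 1, 2, 3}
        qs = np.quantile(z, [0.25, 0.5, 0.75])
        assert (z[codes == 0] <= qs[0]).all()
        assert (z[codes == 3] > qs[2]).all()

    def test_latent_correlation_recovered(self, rng):
        cond = SimulationCondition(n=250, correlation=0.4, seed=2)
        # oracle: direct correlated-normal construction via a matrix root —
        # check the continuous covariates' sample correlation over many draws
        total = []
        for _ in range(200):
            df, _ = generate_complete_data(cond, rng)
            Z = df[["Covar1", "Covar2", "Covar3", "Covar4"]].to_numpy()
            C = np.corrcoef(Z, rowvar=False)
            total.append(C[np.triu_indices(4, 1)].mean())
        # correlation estimator SE ~ (1-rho^2)/sqrt(n) per dataset
        se = (1 - 0.4**2) / np.sqrt(250) / np.sqrt(200)
        assert abs(np.mean(total) - 0.4) < 3 * se * 2
    def test_null_condition_outcome_independent_of_covariates(self, rng):
        """With all coefficients zero the full-data factor p-value is uniform."""
        from mipool.simulate import _full_data_pvalues

        schema = simulation_schema()
        cond = SimulationCondition(n=250, beta_continuous=0.0, beta_cat_sd=0.0, seed=3)
        pvals = []
        for _ in range(400):
            df, _ = generate_complete_data(cond, rng)
            pvals.append(_full_data_pvalues(df, schema)["Factor1"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_condition_validation(self):
        with pytest.raises(InvalidArgument):
            SimulationCondition(correlation=1.5)
        with pytest.raises(InvalidArgument):
            SimulationCondition(miss_pct=1.0)
        with pytest.raises(InvalidArgument):
            SimulationCondition(n=10)


class TestInduceMar:
    def test_zero_missingness_is_identity(self, rng):
        df, _ = generate_complete_data(SimulationCondition(seed=4), rng)
        out = induce_mar(df, 0.0, 1)
        assert out.equals(df)

    def test_realized_fraction_matches_target(self, rng):
        cond = SimulationCondition(n=250, seed=5)
        fracs = []
        for i in range(300):
            df, _ = generate_complete_data(cond, rng)
            inc = induce_mar(df, 0.25, int(rng.integers(2**31)))
            fracs.append(inc["Factor1"].isna().mean())
        se = np.sqrt(0.25 * 0.75 / 250) / np.sqrt(300)
        assert abs(np.mean(fracs) - 0.25) < 3 * se

    def test_missingness_depends_on_observed_covariates(self, rng):
        """The configured MAR dependence is recoverable by a logistic fit of
        the missingness indicator on the driving covariates."""
        cond = SimulationCondition(n=250, seed=6)
        rows = []
        for _ in range(60):
            df, _ = generate_complete_data(cond, rng)
            inc = induce_mar(df, 0.25, int(rng.integers(2**31)))
            ind = inc["Covar1"].isna().astype(float).to_numpy()
            rows.append(np.column_stack([ind, df[["Covar2", "Covar3", "Covar4"]]]))
        all_rows = np.vstack(rows)
        X = sm.add_constant(all_rows[:, 1:].mean(axis=1))
        slope = sm.Logit(all_rows[:, 0], X).fit(disp=0).params[1]
        assert slope > 0.5  # positive dependence, as configured


class TestRunCondition:
    def test_single_replication_is_deterministic(self):
        cond = SimulationCondition(n=250, miss_pct=0.25, m=3, reps=1,
                                   iterations=3, seed=77)
        a = run_condition(cond)
        b = run_condition(cond)
        assert a.table.equals(b.table)

    def test_method_subset_respected(self):
        cond = SimulationCondition(n=250, miss_pct=0.25, m=3, reps=2,
                                   iterations=3, seed=78)
        rt = run_condition(cond, ("fulldata", "MPR_out"))
        assert set(rt.table["method"]) == {"fulldata", "MPR_out"}

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidArgument):
            run_condition(SimulationCondition(reps=1), ("nonsense",))

    def test_rates_are_exact_count_ratios(self):
        cond = SimulationCondition(n=250, miss_pct=0.25, m=3, reps=5,
                                   iterations=3, seed=79)
        rt = run_condition(cond, ("fulldata", "RR", "MPR_out"))
        for row in rt.table.itertuples():
            assert (row.rejection_rate * row.reps_effective) == pytest.approx(
                round(row.rejection_rate * row.reps_effective)
            )
            assert row.mc_se == pytest.approx(
                mc_se(row.rejection_rate, row.reps_effective)
            )

    def test_no_missingness_pooled_p_equals_full_data(self):
        """With miss_pct = 0 the stacks are m identical copies, so every
        Wald-route pooled p matches the full-data Wald p and every LRT-route
        p matches the full-data LRT p, replication by replication."""
        cond = SimulationCondition(n=250, miss_pct=0.0, m=3, reps=3,
                                   iterations=3, seed=80)
        rt = run_condition(cond, collect_pvalues=True)
        pv = rt.pvalues
        for v in ("Covar1", "Covar2"):
            np.testing.assert_allclose(
                pv[(v, "RR")], pv[(v, "fulldata")], atol=1e-10
            )
            np.testing.assert_allclose(
                pv[(v, "D1")], pv[(v, "fulldata")], atol=1e-6
            )
        np.testing.assert_allclose(
            pv[("Factor1", "D3")], pv[("Factor1", "fulldata")], atol=1e-6
        )
        np.testing.assert_allclose(
            pv[("Factor1", "MPR_in")], pv[("Factor1", "fulldata")], atol=1e-10
        )
        np.testing.assert_allclose(
            pv[("Factor1", "MPR_out")], pv[("Factor1", "fulldata")], atol=1e-10
        )

    def test_fulldata_power_increases_with_effect_size(self):
        weak = SimulationCondition(n=250, beta_continuous=0.1, miss_pct=0.0,
                                   m=1, reps=200, iterations=1, seed=81)
        strong = SimulationCondition(n=250, beta_continuous=1.0, miss_pct=0.0,
                                     m=1, reps=200, iterations=1, seed=81)
        pw = run_condition(weak, ("fulldata",)).rate("Covar2", "fulldata")
        ps = run_condition(strong, ("fulldata",)).rate("Covar2", "fulldata")
        assert ps > pw

    def test_full_profile_parameters_accepted(self):
        # the full study scale must be representable even though it is not
        # run here: 4 correlations x 11 coefficient settings x 2 missingness
        conds = [
            SimulationCondition.from_beta(
                b, n=250, correlation=c, miss_pct=ms, m=100, reps=1000, seed=1
            )
            for c in (0.2, 0.4, 0.6, 0.8)
            for b in np.round(np.arange(0.0, 1.01, 0.1), 1)
            for ms in (0.25, 0.40)
        ]
        assert len(conds) == 88
        assert all(c.m == 100 and c.reps == 1000 for c in conds)
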
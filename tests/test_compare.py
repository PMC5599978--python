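import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nutriqg import (McmcSettings, angle_posterior, partial_f,
                     sequential_f_tests, simulate_nochoice, vector_angle,
                     z_standardize)
from nutriqg import reference
from nutriqg.mcmc import ANGLE_PUBLISHED_SETTINGS
from nutriqg.synthetic import surface_spec

finite2 = st.tuples(st.floats(-10, 10), st.floats(-10, 10)).filter(
    lambda v: np.hypot(*v) > 1e-3)


class TestPartialF:
    @pytest.mark.parametrize(
        "ss_r, ss_c, df1, df2, expected",
        [
            (272.22, 199.81, 2, 424, 76.83),
            (190.38, 189.46, 1, 418, 2.03),
            (253.60, 243.44, 2, 424, 8.85),
        ],
    )
    def test_published_components_reproduce_f(self, ss_r, ss_c, df1, df2,
                                              expected):
        F, p = partial_f(ss_r, ss_c, df1, df2)
        assert round(F, 2) == expected
        assert 0 <= p <= 1

    def test_equal_sums_of_squares(self):
        F, p = partial_f(5.0, 5.0, 2, 100)
        assert F == 0.0 and p == 1.0

    def test_zero_complete_rss_flagged_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            F, p = partial_f(3.0, 0.0, 1, 10)
        assert np.isinf(F) and p == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            partial_f(1.0, 2.0, 1, 10)
        with pytest.raises(ValueError):
            partial_f(2.0, 1.0, 0, 10)


class TestVectorAngle:
    def test_aligned_orthogonal_and_published(self):
        # arccos loses ~1e-8 rad of precision at cos = 1, i.e. ~1e-5 degrees
        assert vector_angle((1, 1), (2, 2)) == pytest.approx(0.0, abs=1e-5)
        assert vector_angle((1, 0), (0, 1)) == pytest.approx(90.0)
        # plug-in from the printed coefficients; the published posterior-mean
        # angle is 25.99
        theta = vector_angle(reference.linear_vector("female", "lifespan"),
                             reference.linear_vector("male", "lifespan"))
        assert theta == pytest.approx(25.99, abs=0.06)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            vector_angle((0, 0), (1, 1))

    @settings(deadline=None, derandomize=True)
    @given(a=finite2, b=finite2, c=st.floats(1e-3, 1e3))
    def test_symmetry_and_scale_invariance(self, a, b, c):
        t1 = vector_angle(a, b)
        assert t1 == pytest.approx(vector_angle(b, a), abs=1e-9)
        assert t1 == pytest.approx(vector_angle(np.multiply(c, a), b), abs=1e-5)
        assert 0 <= t1 <= 180


def _two_group_data(beta_a, beta_b, quad_a=(0, 0), quad_b=(0, 0),
                    corr_a=0.0, corr_b=0.0, noise=0.9, seed=0, n_per=10):
    specs = {("female", "y"): surface_spec(beta_a, quad_a, corr_a, noise),
             ("male", "y"): surface_spec(beta_b, quad_b, corr_b, noise)}
    raw = simulate_nochoice(specs, n_per_diet_per_sex=n_per, seed=seed)
    fem = z_standardize(raw[raw["sex"] == "female"], group_by=None).data
    mal = z_standardize(raw[raw["sex"] == "male"], group_by=None).data
    return fem, mal


class TestSequential:
    def test_df_pattern_matches_published_design(self):
        """With n = 222 + 208 pooled rows the tier error dfs are 424, 420,
        418 — the published bookkeeping."""
        rng = np.random.default_rng(1)

        def tab(n):
            return pd.DataFrame({"p_intake": rng.standard_normal(n),
                                 "c_intake": rng.standard_normal(n),
                                 "y": rng.standard_normal(n)})

        seq = sequential_f_tests(tab(222), tab(208), "y")
        assert seq.tiers["linear"]["df2"] == 424
        assert seq.tiers["quadratic"]["df2"] == 420
        assert seq.tiers["correlational"]["df2"] == 418
        assert seq.tiers["linear"]["df1"] == 2
        assert seq.tiers["correlational"]["df1"] == 1

    def test_matches_statsmodels_nested_anova(self):
        """Tier partial F agrees with an independent nested-model ANOVA."""
        import statsmodels.api as sm

        fem, mal = _two_group_data((0.2, 0.5), (0.5, 0.2), seed=3)
        seq = sequential_f_tests(fem, mal, "y")
        y = np.concatenate([fem["y"], mal["y"]])
        P = np.concatenate([fem["p_intake"], mal["p_intake"]])
        C = np.concatenate([fem["c_intake"], mal["c_intake"]])
        g = np.concatenate([np.zeros(len(fem)), np.ones(len(mal))])
        Xr = np.column_stack([np.ones_like(y), g, P, C])
        Xc = np.column_stack([Xr, g * P, g * C])
        red = sm.OLS(y, Xr).fit()
        com = sm.OLS(y, Xc).fit()
        table = com.compare_f_test(red)
        assert seq.tiers["linear"]["F"] == pytest.approx(table[0], abs=1e-8)
        assert seq.tiers["linear"]["p"] == pytest.approx(table[1], abs=1e-10)

    def test_correlational_difference_detected(self):
        fem, mal = _two_group_data((0.3, 0.3), (0.3, 0.3),
                                   quad_a=(-0.2, -0.2), quad_b=(-0.2, -0.2),
                                   corr_a=0.4, corr_b=-0.4, noise=0.5, seed=5)
        seq = sequential_f_tests(fem, mal, "y")
        assert seq.tiers["correlational"]["p"] < 0.01

    def test_linear_difference_followups_name_nutrient(self):
        fem, mal = _two_group_data((0.8, 0.3), (-0.3, 0.3), noise=0.4, seed=6)
        seq = sequential_f_tests(fem, mal, "y")
        lin = seq.tiers["linear"]
        assert lin["p"] < 0.01
        assert lin["followups"]["P"]["p"] < 0.01

    def test_identical_membership_rejected(self):
        fem, _ = _two_group_data((0.2, 0.5), (0.2, 0.5), seed=7)
        with pytest.raises(ValueError, match="identical"):
            sequential_f_tests(fem, fem.copy(), "y")

    def test_null_p_values_uniform(self):
        """Under a shared surface the tier-1 p-values are U(0,1)
        (Kolmogorov-Smirnov at alpha = 0.01 over 300 replicates)."""
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(300):
            n = 60
            mk = lambda: pd.DataFrame({
                "p_intake": rng.standard_normal(n),
                "c_intake": rng.standard_normal(n),
                "y": rng.standard_normal(n)})
            seq = sequential_f_tests(mk(), mk(), "y")
            pvals.append(seq.tiers["linear"]["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestAnglePosterior:
    def test_draw_count_arithmetic(self, linear_surface_data):
        _, std = linear_surface_data
        fem = std.data[std.data["sex"] == "female"]
        mal = std.data[std.data["sex"] == "male"]
        s = McmcSettings(iterations=4000, burn_in=500, thin=7, seed=2)
        est = angle_posterior(fem, mal, "lifespan", s)
        assert est.n_draws == (4000 - 500) // 7

    def test_published_settings_retain_15200_draws(self):
        assert ANGLE_PUBLISHED_SETTINGS.n_draws == 15200

    def test_too_few_draws_rejected(self, linear_surface_data):
        _, std = linear_surface_data
        fem = std.data[std.data["sex"] == "female"]
        mal = std.data[std.data["sex"] == "male"]
        with pytest.raises(ValueError, match="100"):
            angle_posterior(fem, mal, "lifespan",
                            McmcSettings(iterations=300, burn_in=100, thin=3))

    def test_noiseless_posterior_collapses_to_plugin(self):
        """In the zero-residual-variance limit (and with the prior scale
        taken to zero with it) the angle posterior collapses to the plug-in
        estimate."""
        fem, mal = _two_group_data((0.2, 0.6), (0.6, 0.2), noise=1e-7, seed=4)
        est = angle_posterior(fem, mal, "y",
                              McmcSettings(iterations=3000, burn_in=500,
                                           thin=5, seed=3, prior_v=1e-10))
        assert abs(est.theta_posterior_mean - est.theta_plugin) < 0.01
        assert est.hpd95[1] - est.hpd95[0] < 0.01

    def test_hpd_covers_generating_angle(self):
        """95% HPD covers the generating angle at near-nominal frequency."""
        rng = np.random.default_rng(21)
        beta_a, beta_b = np.array([0.2, 0.6]), np.array([0.6, 0.3])
        truth = vector_angle(beta_a, beta_b)
        hits = 0
        reps = 100
        for r in range(reps):
            n = 80
            X = rng.standard_normal((n, 2))
            da = pd.DataFrame({"p_intake": X[:, 0], "c_intake": X[:, 1],
                               "y": X @ beta_a + rng.standard_normal(n)})
            X2 = rng.standard_normal((n, 2))
            db = pd.DataFrame({"p_intake": X2[:, 0], "c_intake": X2[:, 1],
                               "y": X2 @ beta_b + rng.standard_normal(n)})
            est = angle_posterior(da, db, "y",
                                  McmcSettings(iterations=2500, burn_in=500,
                                               thin=4, seed=r))
            hits += est.hpd95[0] <= truth <= est.hpd95[1]
        assert hits / reps >= 0.88

    def test_seed_reproducibility(self, linear_surface_data):
        _, std = linear_surface_data
        fem = std.data[std.data["sex"] == "female"]
        mal = std.data[std.data["sex"] == "male"]
        s = McmcSettings(iterations=2000, burn_in=200, thin=4, seed=11)
        a = angle_posterior(fem, mal, "lifespan", s)
        b = angle_posterior(fem, mal, "lifespan", s)
        assert np.array_equal(a.theta_draws, b.theta_draws)
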
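import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nutriqg import (compute_rip, diet_preference, fit_landscape,
                     manova_intake, overlay_rip, rip_sex_test,
                     simulate_outbred_choice)
from nutriqg.choice import RegulatedIntakePoint
from nutriqg.reference import RIP_MEAN


def _choice_table(n_per_cell=6, seed=0, sex_shift=(0.0, 0.0),
                  pair_shift=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for sex_i, sex in enumerate(("female", "male")):
        for pr in range(1, 5):
            for k in range(n_per_cell):
                p = 200 + sex_i * sex_shift[0] + pr * pair_shift \
                    + rng.normal(0, 20)
                c = 500 + sex_i * sex_shift[1] + pr * pair_shift \
                    + rng.normal(0, 30)
                rows.append({"individual_id": f"{sex}{pr}{k}", "sex": sex,
                             "design_cell": f"pair{pr}",
                             "p_intake": p, "c_intake": c,
                             "consumed_high_p": p * 2, "consumed_high_c": c})
    return pd.DataFrame(rows)


class TestDietPreference:
    def test_identical_consumption_is_exact_tie(self):
        tab = _choice_table()
        tab["consumed_high_c"] = tab["consumed_high_p"]
        out = diet_preference(tab)
        assert (out["t"] == 0).all() and (out["p"] == 1).all()
        assert out["tie"].all()

    def test_constant_nonzero_difference_flagged_certain(self):
        tab = _choice_table()
        tab["consumed_high_c"] = tab["consumed_high_p"] + 5.0
        out = diet_preference(tab)
        assert np.isinf(out["t"]).all() and (out["p"] == 0).all()
        assert out["tie"].all()

    def test_t_grows_with_sqrt_n(self):
        """For a fixed mean difference and SD, t = dbar / (s / sqrt(n))."""
        rng = np.random.default_rng(1)
        diffs = rng.normal(3.0, 4.0, size=400)

        def t_at(n):
            d = diffs[:n]
            tab = pd.DataFrame({
                "sex": "female", "design_cell": "pair1",
                "consumed_high_p": np.zeros(n), "consumed_high_c": d})
            row = diet_preference(tab).iloc[0]
            # closed form
            assert row["t"] == pytest.approx(
                d.mean() / (d.std(ddof=1) / np.sqrt(n)), abs=1e-10)
            return row["t"]

        assert t_at(400) > 1.6 * t_at(100)

    def test_simulated_c_preference_power(self):
        """The default generator's C-biased regulation yields a significant
        high-C preference in essentially every pair at n = 30."""
        hits = total = 0
        for seed in range(5):
            out = diet_preference(simulate_outbred_choice(seed=seed))
            hits += (out["p"] < 0.05).sum()
            total += len(out)
        assert hits / total >= 0.95

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="consumed_high_p"):
            diet_preference(pd.DataFrame({"sex": [], "design_cell": []}))


class TestManova:
    def test_single_response_reduces_to_univariate_f(self):
        tab = _choice_table(seed=3, sex_shift=(30, 0), pair_shift=5)
        res = manova_intake(tab, responses=("p_intake",))
        uni = res.univariate
        for term in ("sex", "diet_pair", "sex:diet_pair"):
            urow = uni[(uni["term"] == term) & (uni["nutrient"] == "p_intake")]
            assert res.terms[term]["F"] == pytest.approx(
                float(urow["F"].iloc[0]), abs=1e-8)

    def test_matches_statsmodels_manova(self):
        """Pillai's trace and its approximate F per term agree with the
        independent statsmodels multivariate test."""
        from statsmodels.multivariate.manova import MANOVA

        tab = _choice_table(seed=4, sex_shift=(40, -20), pair_shift=8)
        res = manova_intake(tab, follow_up=False)
        mv = MANOVA.from_formula(
            "p_intake + c_intake ~ C(sex, Sum) * C(design_cell, Sum)",
            data=tab).mv_test()
        for term, sm_name in (("sex", "C(sex, Sum)"),
                              ("diet_pair", "C(design_cell, Sum)"),
                              ("sex:diet_pair",
                               "C(sex, Sum):C(design_cell, Sum)")):
            sm_tab = mv.results[sm_name]["stat"]
            assert res.terms[term]["pillai"] == pytest.approx(
                float(sm_tab.loc["Pillai's trace", "Value"]), abs=1e-8)
            assert res.terms[term]["F"] == pytest.approx(
                float(sm_tab.loc["Pillai's trace", "F Value"]), rel=1e-6)

    def test_pillai_matches_eigenvalue_oracle(self):
        """Pillai = sum(lambda_i / (1 + lambda_i)) over eigenvalues of
        E^-1 H, computed by brute force."""
        tab = _choice_table(n_per_cell=3, seed=5, sex_shift=(25, 10))
        res = manova_intake(tab, follow_up=False)
        # brute-force H and E for the sex term via explicit nested fits
        # (deviation coding written out by hand, independent of the package)
        Y = tab[["p_intake", "c_intake"]].to_numpy()
        sex = (tab["sex"] == "female").to_numpy(float) \
            - (tab["sex"] == "male").to_numpy(float)
        pair_levels = sorted(tab["design_cell"].unique())
        pair_cols = [
            (tab["design_cell"] == lev).to_numpy(float)
            - (tab["design_cell"] == pair_levels[-1]).to_numpy(float)
            for lev in pair_levels[:-1]]
        one = np.ones(len(tab))
        inter = [sex * pc for pc in pair_cols]
        Xf = np.column_stack([one, sex] + pair_cols + inter)
        Xr = np.column_stack([one] + pair_cols + inter)

        def rss(X):
            b, *_ = np.linalg.lstsq(X, Y, rcond=None)
            R = Y - X @ b
            return R.T @ R

        E = rss(Xf)
        H = rss(Xr) - E
        lam = np.linalg.eigvals(np.linalg.inv(E) @ H).real
        assert res.terms["sex"]["pillai"] == pytest.approx(
            float(np.sum(lam / (1 + lam))), abs=1e-8)

    def test_pillai_affine_invariance(self):
        tab = _choice_table(seed=6, sex_shift=(30, 15), pair_shift=4)
        res1 = manova_intake(tab, follow_up=False)
        M = np.array([[2.0, 0.5], [-1.0, 3.0]])
        Y2 = tab[["p_intake", "c_intake"]].to_numpy() @ M.T + [10, -5]
        tab2 = tab.copy()
        tab2[["p_intake", "c_intake"]] = Y2
        res2 = manova_intake(tab2, follow_up=False)
        for term in res1.terms:
            assert res1.terms[term]["pillai"] == pytest.approx(
                res2.terms[term]["pillai"], abs=1e-8)

    def test_empty_cell_rejected(self):
        tab = _choice_table()
        tab = tab[~((tab["sex"] == "male") & (tab["design_cell"] == "pair2"))]
        with pytest.raises(ValueError, match="pair2"):
            manova_intake(tab)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(17)
        rej = {"sex": 0, "diet_pair": 0, "sex:diet_pair": 0}
        reps = 400
        for r in range(reps):
            tab = _choice_table(n_per_cell=5, seed=10_000 + r)
            res = manova_intake(tab, follow_up=False)
            for term in rej:
                rej[term] += res.terms[term]["p"] < 0.05
        for term, count in rej.items():
            assert 0.02 <= count / reps <= 0.08, term

    def test_lsd_ordering_resolves_strong_pair_differences(self):
        tab = _choice_table(n_per_cell=25, seed=8, pair_shift=40.0)
        res = manova_intake(tab)
        order = res.lsd[("female", "p_intake")]
        assert order.startswith("pair1") and order.endswith("pair4")
        assert "<" in order


class TestRip:
    def test_published_means_give_published_ratios(self):
        for sex, printed_ratio in (("female", 2.20), ("male", 3.23)):
            p, c = RIP_MEAN[sex]
            rip = RegulatedIntakePoint(sex=sex, mean_p=p, se_p=1.0,
                                       mean_c=c, se_c=1.0, n=120)
            assert round(rip.pc_ratio, 2) == printed_ratio
            assert rip.ratio_string == f"1P:{printed_ratio:.2f}C"

    def test_degenerate_point(self):
        tab = pd.DataFrame({"sex": "female", "design_cell":
                            ["pair1", "pair1", "pair2", "pair2"],
                            "p_intake": 100.0, "c_intake": 100.0,
                            "individual_id": list("abcd")})
        tab.loc[0, "p_intake"] = 100.0
        rip = compute_rip(tab, "female")
        assert rip.mean_p == pytest.approx(100.0)
        assert rip.pc_ratio == pytest.approx(1.0)

    def test_balanced_pooled_equals_pair_mean_average(self, choice_data):
        rip = compute_rip(choice_data, "female")
        sub = choice_data[choice_data["sex"] == "female"]
        assert rip.mean_p == pytest.approx(sub["p_intake"].mean(), rel=1e-12)

    def test_unbalanced_uses_pair_means(self):
        tab = pd.DataFrame({
            "sex": "female",
            "design_cell": ["pair1"] * 3 + ["pair2"] * 1,
            "p_intake": [10.0, 10.0, 10.0, 50.0],
            "c_intake": [1.0] * 4,
            "individual_id": list("abcd")})
        rip = compute_rip(tab, "female")
        assert rip.mean_p == pytest.approx(30.0)  # (10 + 50) / 2, not 20

    def test_missing_sex_rejected(self, choice_data):
        with pytest.raises(ValueError, match="no records"):
            compute_rip(choice_data, "hermaphrodite")


class TestRipSexTest:
    def test_interaction_power_at_study_scale(self):
        hits = 0
        for seed in range(10):
            tab = simulate_outbred_choice(seed=100 + seed)
            res = rip_sex_test(tab)
            hits += res.loc[res["term"] == "sex:p_intake", "p"].iloc[0] < 0.05
        assert hits >= 9

    def test_intercept_shift_hits_sex_term_not_interaction(self):
        rng = np.random.default_rng(2)
        rows = []
        for sex_i, sex in enumerate(("female", "male")):
            p = rng.uniform(100, 300, 150)
            c = 2.0 * p + 100 + 120 * sex_i + rng.normal(0, 25, 150)
            for j in range(150):
                rows.append({"sex": sex, "design_cell": f"pair{j % 4 + 1}",
                             "p_intake": p[j], "c_intake": c[j]})
        res = rip_sex_test(pd.DataFrame(rows))
        assert res.loc[res["term"] == "sex", "p"].iloc[0] < 0.001
        assert res.loc[res["term"] == "sex:p_intake", "p"].iloc[0] > 0.01

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        rej = 0
        reps = 300
        for _ in range(reps):
            p = rng.uniform(100, 300, 60)
            c = 2.0 * p + rng.normal(0, 30, 60)
            tab = pd.DataFrame({
                "sex": np.repeat(["female", "male"], 30),
                "design_cell": "pair1", "p_intake": p, "c_intake": c})
            res = rip_sex_test(tab)
            rej += res.loc[res["term"] == "sex:p_intake", "p"].iloc[0] < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_degenerate_inputs_rejected(self):
        tab = pd.DataFrame({"sex": ["female"] * 5 + ["male"] * 5,
                            "p_intake": [1.0] * 5 + [1, 2, 3, 4, 5],
                            "c_intake": range(10)})
        with pytest.raises(ValueError, match="zero variance"):
            rip_sex_test(tab)


class TestOverlay:
    def _landscape(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 10, size=(150, 2))
        y = -(X[:, 0] - 6.0) ** 2 - (X[:, 1] - 4.0) ** 2
        df = pd.DataFrame({"sex": "female", "p_intake": X[:, 0],
                           "c_intake": X[:, 1], "lifespan": y})
        return fit_landscape(df, "lifespan", smoothing=1e-6, n_grid=60)

    def test_rip_at_peak_has_zero_distance(self):
        grid = self._landscape()
        p, c, _ = grid.peak()
        rip = RegulatedIntakePoint("female", p, 0.1, c, 0.1, 10)
        out = overlay_rip(rip, grid)
        assert out["distance_to_peak"] == 0.0
        assert not out["extrapolated"]

    def test_peak_near_analytic_optimum_and_distance_arithmetic(self):
        grid = self._landscape()
        p, c, _ = grid.peak()
        cell = np.diff(grid.p_grid)[0]
        assert abs(p - 6.0) <= 2 * cell and abs(c - 4.0) <= 2 * cell
        rip = RegulatedIntakePoint("female", 3.0, 0.1, 4.0, 0.1, 10)
        out = overlay_rip(rip, grid)
        assert out["distance_to_peak"] == pytest.approx(
            np.hypot(3.0 - p, 4.0 - c))

    def test_extrapolated_rip_reported_not_evaluated(self):
        grid = self._landscape()
        rip = RegulatedIntakePoint("female", 500.0, 0.1, 500.0, 0.1, 10)
        out = overlay_rip(rip, grid)
        assert out["extrapolated"] and np.isnan(out["value_at_rip"])
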
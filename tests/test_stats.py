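import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from brainmass import (
    association,
    group_compare,
    make_region_table,
    median_j,
    residualize_to_z,
    size_correct_j,
)


class TestMedianJ:
    def test_patient_medians(self):
        rt = make_region_table(list("abcd"), [1, 1, 1, 1], [True, True, False, False])
        s = median_j(np.array([1.0, 2, 3, 4]), rt, group="GLI")
        assert (s.j_tumor, s.j_nontumor, s.j_brain) == (1.5, 3.5, 2.5)

    def test_control_nontumor_equals_brain(self):
        rt = make_region_table(list("abc"), [1, 1, 1])
        s = median_j(np.array([1.0, 2, 3]), rt, group="CON")
        assert s.j_brain == s.j_nontumor == 2.0
        assert s.j_tumor is None

    def test_all_equal(self):
        rt = make_region_table(list("abc"), [1, 1, 1], [True, False, False])
        s = median_j(np.array([2.0, 2, 2]), rt, group="MEN")
        assert s.j_brain == s.j_tumor == s.j_nontumor == 2.0

    def test_patient_without_tumor_flags_rejected(self):
        rt = make_region_table(list("abc"), [1, 1, 1])
        with pytest.raises(ValueError, match="no tumor-flagged"):
            median_j(np.array([1.0, 2, 3]), rt, group="GLI")

    def test_control_with_tumor_flags_rejected(self):
        rt = make_region_table(list("abc"), [1, 1, 1], [True, False, False])
        with pytest.raises(ValueError):
            median_j(np.array([1.0, 2, 3]), rt, group="CON")


class TestSizeCorrectJ:
    def test_exactly_linear_gives_zero_residuals(self):
        sizes = np.array([100.0, 200, 300, 400])
        j = 0.5 + 0.001 * sizes
        np.testing.assert_allclose(size_correct_j(j, sizes), 0.0, atol=1e-12)

    def test_orthogonal_size_gives_centered_j(self):
        sizes = np.array([1.0, 2, 1, 2])
        j = np.array([5.0, 5, 7, 7])  # uncorrelated with size
        np.testing.assert_allclose(size_correct_j(j, sizes), j - j.mean())

    def test_matches_normal_equations_oracle(self, rng):
        sizes = rng.uniform(500, 3000, 30)
        j = rng.uniform(0.5, 3.0, 30)
        X = np.column_stack([np.ones(30), sizes])
        beta = np.linalg.solve(X.T @ X, X.T @ j)
        np.testing.assert_allclose(size_correct_j(j, sizes), j - X @ beta,
                                   atol=1e-10)

    def test_per_subject_grouping_removes_subject_offsets(self, rng):
        sizes = np.tile(rng.uniform(500, 3000, 10), 2)
        j = np.r_[rng.uniform(1, 2, 10), rng.uniform(3, 4, 10)]
        ids = np.r_[np.zeros(10), np.ones(10)]
        res = size_correct_j(j, sizes, subject_ids=ids)
        assert abs(res[:10].mean()) < 1e-10
        assert abs(res[10:].mean()) < 1e-10

    def test_zero_variance_sizes_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            size_correct_j(np.array([1.0, 2, 3]), np.array([5.0, 5, 5]))


class TestResidualizeToZ:
    def test_controls_standardized_by_construction(self, rng):
        n = 40
        cov = pd.DataFrame({"age": rng.uniform(20, 80, n),
                            "sex": rng.integers(0, 2, n)})
        y = 0.1 * cov["age"].to_numpy() + rng.standard_normal(n)
        mask = np.zeros(n, bool)
        mask[:15] = True
        z = residualize_to_z(y, cov, mask)
        assert z[mask].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[mask].std(ddof=1) == pytest.approx(1.0)

    def test_outcome_translation_invariance(self, rng):
        # shifting every outcome by a constant is absorbed by the intercept
        n = 12
        cov = pd.DataFrame({"x": rng.standard_normal(n)})
        y = rng.standard_normal(n)
        mask = np.arange(n) < 5
        z1 = residualize_to_z(y, cov, mask)
        z2 = residualize_to_z(y + 100.0, cov, mask)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_matches_hand_ols_oracle(self):
        y = np.array([2.0, 3.5, 3.0, 5.0, 4.5, 6.0])
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        mask = np.array([True, True, True, False, False, False])
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        expected = (resid - resid[mask].mean()) / resid[mask].std(ddof=1)
        z = residualize_to_z(y, pd.DataFrame({"x": x}), mask)
        np.testing.assert_allclose(z, expected, atol=1e-10)

    def test_affine_covariate_rescaling_invariance(self, rng):
        n = 25
        cov = pd.DataFrame({"a": rng.standard_normal(n)})
        y = rng.standard_normal(n)
        mask = np.zeros(n, bool)
        mask[:8] = True
        z1 = residualize_to_z(y, cov, mask)
        z2 = residualize_to_z(y, cov * 100 + 7, mask)
        np.testing.assert_allclose(z1, z2, atol=1e-8)

    def test_collinear_design_rejected(self, rng):
        n = 20
        a = rng.standard_normal(n)
        cov = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize_to_z(rng.standard_normal(n), cov, np.arange(n) < 5)


class TestGroupCompare:
    def test_identical_groups_f_zero(self):
        vals = np.r_[[1.0, 2, 3, 4], [1.0, 2, 3, 4]]
        groups = np.r_[["a"] * 4, ["b"] * 4]
        rep = group_compare(vals, groups, family="anova")
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)

    def test_anova_matches_sum_of_squares_oracle(self):
        g1 = np.array([6.0, 8, 4, 5, 3, 4])
        g2 = np.array([8.0, 12, 9, 11, 6, 8])
        g3 = np.array([13.0, 9, 11, 8, 7, 12])
        vals = np.r_[g1, g2, g3]
        groups = np.r_[["a"] * 6, ["b"] * 6, ["c"] * 6]
        grand = vals.mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in (g1, g2, g3))
        ss_w = sum(((g - g.mean()) ** 2).sum() for g in (g1, g2, g3))
        f_oracle = (ss_b / 2) / (ss_w / 15)
        rep = group_compare(vals, groups, family="anova")
        assert rep.statistic == pytest.approx(f_oracle, abs=1e-10)
        assert rep.df == (2, 15)
        assert rep.posthoc is not None and len(rep.posthoc) == 3

    def test_levene_zero_for_identical_groups(self):
        vals = np.r_[[1.0, 5, 2, 4], [1.0, 5, 2, 4]]
        groups = np.r_[["a"] * 4, ["b"] * 4]
        rep = group_compare(vals, groups, family="levene")
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)

    def test_auto_picks_kruskal_for_skewed_data(self, rng):
        vals = np.r_[rng.lognormal(0, 2, 30), rng.lognormal(0.5, 2, 30)]
        groups = np.r_[["a"] * 30, ["b"] * 30]
        rep = group_compare(vals, groups, family="auto")
        assert rep.family == "kruskal"

    def test_auto_picks_anova_for_normal_data(self, rng):
        vals = np.r_[rng.standard_normal(30), rng.standard_normal(30) + 0.5]
        groups = np.r_[["a"] * 30, ["b"] * 30]
        rep = group_compare(vals, groups, family="auto")
        assert rep.family == "anova"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))

    def test_null_type_one_error_rate(self):
        # under H0 the ANOVA p-value should be uniform: empirical alpha near 0.05
        rng = np.random.default_rng(1234)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            vals = rng.standard_normal(30)
            groups = np.repeat(["a", "b", "c"], 10)
            rep = group_compare(vals, groups, family="anova")
            rejections += rep.p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.08


class TestAssociation:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = association(2 * x, x)
        assert res["slope"] == pytest.approx(2.0)
        assert res["eta_squared"] == pytest.approx(1.0)

    def test_orthogonal_predictor(self):
        x = np.array([1.0, -1, 1, -1, 1, -1])
        y = np.array([1.0, 1, 2, 2, 3, 3])
        assert abs(x @ (y - y.mean())) < 1e-12
        res = association(y, x)
        assert res["slope"] == pytest.approx(0.0, abs=1e-12)
        assert res["eta_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_t_matches_simple_regression_closed_form(self, rng):
        n = 20
        x = rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        r = np.corrcoef(x, y)[0, 1]
        t_oracle = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        res = association(y, x)
        assert res["t"] == pytest.approx(t_oracle, abs=1e-8)
        assert res["eta_squared"] == pytest.approx(r**2, abs=1e-10)

    def test_covariate_adjustment(self, rng):
        n = 50
        c = rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = 3.0 * c + 0.0 * x + 0.1 * rng.standard_normal(n)
        res = association(y, x, covariates=pd.DataFrame({"c": c}))
        assert abs(res["slope"]) < 0.1
        assert res["eta_squared"] < 0.05

    def test_collinear_rejected(self, rng):
        x = rng.standard_normal(10)
        with pytest.raises(ValueError, match="collinear"):
            association(rng.standard_normal(10), x,
                        covariates=pd.DataFrame({"c": 2 * x}))
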
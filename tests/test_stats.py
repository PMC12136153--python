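import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from specsense import (
    anova_tukey,
    fit_linear_mixed,
    kde_mode_count,
    proportion_with_sem,
    ttest_vs_expected,
)


class TestProportion:
    def test_degenerate_zero_count(self):
        gp = proportion_with_sem(0, 20)
        assert gp.percent == 0.0
        assert gp.percent_sem == 0.0

    def test_invariants(self):
        gp = proportion_with_sem(34, 48)
        assert gp.p_hat == pytest.approx(34 / 48)
        assert gp.sem == pytest.approx(np.sqrt(gp.p_hat * (1 - gp.p_hat) / 48))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_with_sem(5, 0)
        with pytest.raises(ValueError):
            proportion_with_sem(10, 5)


class TestTTest:
    def test_sample_equal_to_expected(self):
        res = ttest_vs_expected([355.0] * 10, 355.0, n_comparisons=4)
        assert res["t"] == 0.0
        assert res["p_corrected"] == 1.0

    def test_single_comparison_identity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(360, 5, 12)
        res = ttest_vs_expected(x, 355.0, n_comparisons=1)
        assert res["p_corrected"] == pytest.approx(res["p"])

    def test_matches_closed_form(self):
        x = np.array([352.0, 356.0, 361.0, 349.0, 358.0, 363.0])
        expected = 355.0
        t_manual = (x.mean() - expected) / (x.std(ddof=1) / np.sqrt(x.size))
        res = ttest_vs_expected(x, expected, n_comparisons=2)
        assert res["t"] == pytest.approx(t_manual, rel=1e-12)
        p_manual = 2 * sps.t.sf(abs(t_manual), x.size - 1)
        assert res["p_corrected"] == pytest.approx(min(1.0, 2 * p_manual))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            ttest_vs_expected([1.0, 2.0], 0.0)


class TestAnovaTukey:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(50, 5, 20), rng.normal(55, 5, 25)
        res = anova_tukey({"a": a, "b": b})
        t, _ = sps.ttest_ind(a, b)
        assert res["F"] == pytest.approx(t**2, rel=1e-9)
        assert res["df"] == (1, 43)

    def test_extreme_group_isolated_in_letters(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(60, 3, 15) for i in range(3)}
        groups["shifted"] = rng.normal(120, 3, 15)
        res = anova_tukey(groups)
        letters = res["letters"]
        others = {letters[f"g{i}"] for i in range(3)}
        assert all(set(letters["shifted"]).isdisjoint(set(o)) for o in others)

    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(60, 5, 30) for i in range(4)}
        res = anova_tukey(groups)
        common = set.intersection(*(set(v) for v in res["letters"].values()))
        assert common  # no pair separated

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1.0]})


class TestLinearMixed:
    def make_df(self, shift=0.0, sigma_ind=0.0, seed=0, per_ind=1):
        rng = np.random.default_rng(seed)
        rows = []
        for gi, group in enumerate(["g1", "g2"]):
            for ind in range(20):
                u = rng.normal(0, sigma_ind) if sigma_ind else 0.0
                for c in range(per_ind):
                    rows.append(dict(
                        group=group,
                        individual_id=f"{group}_i{ind}",
                        lambda_max=370.0 + shift * gi + u + rng.normal(0, 5),
                    ))
        return pd.DataFrame(rows)

    def test_zero_variance_matches_ols(self):
        df = self.make_df(shift=10.0)
        fit = fit_linear_mixed(df)
        X = np.column_stack([np.ones(len(df)), (df.group == "g2").astype(float)])
        ols = np.linalg.lstsq(X, df.lambda_max.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.params, ols, atol=1e-6)

    def test_identical_groups_null_contrast(self):
        df = self.make_df(shift=0.0, seed=4, per_ind=3, sigma_ind=3.0)
        fit = fit_linear_mixed(df)
        assert abs(fit.tstats[1]) < 2.5

    def test_group_shift_recovered_within_ci(self):
        df = self.make_df(shift=20.0, seed=5, per_ind=3, sigma_ind=4.0)
        fit = fit_linear_mixed(df)
        lo = fit.params[1] - 1.96 * fit.se[1]
        hi = fit.params[1] + 1.96 * fit.se[1]
        assert lo <= 20.0 <= hi
        assert fit.random_intercept_sd > 1.0


class TestModeCount:
    def test_unimodal(self):
        rng = np.random.default_rng(6)
        assert kde_mode_count(rng.normal(370, 5, 200)) == 1

    def test_bimodal(self):
        rng = np.random.default_rng(7)
        x = np.r_[rng.normal(355, 3, 100), rng.normal(395, 3, 100)]
        assert kde_mode_count(x) == 2
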
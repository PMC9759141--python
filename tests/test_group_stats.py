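import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bbbdce import (
    ancova_genotype,
    cohens_d,
    directional_summary,
    rout_outliers,
    sample_cohort_metrics,
    summarize_table,
)
from bbbdce.synthetic import GroupEffectSpec


class TestCohensD:
    @pytest.mark.parametrize(
        "mean_a, sd_a, mean_b, sd_b, expected",
        [
            (4.66, 1.8, 4.41, 1.5, 0.15),  # left hippocampus peak height
            (3.65, 2.7, 4.06, 4.4, 0.11),  # right hippocampus peak height
            (4.00, 2.3, 3.43, 1.7, 0.28),  # left WM ACC peak height
            (9.95, 9.9, 7.41, 3.1, 0.35),  # left anterior cortex peak height
            (2.78, 1.3, 3.20, 1.4, 0.31),  # posterior parahippocampal height
            (3.55, 1.6, 3.56, 1.1, 0.01),  # subcortical probe right hippocampus
        ],
    )
    def test_reported_group_summaries(self, mean_a, sd_a, mean_b, sd_b, expected):
        assert round(cohens_d(mean_a, sd_a, mean_b, sd_b), 2) == expected

    def test_unweighted_pooling_differs_from_n_weighted(self):
        """The RMS-of-SDs convention is discriminable when SDs are unequal."""
        d = cohens_d(9.95, 9.9, 7.41, 3.1)
        pooled_nw = np.sqrt((18 * 9.9**2 + 16 * 3.1**2) / 34)
        d_weighted = abs(9.95 - 7.41) / pooled_nw
        assert round(d, 2) == 0.35
        assert round(d_weighted, 2) == 0.34

    def test_equal_means_give_zero(self):
        assert cohens_d(3.0, 1.0, 3.0, 2.0) == 0.0

    def test_undefined_when_no_spread_but_means_differ(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_d(1.0, 0.0, 2.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        ma=st.floats(-50, 50), mb=st.floats(-50, 50),
        sa=st.floats(0.1, 20), sb=st.floats(0.1, 20),
        scale=st.floats(0.1, 10), offset=st.floats(-100, 100),
    )
    def test_symmetry_and_affine_invariance(self, ma, mb, sa, sb, scale, offset):
        d = cohens_d(ma, sa, mb, sb)
        assert d == pytest.approx(cohens_d(mb, sb, ma, sa))  # group symmetry
        assert cohens_d(
            scale * ma + offset, scale * sa, scale * mb + offset, scale * sb
        ) == pytest.approx(d, rel=1e-9)

    def test_scales_inversely_with_common_sd_inflation(self):
        assert cohens_d(1.0, 2.0, 3.0, 4.0) == pytest.approx(
            cohens_d(1.0, 1.0, 3.0, 2.0) / 2.0
        )


class TestRoutOutliers:
    def test_tight_cluster_untouched(self):
        vals = np.array([10.0, 10.1, 9.9, 10.2, 9.8])
        kept, removed = rout_outliers(vals)
        assert removed.size == 0
        np.testing.assert_array_equal(kept, vals)

    def test_gross_outlier_removed(self):
        vals = np.array([10.0, 10.1, 9.9, 10.2, 9.8, 50.0])
        # oracle: robust z of the extreme point is enormous
        resid = vals - np.median(vals)
        rsdr = np.percentile(np.abs(resid), 68.27) * 6 / 5
        assert abs(resid[-1]) / rsdr > 20
        kept, removed = rout_outliers(vals)
        assert removed.tolist() == [5]
        assert 50.0 not in kept

    def test_degenerate_n_passes_through(self, caplog):
        vals = np.array([1.0, 100.0])
        with caplog.at_level("WARNING"):
            kept, removed = rout_outliers(vals)
        assert removed.size == 0 and kept.size == 2
        assert "no removal" in caplog.text

    def test_false_positive_rate_is_low_on_null_data(self):
        rng = np.random.default_rng(2)
        n_removed = sum(
            rout_outliers(rng.normal(size=19))[1].size for _ in range(200)
        )
        assert n_removed / (200 * 19) < 0.02  # Q = 1% target


class TestAncova:
    def test_identical_groups_give_f_zero_p_one(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        group = np.array(["a", "a", "a", "b", "b", "b"])
        # same covariate pattern in both groups (orthogonal to grouping) but
        # not collinear with y, so the residual variance stays positive
        cov = np.array([5.0, 1.0, 3.0, 5.0, 1.0, 3.0])
        res = ancova_genotype(y, group, cov)
        assert res.f_stat == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_explicit_normal_equations(self):
        """Six-subject toy set against a hand-rolled least-squares F test."""
        y = np.array([2.1, 3.3, 1.8, 4.0, 4.4, 3.6])
        group = np.array(["a", "a", "a", "b", "b", "b"])
        cov = np.array([10.0, 14.0, 9.0, 12.0, 15.0, 11.0])
        res = ancova_genotype(y, group, cov)

        g = (group == "b").astype(float)
        X = np.column_stack([np.ones(6), g, cov - cov.mean()])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        df_den = 6 - 3
        s2 = resid @ resid / df_den
        var_beta = s2 * np.linalg.inv(X.T @ X)
        f_manual = beta[1] ** 2 / var_beta[1, 1]
        p_manual = sps.f.sf(f_manual, 1, df_den)
        assert res.f_stat == pytest.approx(f_manual, abs=1e-10, rel=1e-10)
        assert res.p_value == pytest.approx(p_manual, abs=1e-10, rel=1e-10)
        assert res.adjusted_means["a"] == pytest.approx(beta[0], rel=1e-10)
        assert res.adjusted_means["b"] == pytest.approx(beta[0] + beta[1], rel=1e-10)

    def test_agrees_with_independent_ancova_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        y = rng.normal(size=24)
        group = np.array(["a"] * 12 + ["b"] * 12)
        cov = rng.normal(size=24)
        res = ancova_genotype(y, group, cov)
        df = pd.DataFrame({"y": y, "g": group, "c": cov})
        pg = pingouin.ancova(data=df, dv="y", between="g", covar="c")
        row = pg[pg["Source"] == "g"].iloc[0]
        assert res.f_stat == pytest.approx(row["F"], rel=1e-9)
        assert res.p_value == pytest.approx(row["p_unc"], rel=1e-9)

    def test_covariate_shift_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        group = np.array(["a"] * 10 + ["b"] * 10)
        cov = rng.normal(size=20)
        r1 = ancova_genotype(y, group, cov)
        r2 = ancova_genotype(y, group, cov + 1234.5)
        assert r1.f_stat == pytest.approx(r2.f_stat, rel=1e-10)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-10)

    def test_constant_covariate_degrades_to_anova_with_warning(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=12)
        group = np.array(["a"] * 6 + ["b"] * 6)
        with pytest.warns(UserWarning, match="constant"):
            res = ancova_genotype(y, group, np.full(12, 7.0))
        f_anova, p_anova = sps.f_oneway(y[:6], y[6:])
        assert res.f_stat == pytest.approx(f_anova, rel=1e-9)
        assert res.p_value == pytest.approx(p_anova, rel=1e-9)

    def test_collinear_covariate_rejected(self):
        y = np.arange(8.0)
        group = np.array(["a"] * 4 + ["b"] * 4)
        cov = (group == "b").astype(float) * 3.0 + 1.0
        with pytest.raises(ValueError, match="collinear"):
            ancova_genotype(y, group, cov)

    def test_ancova_f_converges_to_anova_f_for_null_covariate(self):
        """With a covariate constructed orthogonal to both group and metric
        (zero covariate effect), the ANCOVA group F equals the two-sample
        ANOVA F up to the one-df change in the residual denominator."""
        rng = np.random.default_rng(11)
        n = 200
        group = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        g = (group == "b").astype(float)
        y = rng.normal(size=n) + 0.3 * g
        raw = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), g, y])
        cov = raw - basis @ np.linalg.lstsq(basis, raw, rcond=None)[0]
        res = ancova_genotype(y, group, cov)
        f_anova, _ = sps.f_oneway(y[group == "a"], y[group == "b"])
        # the extra parameter costs one residual df, deflating F by (n-3)/(n-2)
        assert res.f_stat == pytest.approx(f_anova * (n - 3) / (n - 2), rel=1e-9)


@pytest.fixture(scope="module")
def metrics():
    return sample_cohort_metrics(GroupEffectSpec(rng_seed=5))


class TestSummaryTable:

    def test_table_structure(self, metrics):
        table = summarize_table(metrics)
        assert len(table) == 20  # 10 ROIs x 2 metrics
        assert set(table["metric"]) == {"peak_height", "peak_position"}
        assert ((table["ancova_p"] > 0) & (table["ancova_p"] <= 1)).all()
        assert (table["cohens_d"] >= 0).all()
        assert (table["n_a"] + table["n_b"] <= 36).all()

    def test_outlier_is_removed_from_summary(self, metrics):
        spiked = metrics.copy()
        i = spiked.index[(spiked.roi_id == 1) & (spiked.group == "APOE3")][0]
        spiked.loc[i, "peak_height"] = 1e4
        table = summarize_table(spiked)
        row = table[(table.roi_id == 1) & (table.metric == "peak_height")].iloc[0]
        assert spiked.loc[i, "subject_id"] in row["outliers_removed"]
        assert row["n_a"] <= 18
        assert row["mean_a"] < 100

    def test_directional_summary_counts_rois(self, metrics):
        d = directional_summary(metrics)
        assert d["n_rois"] == 10
        assert 0 <= d["n_group_b_higher"] <= 10
        assert len(d["rois_group_b_higher"]) == d["n_group_b_higher"]

    def test_missing_metric_column_yields_nan_row_not_crash(self, metrics, caplog):
        broken = metrics.drop(columns=["peak_position"])
        with caplog.at_level("WARNING"):
            table = summarize_table(broken)
        assert set(table["metric"]) == {"peak_height"}
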
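"""Regional statistics, Gd conversion, Deming regression, group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import odr, stats

from cardiot1.quantify import (
    GdMeasurement,
    classify_tissue,
    compare_groups,
    correlate,
    gd_concentration,
    orthogonal_regression,
    regional_means,
    sectors_from_segments,
)
from cardiot1.relaxometry import RelaxationMap


class TestRegionalMeans:
    def test_piecewise_constant_map_gives_exact_means(self, default_truth, segmentation, default_spec):
        t1 = RelaxationMap(np.nan_to_num(default_truth.t1_pre_map), unit="ms")
        means = regional_means(t1, segmentation).set_index("segment_id")
        # segment 12 (mid anterolateral) is fully inside the lesion
        assert means.loc[12, "mean"] == default_spec.t1_infarct_ms
        assert means.loc[8, "mean"] == default_spec.t1_remote_ms

    def test_permutation_invariance_of_means(self, default_truth, segmentation):
        t1 = RelaxationMap(np.nan_to_num(default_truth.t1_pre_map), unit="ms")
        a = regional_means(t1, segmentation)
        # permuting voxel values within a segment leaves the mean unchanged
        perm = t1.value.copy()
        sel = segmentation.segment_id == 9
        vals = perm[sel]
        perm[sel] = vals[::-1]
        b = regional_means(RelaxationMap(perm, unit="ms"), segmentation)
        pd.testing.assert_frame_equal(a, b)

    def test_grid_mismatch_rejected(self, segmentation):
        with pytest.raises(ValueError):
            regional_means(RelaxationMap(np.ones((2, 2, 2)), unit="ms"), segmentation)

    def test_empty_segment_flagged(self, default_truth, segmentation):
        t1 = RelaxationMap(
            np.nan_to_num(default_truth.t1_pre_map),
            unit="ms",
            valid_mask=segmentation.segment_id != 17,
        )
        means = regional_means(t1, segmentation).set_index("segment_id")
        assert means.loc[17, "n_voxels"] == 0 and np.isnan(means.loc[17, "mean"])


class TestClassification:
    @pytest.mark.parametrize(
        "swt, expected",
        [
            (10.0, "infarct"),
            (14.999, "infarct"),
            (15.0, "intermediate"),  # strict inequality at the boundary
            (30.0, "intermediate"),
            (45.0, "intermediate"),
            (45.001, "remote"),
            (65.0, "remote"),
            (float("nan"), None),
        ],
    )
    def test_thresholds(self, swt, expected):
        assert classify_tissue(swt) == expected

    def test_vectorized(self):
        assert classify_tissue([10.0, 30.0, 65.0]) == ["infarct", "intermediate", "remote"]


class TestGdConcentration:
    def test_unit_cancellation_oracle(self):
        assert gd_concentration(0.0, 1.0) == 0.0
        assert gd_concentration(157.25, 1.05) == pytest.approx(1.0, rel=1e-12)
        assert gd_concentration(15.725, 10.5) == pytest.approx(0.01, rel=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(ng=st.floats(0.0, 1e4), mg=st.floats(0.1, 100.0), k=st.floats(0.1, 10.0))
    def test_scaling_both_masses_leaves_concentration(self, ng, mg, k):
        assert gd_concentration(k * ng, k * mg) == pytest.approx(gd_concentration(ng, mg), rel=1e-9)

    def test_bad_masses_rejected(self):
        with pytest.raises(ValueError):
            gd_concentration(10.0, 0.0)
        with pytest.raises(ValueError):
            GdMeasurement("septal", -1.0, 1.0)


class TestSectorAggregation:
    def test_uniform_value_gives_equal_sectors(self, segmentation):
        table = pd.DataFrame(
            {"segment_id": range(7, 13), "delta_r1": 0.42, "n_voxels": [350, 348, 354, 350, 348, 354]}
        )
        sectors = sectors_from_segments(table, segmentation)
        assert np.allclose(sectors.delta_r1, 0.42)

    def test_weighted_mean_consistency_over_all_sectors(self, segmentation):
        rng = np.random.default_rng(3)
        n_vox = np.full(6, 351)
        table = pd.DataFrame({"segment_id": range(7, 13), "delta_r1": rng.uniform(0.1, 0.7, 6), "n_voxels": n_vox})
        sectors = sectors_from_segments(table, segmentation)
        whole_level = np.average(table.delta_r1, weights=n_vox)
        assert np.average(sectors.delta_r1, weights=sectors.weight) == pytest.approx(whole_level, rel=1e-9)

    def test_anterolateral_lesion_peaks_in_lateral_and_anterior(self, segmentation):
        # lesion in segments 11 (half) and 12 (full), as the default phantom
        dr1 = {7: 0.15, 8: 0.15, 9: 0.15, 10: 0.15, 11: 0.375, 12: 0.6}
        table = pd.DataFrame(
            {"segment_id": list(dr1), "delta_r1": list(dr1.values()), "n_voxels": 350}
        )
        sectors = sectors_from_segments(table, segmentation).set_index("sector_id")
        ranked = sectors.delta_r1.sort_values(ascending=False)
        assert set(ranked.index[:2]) == {"lateral", "anterior"}
        assert ranked.index[-1] in ("septal", "posterior")


class TestDeming:
    def test_exact_collinear_any_lambda(self):
        x = np.array([0.0, 0.2, 0.4, 0.7, 1.0])
        y = 2.0 * x + 1.0
        for lam in (0.25, 1.0, 4.0):
            fit = orthogonal_regression(x, y, lam)
            assert fit.slope == pytest.approx(2.0, rel=1e-12)
            assert fit.intercept == pytest.approx(1.0, rel=1e-12)
            assert fit.pearson_r == pytest.approx(1.0)

    def test_matches_scipy_odr(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.05, 0.6, 8)
        y = 0.1 + 1.06 * x
        xo = x + rng.normal(0, 0.05, 8)
        yo = y + rng.normal(0, 0.05, 8)
        fit = orthogonal_regression(xo, yo, 1.0)
        ref = odr.ODR(odr.Data(xo, yo, wd=1.0, we=1.0), odr.unilinear, beta0=[1.0, 0.0]).run()
        assert fit.slope == pytest.approx(ref.beta[0], rel=1e-5)
        assert fit.intercept == pytest.approx(ref.beta[1], rel=1e-4)

    def test_lambda_infinity_reproduces_ols(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 12)
        y = 0.3 + 1.7 * x + rng.normal(0, 0.1, 12)
        fit = orthogonal_regression(x, y, 1e9)
        ols = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ols.slope, rel=1e-6)
        assert fit.intercept == pytest.approx(ols.intercept, rel=1e-6)

    def test_symmetry_in_xy_exchange(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 15)
        y = 0.5 * x + rng.normal(0, 0.2, 15)
        f_xy = orthogonal_regression(x, y, 1.0)
        f_yx = orthogonal_regression(y, x, 1.0)
        assert f_xy.slope * f_yx.slope == pytest.approx(1.0, rel=1e-9)

    def test_attenuation_ordering_vs_ols(self):
        # with noise on x, |Deming slope| >= |OLS slope| on any dataset
        rng = np.random.default_rng(100)
        for _ in range(100):
            n = rng.integers(5, 25)
            x = rng.normal(0, 1, n)
            y = rng.uniform(-2, 2) * x + rng.normal(0, rng.uniform(0.05, 1.0), n)
            x = x + rng.normal(0, rng.uniform(0.05, 1.0), n)
            if np.ptp(x) == 0:
                continue
            dem = orthogonal_regression(x, y, 1.0).slope
            ols = stats.linregress(x, y).slope
            assert abs(dem) >= abs(ols) - 1e-12

    def test_jackknife_ci_contains_estimate_and_detects_offset(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0.05, 0.6, 20)
        y = 0.1 + 1.06 * x + rng.normal(0, 0.02, 20)
        fit = orthogonal_regression(x + rng.normal(0, 0.02, 20), y, 1.0)
        assert fit.slope_ci[0] < fit.slope < fit.slope_ci[1]
        assert fit.intercept_ci[0] < fit.intercept < fit.intercept_ci[1]
        assert fit.intercept_ci[0] > 0.0  # the nonzero offset is resolved

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            orthogonal_regression([1.0, 1.0, 1.0], [0.0, 1.0, 2.0], 1.0)
        fit = orthogonal_regression([0.0, 1.0, 2.0], [5.0, 6.0, 4.0][:3], 1.0)
        assert np.isfinite(fit.slope)
        # isotropic cloud: s_xy = 0 and s_yy = lambda * s_xx -> undetermined
        x = np.array([1.0, -1.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, -1.0])
        fit = orthogonal_regression(x, y, 1.0)
        assert fit.degenerate


class TestCorrelate:
    def test_identity_is_perfect(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        r, r2 = correlate(x, x)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_r_squared_is_square_of_r(self):
        # the printed pairs: r=0.6 -> 0.36; r=0.81 -> 0.6561 ~ 0.65
        assert 0.6**2 == pytest.approx(0.36)
        assert 0.81**2 == pytest.approx(0.65, abs=0.01)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        r, r2 = correlate(x, y)
        assert r2 == pytest.approx(r**2, rel=1e-12)

    def test_per_slice_averaging_improves_misaligned_sectors(self):
        # simulate slices of 4 sectors where the lesion is rotated between
        # the two "modalities": per-segment r suffers, per-slice r does not
        rng = np.random.default_rng(12)
        x_all, y_all, groups = [], [], []
        for animal in range(8):
            lesion = np.zeros(4)
            lesion[rng.integers(0, 4)] = rng.uniform(0.3, 0.6)
            x = lesion + 0.05  # ex vivo concentrations
            y = 1.06 * (np.roll(lesion, 1) + 0.05)  # cut rotated by one sector
            x_all.extend(x)
            y_all.extend(y)
            groups.extend([animal] * 4)
        r_seg, _ = correlate(x_all, y_all)
        r_slice, _ = correlate(x_all, y_all, groups=groups)
        assert r_slice > r_seg

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])


class TestGroupComparison:
    def test_identical_groups_show_nothing(self):
        g = {"a": [1.0, 1.1, 0.9, 1.0], "b": [1.0, 1.1, 0.9, 1.0], "c": [1.0, 1.1, 0.9, 1.0]}
        res = compare_groups(g)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert np.all(res.tukey.p_value > 0.99)

    def test_two_group_anova_equals_pooled_t_test(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 15)
        res = compare_groups({"a": a, "b": b})
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-9)

    def test_separated_groups_all_pairs_significant(self):
        rng = np.random.default_rng(9)
        res = compare_groups(
            {
                "infarct": 0.60 + rng.normal(0, 0.02, 10),
                "remote": 0.15 + rng.normal(0, 0.02, 10),
                "control": 0.23 + rng.normal(0, 0.02, 10),
            }
        )
        assert res.p_value < 1e-6
        assert res.tukey.significant.all()

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0]})
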
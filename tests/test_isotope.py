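"""Crosstalk calibration, window correction, activities, selectivity, t-tests."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_wells
from zipswap.isotope import (aggregate_and_test, compute_activity,
                             correct_cd_window, crosstalk_slope_se,
                             fit_crosstalk, selectivity, well_zn_cd_ratio)
from zipswap.synthdata import gen_assay, gen_standards


class TestFitCrosstalk:
    def test_noiseless_slope_recovered_exactly(self, noiseless_calib):
        assert noiseless_calib.slope == pytest.approx(0.235, abs=1e-12)
        assert noiseless_calib.intercept == 0.0
        assert noiseless_calib.r_squared == pytest.approx(1.0)

    def test_zero_cd_counts_give_zero_slope(self):
        df = pd.DataFrame({"zn_window_cpm": [1e4, 2e4, 4e4],
                           "cd_window_cpm": [0.0, 0.0, 0.0]})
        assert fit_crosstalk(df).slope == 0.0

    def test_identical_standards_rejected(self):
        df = pd.DataFrame({"zn_window_cpm": [5e4, 5e4],
                           "cd_window_cpm": [1e4, 1e4]})
        with pytest.raises(np.linalg.LinAlgError):
            fit_crosstalk(df)

    def test_poisson_noise_recovery_within_3_se(self):
        # 6-point series, truth slope 0.2, expected counts >= 1e4
        rng = np.random.default_rng(0)
        zn_mean = np.array([1e4, 2e4, 4e4, 8e4, 1.2e5, 2e5])
        df = pd.DataFrame({
            "zn_window_cpm": rng.poisson(zn_mean).astype(float),
            "cd_window_cpm": rng.poisson(0.2 * zn_mean).astype(float),
        })
        calib = fit_crosstalk(df)
        se = crosstalk_slope_se(df, calib.slope)
        assert abs(calib.slope - 0.2) <= 3 * max(se, 1e-4)

    def test_slope_estimator_unbiased_over_replicates(self):
        slopes = [fit_crosstalk(gen_standards(slope=0.2, seed=k)).slope
                  for k in range(1000)]
        mean, sem = np.mean(slopes), np.std(slopes, ddof=1) / np.sqrt(1000)
        assert abs(mean - 0.2) <= 2 * sem + 1e-4

    def test_count_scaling_shrinks_estimator_variance(self):
        # 100x more counts -> ~100x smaller Poisson variance of the slope
        small = [fit_crosstalk(gen_standards(cpm_per_uM=5e3, seed=k)).slope
                 for k in range(300)]
        large = [fit_crosstalk(gen_standards(cpm_per_uM=5e5, seed=k)).slope
                 for k in range(300)]
        ratio = np.var(small) / np.var(large)
        assert 50 < ratio < 200


class TestCorrectCdWindow:
    @pytest.mark.parametrize("cd, zn, slope, expected, clipped", [
        (1000.0, 1000.0, 0.235, 765.0, False),
        (100.0, 1000.0, 0.235, 0.0, True),     # 100 - 235 < 0 -> clipped
        (1234.0, 5000.0, 0.0, 1234.0, False),  # slope 0 -> raw counts
    ])
    def test_examples(self, cd, zn, slope, expected, clipped,
                      noiseless_calib):
        calib = noiseless_calib
        if slope != calib.slope:
            from dataclasses import replace
            calib = replace(calib, slope=slope)
        corrected, flag = correct_cd_window(cd, zn, calib)
        assert corrected == pytest.approx(expected)
        assert flag == clipped

    def test_exact_on_noiseless_synthetic_for_any_slope(self):
        for s in (0.0, 0.1, 0.235, 0.5, 0.9):
            zn = np.array([1e4, 2e4, 5e4])
            cd_true = np.array([500.0, 900.0, 1500.0])
            calib = fit_crosstalk(pd.DataFrame(
                {"zn_window_cpm": zn, "cd_window_cpm": s * zn}))
            corrected, _ = correct_cd_window(cd_true + s * zn, zn, calib)
            np.testing.assert_allclose(corrected, cd_true, rtol=1e-12)


class TestComputeActivity:
    def test_construct_equal_to_empty_gives_zero(self, noiseless_calib):
        wells = make_wells([("e1", "WT", 5000, 2000),
                            ("e1", "empty_vector", 5000, 2000)])
        acts = compute_activity(wells, noiseless_calib)
        assert (acts["activity_cpm"] == 0).all()

    def test_relative_activity_ratio(self, noiseless_calib):
        wells = make_wells([
            ("e1", "WT", 2500, 0), ("e1", "V", 1000, 0),
            ("e1", "empty_vector", 500, 0)])
        acts = compute_activity(wells, noiseless_calib)
        zn = acts[acts["metal"] == "Zn"].set_index("construct")
        assert zn.loc["WT", "relative_activity_pct"] == 100.0
        assert zn.loc["V", "relative_activity_pct"] == pytest.approx(25.0)

    def test_missing_wt_names_experiment(self, noiseless_calib):
        wells = make_wells([("e7", "V", 1000, 100),
                            ("e7", "empty_vector", 100, 10)])
        with pytest.raises(ValueError, match="e7"):
            compute_activity(wells, noiseless_calib)

    def test_missing_empty_vector_is_an_error(self, noiseless_calib):
        wells = make_wells([("e1", "WT", 1000, 100)])
        with pytest.raises(ValueError, match="empty"):
            compute_activity(wells, noiseless_calib)

    def test_simulated_relative_activity_recovers_truth(self):
        multipliers = {"WT": (1.0, 1.0), "V": (0.4, 0.4)}
        _, wells, _ = gen_assay(multipliers=multipliers, seed=21,
                                n_experiments=3, expression_cv=0.05)
        calib = fit_crosstalk(gen_standards(seed=99))
        acts = compute_activity(wells, calib)
        rel = acts[(acts["construct"] == "V") & (acts["metal"] == "Zn")]
        assert rel["relative_activity_pct"].mean() == pytest.approx(40, abs=5)


class TestSelectivity:
    def test_wt_is_100_by_construction(self, noiseless_calib):
        wells = make_wells([
            ("e1", "WT", 4000, 2000), ("e1", "V", 3000, 1500),
            ("e1", "empty_vector", 0, 0),
            ("e2", "WT", 5000, 2500), ("e2", "V", 2000, 1000),
            ("e2", "empty_vector", 0, 0)])
        res = selectivity(compute_activity(wells, noiseless_calib))
        wt = res.summary.set_index("construct").loc["WT"]
        assert wt["relative_selectivity_pct"] == 100.0
        per = res.per_experiment
        assert (per[per["construct"] == "WT"]
                ["relative_selectivity_pct"] == 100.0).all()

    def test_fourfold_cd_suppression_gives_400_percent(self):
        # Cd activity suppressed 4x with Zn unchanged -> relative
        # selectivity ~400%, the double-variant phenotype scale
        multipliers = {"WT": (1.0, 1.0), "2M": (1.0, 0.25)}
        _, wells, truth = gen_assay(multipliers=multipliers, seed=13)
        calib = fit_crosstalk(gen_standards(seed=14))
        res = selectivity(compute_activity(wells, calib))
        got = res.summary.set_index("construct").loc[
            "2M", "relative_selectivity_pct"]
        assert truth.expected_relative_selectivity_pct["2M"] == 400.0
        assert got == pytest.approx(400.0, rel=0.10)

    def test_internal_competition_ratio_invariance(self, noiseless_calib):
        # common per-well factor (expression, cell number) cancels exactly
        rng = np.random.default_rng(3)
        zn = rng.uniform(1e3, 1e5, size=20)
        cd = rng.uniform(1e3, 1e5, size=20) + 0.235 * zn
        base = well_zn_cd_ratio(zn, cd, noiseless_calib)
        for factor in (0.1, 3.0, 42.0):
            scaled = well_zn_cd_ratio(factor * zn, factor * cd,
                                      noiseless_calib)
            np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_nonpositive_cd_experiment_excluded_with_flag(self,
                                                          noiseless_calib):
        wells = make_wells([
            ("e1", "WT", 4000, 2000), ("e1", "V", 3000, 100),
            ("e1", "empty_vector", 0, 1000),
            ("e2", "WT", 4000, 2000), ("e2", "V", 3000, 1500),
            ("e2", "empty_vector", 0, 0)])
        res = selectivity(compute_activity(wells, noiseless_calib))
        assert ("V" in set(res.excluded["construct"]))
        v_rows = res.per_experiment[res.per_experiment["construct"] == "V"]
        assert list(v_rows["experiment_id"]) == ["e2"]


class TestAggregateAndTest:
    def test_identical_arms_give_p_of_1(self):
        res = aggregate_and_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_large_shift_is_significant(self):
        from scipy import stats
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        res = aggregate_and_test(a, b)
        assert res.p_value < 0.001
        # closed-form two-sample t with pooled variance as oracle
        t_oracle = (np.mean(a) - np.mean(b)) / (1.0 * np.sqrt(2 / 3))
        assert res.t_statistic == pytest.approx(t_oracle)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_oracle), df=4))

    def test_n_below_2_rejected(self):
        with pytest.raises(ValueError):
            aggregate_and_test([1.0], [1.0, 2.0])

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(2024)
        reps = 10_000
        a = rng.normal(size=(8, reps))
        b = rng.normal(size=(8, reps))
        from scipy import stats
        _, p = stats.ttest_ind(a, b, axis=0)
        # sanity: the vectorized null matches the scalar implementation
        one = aggregate_and_test(a[:, 0], b[:, 0])
        assert one.p_value == pytest.approx(p[0])
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)
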
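"""Confound adjustment, trajectory fits, shift test, effect sizes, ANCOVA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from vbmtraj.simulate import TrajectoryParams, generate_cohort, simulate_regional_gm
from vbmtraj.trajectory import (
    adjust_gm,
    cohens_d,
    fit_group_trajectory,
    global_volume_ancova,
    one_sample_t,
    shift_test,
)
from tests.conftest import make_cohort


def quadratic(age, b0, b1, b2):
    return b0 + b1 * age + b2 * age**2


class TestAdjustGM:
    def test_no_confounds_removes_group_mean_only(self, cohort12):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(cohort12))
        adj = adjust_gm(y, cohort12, confounds=())
        for g in ("ASD", "CTRL"):
            sel = (cohort12["group"] == g).to_numpy()
            np.testing.assert_allclose(adj.values[sel], y[sel] - y[sel].mean(), atol=1e-12)
            assert adj.group_offset[g] == pytest.approx(y[sel].mean())

    def test_orthogonal_to_confound_within_group(self, cohort80):
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(cohort80)) + 0.01 * cohort80["tbv"].to_numpy()
        adj = adjust_gm(y, cohort80, confounds=("tbv", "fsiq"))
        for g in ("ASD", "CTRL"):
            sel = (cohort80["group"] == g).to_numpy()
            for cov in ("tbv", "fsiq"):
                c = cohort80[cov].to_numpy()[sel]
                assert abs(adj.values[sel] @ (c - c.mean())) < 1e-6

    def test_age_confound_rejected(self, cohort12):
        with pytest.raises(ValueError, match="age"):
            adjust_gm(np.zeros(12), cohort12, confounds=("age", "tbv"))

    def test_noise_free_generative_oracle(self):
        """With tbv constructed orthogonal to the age signal, adjustment
        returns the pure quadratic up to one additive constant per group."""
        ages = np.array([10.0, 15.0, 20.0, 25.0, 30.0, 35.0])
        cohort = make_cohort(ages, ages + 1.0, seed=3)
        signal = quadratic(cohort["age"].to_numpy(), 1.0, 0.9, -0.02)
        # Gram-Schmidt: make tbv orthogonal to [1, signal] within each group
        tbv = np.empty(len(cohort))
        rng = np.random.default_rng(4)
        for g in ("ASD", "CTRL"):
            sel = (cohort["group"] == g).to_numpy()
            raw = rng.normal(size=sel.sum())
            basis = np.column_stack([np.ones(sel.sum()), signal[sel]])
            tbv[sel] = raw - basis @ np.linalg.lstsq(basis, raw, rcond=None)[0]
        cohort = cohort.assign(tbv=tbv)
        y = signal + 0.5 * tbv
        adj = adjust_gm(y, cohort, confounds=("tbv",))
        for g in ("ASD", "CTRL"):
            sel = (cohort["group"] == g).to_numpy()
            resid = adj.values[sel] - signal[sel]
            np.testing.assert_allclose(resid, resid.mean(), atol=1e-8)

    def test_idempotent(self, cohort80):
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(cohort80))
        once = adjust_gm(y, cohort80)
        twice = adjust_gm(once.values, cohort80)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-8)


class TestFitGroupTrajectory:
    def test_exact_quadratic_interpolation(self):
        ages = np.array([10.0, 20.0, 30.0, 40.0])
        cohort = make_cohort(ages, ages, seed=6)
        y = quadratic(cohort["age"].to_numpy(), 2.0, 1.0, -0.02)
        fit = fit_group_trajectory(adjust_gm(y, cohort, confounds=()))
        for curve in fit.curves.values():
            assert curve.beta2 == pytest.approx(-0.02, abs=1e-10)
            assert curve.peak_age == pytest.approx(25.0, abs=1e-8)
            assert curve.trough_age is None
            assert curve.r2 == pytest.approx(1.0)

    def test_u_shape_reports_trough_not_peak(self):
        ages = np.linspace(8, 50, 15)
        cohort = make_cohort(ages, ages, seed=7)
        y = quadratic(cohort["age"].to_numpy(), 10.0, -0.6, 0.01)
        fit = fit_group_trajectory(adjust_gm(y, cohort, confounds=()))
        for curve in fit.curves.values():
            assert curve.peak_age is None
            assert curve.trough_age == pytest.approx(30.0, abs=1e-8)

    def test_recovery_under_noise(self):
        cohort = generate_cohort(50, 50, seed=8)
        params = TrajectoryParams.null(10.0, 0.02, 25.0, noise_sd=0.2)
        data = simulate_regional_gm(cohort, params, seed=9)
        fit = fit_group_trajectory(adjust_gm(data.values[:, 0], cohort))
        for curve in fit.curves.values():
            assert curve.peak_age == pytest.approx(25.0, abs=2.0)

    def test_too_few_subjects_rejected(self):
        cohort = make_cohort([10.0, 20.0], [10.0, 20.0, 30.0], seed=10)
        with pytest.raises(ValueError, match="at least 3"):
            fit_group_trajectory(adjust_gm(np.zeros(5), cohort, confounds=()))


class TestOneSampleT:
    def test_closed_form_example(self):
        t, df, p = one_sample_t(np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-9)
        assert t == pytest.approx(3.4641016, rel=1e-6)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_all_zeros(self):
        t, df, p = one_sample_t(np.zeros(5))
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_zero_variance_nonzero_mean(self):
        with pytest.warns(UserWarning, match="infinite"):
            t, _, p = one_sample_t(np.full(4, 2.0))
        assert np.isinf(t) and p == 0.0

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            d = rng.normal(size=rng.integers(2, 40))
            t, df, p = one_sample_t(d)
            ref = stats.ttest_1samp(d, 0.0)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestCohensD:
    def test_identical_groups_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a) == 0.0

    def test_hand_example(self):
        d = cohens_d(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        assert d == pytest.approx(-1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning, match="pooled"):
            assert np.isnan(cohens_d(np.ones(3), np.ones(3)))


def shifted_adjusted(delta, seed, noise=1.0, n=40, mu=40.0):
    cohort = generate_cohort(n, n, seed=seed)
    params = TrajectoryParams.shifted(10.0, 0.02, mu, delta, noise_sd=noise)
    data = simulate_regional_gm(cohort, params, seed=seed + 10_000)
    return adjust_gm(data.values[:, 0], cohort)


class TestShiftTest:
    def test_identical_groups_self_match(self):
        ages = [10.0, 18.0, 26.0, 34.0, 42.0]
        cohort = make_cohort(ages, ages, seed=13)
        y_half = np.array([1.0, 4.0, 2.0, 5.0, 3.0])
        y = np.concatenate([y_half, y_half])
        res = shift_test(adjust_gm(y, cohort, confounds=()), k=3)
        np.testing.assert_array_equal(res.deltas, 0.0)
        assert res.mean_delta == 0.0
        assert res.direction == "none"

    def test_leftward_shift_detected(self):
        res = shift_test(shifted_adjusted(5.0, seed=1), k=5)
        assert res.mean_delta > 0
        assert res.p < 0.05
        assert res.direction == "leftward"
        assert res.df == 39

    def test_label_swap_flips_direction(self):
        adj = shifted_adjusted(5.0, seed=2)
        fwd = shift_test(adj, k=5)
        rev = shift_test(adj, k=5, test_group="CTRL", ref_group="ASD")
        assert fwd.mean_delta > 0 > rev.mean_delta
        assert rev.direction == "rightward"

    def test_bias_vanishes_as_noise_vanishes(self):
        """Nearest-neighbour (k=1) matching recovers the true shift as noise -> 0."""
        means = [
            shift_test(shifted_adjusted(5.0, s, noise=0.05), k=1).mean_delta
            for s in range(10)
        ]
        assert np.mean(means) == pytest.approx(5.0, abs=0.75)

    def test_k_sensitivity_attenuates_but_preserves_direction(self):
        """Larger candidate sets shrink the estimate toward zero; the
        direction and its significance survive for k in {1, 3, 5, 10}."""
        by_k = {}
        for k in (1, 3, 5, 10):
            res = [shift_test(shifted_adjusted(5.0, s), k=k) for s in range(8)]
            assert np.mean([r.p < 0.05 and r.mean_delta > 0 for r in res]) >= 0.75
            by_k[k] = np.mean([r.mean_delta for r in res])
        assert all(m > 0 for m in by_k.values())
        assert by_k[1] > by_k[3] > by_k[10]

    def test_min_gm_selection_mode(self):
        adj = shifted_adjusted(5.0, seed=3)
        res = shift_test(adj, k=5, selection="min_gm")
        nearest = shift_test(adj, k=1)
        np.testing.assert_array_equal(res.deltas, nearest.deltas)

    def test_k_clipped_with_warning(self):
        cohort = make_cohort([10.0, 20.0, 30.0], [15.0, 25.0], seed=14)
        adj = adjust_gm(np.arange(5.0), cohort, confounds=())
        with pytest.warns(UserWarning, match="clipped"):
            res = shift_test(adj, k=10)
        assert res.k == 2

    def test_invalid_inputs(self):
        cohort = make_cohort([10.0, 20.0, 30.0], [15.0, 25.0], seed=15)
        adj = adjust_gm(np.arange(5.0), cohort, confounds=())
        with pytest.raises(ValueError):
            shift_test(adj, k=0)
        with pytest.raises(ValueError):
            shift_test(adj, selection="closest")
        with pytest.raises(ValueError):
            shift_test(adj, match_scale="raw")


class TestGlobalAncova:
    def test_statsmodels_nested_oracle(self, cohort12):
        rng = np.random.default_rng(16)
        y = rng.normal(size=len(cohort12)) + np.where(
            cohort12["group"] == "ASD", 0.8, 0.0
        )
        res = global_volume_ancova(y, cohort12)

        cov = np.column_stack(
            [
                cohort12["age"],
                cohort12["age"] ** 2,
                cohort12["fsiq"],
                cohort12["viq"],
                cohort12["piq"],
            ]
        )
        cov = cov - cov.mean(axis=0)
        g = (cohort12["group"] == "ASD").to_numpy().astype(float)
        full = sm.OLS(y, np.column_stack([np.ones(12), g, cov])).fit()
        red = sm.OLS(y, np.column_stack([np.ones(12), cov])).fit()
        F_oracle = (
            (red.ssr - full.ssr) / 1.0
        ) / (full.ssr / full.df_resid)
        assert res.F == pytest.approx(F_oracle, rel=1e-8)
        assert res.p == pytest.approx(
            stats.f.sf(F_oracle, 1, int(full.df_resid)), rel=1e-8
        )

    def test_identical_groups_give_zero_f(self):
        """Pairwise-identical groups: the group factor explains nothing."""
        ages = [9.0, 12.0, 14.0, 17.0, 21.0, 25.0, 30.0, 34.0, 38.0, 45.0]
        half = make_cohort(ages, [], seed=17)
        twin = half.copy()
        twin["group"] = "CTRL"
        twin["subject_id"] = twin["subject_id"].str.replace("ASD", "CTRL")
        cohort = pd.concat([half, twin], ignore_index=True)
        rng = np.random.default_rng(18)
        y_half = 1400.0 + 2.0 * np.array(ages) + rng.normal(0, 30, len(ages))
        res = global_volume_ancova(np.concatenate([y_half, y_half]), cohort)
        assert res.F == pytest.approx(0.0, abs=1e-6)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_null_calibration_matches_ns_pattern(self):
        """TBV-like volumes with no group effect are non-significant in
        the vast majority of replicates."""
        ns = 0
        for s in range(100):
            cohort = generate_cohort(25, 25, seed=s)
            rng = np.random.default_rng(1000 + s)
            vol = 1370.0 + 0.5 * cohort["age"].to_numpy() + rng.normal(0, 50, 50)
            if global_volume_ancova(vol, cohort).p > 0.05:
                ns += 1
        assert ns >= 85
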
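"""HRF, design construction, per-voxel OLS, and LSS single-trial estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import attnmem as am
from attnmem.glm import (
    censor_columns_from_fd,
    double_gamma_hrf,
    hrf_convolved_regressor,
)
from conftest import make_run, simple_recognition_events


class TestHrf:
    def test_peak_between_4_and_7_seconds(self):
        """Dense numerical evaluation of the double-gamma difference."""
        kernel = double_gamma_hrf(am.HrfParams(), tr=0.01)
        t_peak = np.argmax(kernel) * 0.01
        assert 4.0 <= t_peak <= 7.0
        assert kernel.max() == pytest.approx(1.0)

    def test_huge_ratio_removes_undershoot(self):
        kernel = double_gamma_hrf(am.HrfParams(peak_undershoot_ratio=1e9), tr=0.1)
        assert (kernel >= -1e-12).all()

    def test_convolved_boxcar_is_causal_and_length_preserving(self):
        tr = 2.0
        hrf = double_gamma_hrf(am.HrfParams(), tr)
        reg = hrf_convolved_regressor(np.array([20.0]), np.array([2.0]), 50, tr, hrf)
        assert len(reg) == 50
        assert np.allclose(reg[: int(20.0 / tr)], 0.0)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(am.ValidationError):
            am.HrfParams(peak_delay=-1.0)
        with pytest.raises(am.ValidationError):
            double_gamma_hrf(am.HrfParams(), tr=0.0)


class TestBuildDesign:
    def _events(self):
        return pd.DataFrame(dict(
            onset=[0.0, 24.0, 48.0], condition=["prospective", "baseline",
                                                "prospective"],
            is_catch=[False, False, True]))

    def test_no_high_fd_means_no_censor_columns(self):
        run = make_run(np.zeros((4, 40)))
        design = am.build_design(self._events(), run)
        assert design.censor_columns == []

    def test_three_fd_spikes_make_three_one_hot_columns(self):
        fd = 0.05 * np.ones(40)
        fd[[7, 19, 33]] = 0.45
        run = make_run(np.random.default_rng(0).standard_normal((4, 40)), fd=fd)
        design = am.build_design(self._events(), run)
        assert len(design.censor_columns) == 3
        for c in design.censor_columns:
            col = design.matrix[c].to_numpy()
            assert col.sum() == 1.0 and set(np.unique(col)) == {0.0, 1.0}

    def test_fd_exactly_at_threshold_is_not_censored(self):
        assert censor_columns_from_fd(np.array([0.0, 0.3, 0.31])).keys() == {
            "censor_0002"}

    def test_single_event_column_is_hrf_convolved_boxcar(self):
        run = make_run(np.zeros((4, 40)))
        ev = pd.DataFrame(dict(onset=[0.0], condition=["a"], is_catch=[False]))
        design = am.build_design(ev, run, epoch_duration=8.0)
        hrf = double_gamma_hrf(am.HrfParams(), 2.0)
        expected = hrf_convolved_regressor(np.array([0.0]), np.array([8.0]),
                                           40, 2.0, hrf)
        np.testing.assert_allclose(design.matrix["a"], expected)

    def test_event_past_run_end_raises(self):
        run = make_run(np.zeros((4, 10)))
        ev = pd.DataFrame(dict(onset=[18.0], condition=["a"], is_catch=[False]))
        with pytest.raises(am.ValidationError):
            am.build_design(ev, run)

    def test_missing_condition_omitted_with_warning(self):
        run = make_run(np.zeros((4, 40)))
        with pytest.warns(UserWarning, match="column omitted"):
            design = am.build_design(self._events(), run,
                                     conditions=["prospective", "retrospective"])
        assert "retrospective" not in design.matrix.columns
        assert design.warnings


class TestFitGlm:
    def test_noiseless_exact_coefficient_recovery(self):
        rng = np.random.default_rng(3)
        run = make_run(rng.standard_normal((5, 60)))
        ev = pd.DataFrame(dict(onset=[0.0, 40.0], condition=["a", "b"],
                               is_catch=[False, False]))
        design = am.build_design(ev, run, epoch_duration=8.0)
        X = design.values
        B_true = rng.standard_normal((X.shape[1], 5))
        run_exact = make_run((X @ B_true).T, fd=run.fd, motion=run.motion)
        result = am.fit_glm(design, run_exact)
        np.testing.assert_allclose(result.coefficients, B_true, atol=1e-9)

    def test_pure_noise_tstats_follow_student_t(self):
        """KS test of the empirical t distribution over many voxels."""
        rng = np.random.default_rng(4)
        n_vols, n_vox = 80, 10_000
        run = make_run(rng.standard_normal((n_vox, n_vols)))
        ev = pd.DataFrame(dict(onset=[10.0, 60.0], condition=["a", "a"],
                               is_catch=[False, False]))
        design = am.build_design(ev, run, epoch_duration=8.0,
                                 include_motion=False)
        result = am.fit_glm(design, run)
        _, p = sps.kstest(result.t("a"), sps.t(df=result.df).cdf)
        assert p > 0.01

    def test_t_invariant_to_voxelwise_rescaling(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((6, 50))
        ev = pd.DataFrame(dict(onset=[8.0], condition=["a"], is_catch=[False]))
        run = make_run(data)
        design = am.build_design(ev, run)
        t0 = am.fit_glm(design, run).t("a")
        scales = np.array([2.0, -3.0, 0.5, 10.0, -0.1, 1.0])
        run2 = make_run(data * scales[:, None], fd=run.fd, motion=run.motion)
        t1 = am.fit_glm(design, run2).t("a")
        np.testing.assert_allclose(t1, t0 * np.sign(scales), atol=1e-9)

    def test_rank_deficiency_names_collinear_columns(self):
        run = make_run(np.random.default_rng(0).standard_normal((4, 30)))
        ev = pd.DataFrame(dict(onset=[0.0, 0.0], condition=["a", "b"],
                               is_catch=[False, False]))
        design = am.build_design(ev, run)  # identical onsets -> identical columns
        with pytest.raises(am.ValidationError, match="collinear"):
            am.fit_glm(design, run)


class TestLss:
    def _spaced_data(self, n_trials=6, gap=40.0, noise=0.1, seed=1, n_vox=20):
        rng = np.random.default_rng(seed)
        onsets = np.arange(n_trials) * gap + 10.0
        n_vols = int((onsets[-1] + 30.0) / 2.0)
        events = simple_recognition_events(onsets)
        hrf = double_gamma_hrf(am.HrfParams(), 2.0)
        X = np.stack([hrf_convolved_regressor(np.array([o]), np.array([2.0]),
                                              n_vols, 2.0, hrf) for o in onsets],
                     axis=1)
        amplitudes = rng.standard_normal((n_trials, n_vox))
        Y = X @ amplitudes + noise * rng.standard_normal((n_vols, n_vox))
        return events, X, amplitudes, Y

    def test_single_trial_run_reduces_to_plain_glm(self):
        events, X, amp, Y = self._spaced_data(n_trials=1)
        run = make_run(Y.T)
        pats = am.lss_single_trial(events, [run])
        ev = pd.DataFrame(dict(onset=events.picture_onset, condition=["target"],
                               is_catch=[False]))
        design = am.build_design(ev, run, epoch_duration=2.0)
        plain = am.fit_glm(design, run)
        np.testing.assert_allclose(pats[0].values, plain.t("target"), atol=1e-9)

    def test_lss_equals_brute_force_full_glm_on_nonoverlapping_design(self):
        """Oracle equivalence: with disjoint regressor support and a shared
        (empty) nuisance space, each LSS target beta equals the corresponding
        column of the all-trials GLM solved by normal equations."""
        events, X, amp, Y = self._spaced_data()
        run = make_run(Y.T)
        pats = am.lss_single_trial(events, [run], include_intercept=False,
                                   include_motion=False)
        B_full = np.linalg.solve(X.T @ X, X.T @ Y)  # brute-force normal equations
        hrf = double_gamma_hrf(am.HrfParams(), 2.0)
        for k, pat in enumerate(pats):
            cols = [X[:, k], X[:, [j for j in range(X.shape[1]) if j != k]].sum(1)]
            Xl = np.stack(cols, axis=1)
            beta_lss = np.linalg.solve(Xl.T @ Xl, Xl.T @ Y)[0]
            np.testing.assert_allclose(beta_lss, B_full[k], atol=1e-8)
            # and the package's own t-map ranks voxels like the true amplitudes
            assert sps.spearmanr(pat.values, amp[k]).statistic > 0.9

    def test_lss_recovers_per_trial_amplitudes(self):
        """Widely spaced trials, low noise: per-trial estimates track the
        generative amplitudes (rank correlation > 0.95)."""
        rng = np.random.default_rng(7)
        n_trials = 12
        onsets = np.arange(n_trials) * 30.0 + 10.0
        n_vols = int((onsets[-1] + 30.0) / 2.0)
        events = simple_recognition_events(onsets)
        hrf = double_gamma_hrf(am.HrfParams(), 2.0)
        pattern = rng.standard_normal(25)
        scales = rng.uniform(0.5, 2.0, n_trials)
        X = np.stack([hrf_convolved_regressor(np.array([o]), np.array([2.0]),
                                              n_vols, 2.0, hrf) for o in onsets], 1)
        Y = X @ np.outer(scales, pattern) + 0.05 * rng.standard_normal((n_vols, 25))
        pats = am.lss_single_trial(events, [make_run(Y.T)])
        est = [p.values @ pattern for p in pats]
        assert sps.spearmanr(est, scales).statistic > 0.95

    def test_two_overlapping_equal_trials_get_equal_estimates(self):
        rng = np.random.default_rng(8)
        onsets = np.array([20.0, 26.0])
        n_vols = 40
        events = simple_recognition_events(onsets)
        hrf = double_gamma_hrf(am.HrfParams(), 2.0)
        X = np.stack([hrf_convolved_regressor(np.array([o]), np.array([2.0]),
                                              n_vols, 2.0, hrf) for o in onsets], 1)
        pattern = rng.standard_normal(15)
        Y = X @ np.outer([1.0, 1.0], pattern)
        # noiseless, so compare beta series (t is 0/0 with zero residuals)
        pats = am.lss_single_trial(events, [make_run(Y.T)], include_motion=False,
                                   statistic="beta")
        np.testing.assert_allclose(pats[0].values, pats[1].values, atol=1e-8)

    def test_perturbing_censored_volume_changes_nothing(self):
        events, X, amp, Y = self._spaced_data()
        n_vols = Y.shape[0]
        fd = 0.02 + 0.03 * np.random.default_rng(2).random(n_vols)
        fd[0] = 0.0
        fd[26] = 0.8  # off any target's 2-s epoch, so no pattern goes missing
        run_a = make_run(Y.T, fd=fd)
        Y2 = Y.copy()
        Y2[26] += 500.0
        run_b = make_run(Y2.T, fd=fd)
        pats_a = am.lss_single_trial(events, [run_a])
        pats_b = am.lss_single_trial(events, [run_b])
        for a, b in zip(pats_a, pats_b):
            np.testing.assert_allclose(a.values, b.values, atol=1e-7)

    def test_fully_censored_target_is_flagged_missing(self):
        events, X, amp, Y = self._spaced_data()
        n_vols = Y.shape[0]
        fd = 0.02 + 0.03 * np.random.default_rng(2).random(n_vols)
        fd[0] = 0.0
        target_vol = int(events.picture_onset.iloc[0] / 2.0)
        fd[target_vol] = 0.9  # the 2-s epoch spans exactly this volume
        pats = am.lss_single_trial(events, [make_run(Y.T, fd=fd)])
        assert pats[0].missing and pats[0].values is None
        assert not pats[1].missing

    def test_foils_and_no_response_get_their_own_regressors(self):
        onsets = np.arange(6) * 30.0 + 10.0
        is_old = np.array([True, True, False, True, False, True])
        events = simple_recognition_events(onsets, is_old=is_old)
        rng = np.random.default_rng(9)
        n_vols = int((onsets[-1] + 30.0) / 2.0)
        run = make_run(rng.standard_normal((10, n_vols)))
        pats = am.lss_single_trial(events, [run],
                                   no_response_items={"item_05"})
        # targets = old responded trials only
        assert {p.trial_id for p in pats} == {"item_00", "item_01", "item_03"}
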
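"""Normalization chain, phase-volume selection, classifiers and evidence roles."""

import numpy as np
import pandas as pd
import pytest

import attnmem as am
from attnmem.decoding import CLASSES, standardize_run
from conftest import make_run


class TestNormalizeChain:
    def test_volume_zscore_property_after_step_two(self):
        """Direct recomputation: after the per-volume step every volume has
        mean 0 and SD 1 across voxels."""
        rng = np.random.default_rng(0)
        run = make_run(rng.standard_normal((40, 100)) * 3.0 + 1.0)
        z = standardize_run(run)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_final_taskwise_voxel_zscore(self):
        rng = np.random.default_rng(1)
        runs = [make_run(rng.standard_normal((20, 60)), run=r) for r in range(2)]
        sel = pd.DataFrame(dict(run=[0] * 10 + [1] * 10,
                                volumes=[(v,) for v in range(10)] * 2,
                                label="x", sample_id=range(20), phase="enc"))
        vol = am.normalize_chain(runs, sel, task="t")
        np.testing.assert_allclose(vol.data.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(vol.data.std(axis=0), 1.0, atol=1e-9)

    def test_chain_is_idempotent_on_its_fixed_point(self):
        """Re-running the per-run standardization on already-standardized data
        changes nothing (to 1e-9)."""
        rng = np.random.default_rng(2)
        run = make_run(rng.standard_normal((30, 80)))
        z1 = standardize_run(run)
        # iterate to the fixed point of the two z-steps
        cur = z1.T
        for _ in range(60):
            cur = standardize_run(make_run(cur, fd=run.fd, motion=run.motion)).T
        fixed = standardize_run(make_run(cur, fd=run.fd, motion=run.motion)).T
        np.testing.assert_allclose(fixed, cur, atol=1e-9)

    def test_constant_voxel_maps_to_zeros_with_warning(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((10, 50))
        data[4] = 7.7
        with pytest.warns(UserWarning, match="constant"):
            z = standardize_run(make_run(data))
        # that voxel contributes 0 before the across-voxel step
        assert np.isfinite(z).all()

    def test_too_few_selected_volumes_rejected(self):
        run = make_run(np.random.default_rng(0).standard_normal((10, 50)))
        sel = pd.DataFrame(dict(run=[0], volumes=[(3,)], label=["x"],
                                sample_id=[0], phase=["enc"]))
        with pytest.raises(am.ValidationError):
            am.normalize_chain([run], sel)


class TestSelection:
    def test_encoding_volume_is_third_tr_after_picture_onset(self, small_config):
        """Enumeration against a hand-built timeline: trial onset at volume
        6i, picture at 6i+1, encoding selection at 6i+3."""
        ev = am.attention_design(small_config, 0)
        sel = am.attention_selection(ev, small_config, "encoding")
        for row in sel.itertuples():
            trial = ev[(ev.run == row.run) & (ev.trial_index == row.trial_index)]
            v0 = int(trial.onset.iloc[0] / small_config.tr_seconds)
            assert row.volumes == (v0 + 1 + 2,)

    def test_maintenance_volumes_cover_8_to_12s_of_trial(self, small_config):
        ev = am.attention_design(small_config, 0)
        sel = am.attention_selection(ev, small_config, "maintenance")
        for row in sel.itertuples():
            trial = ev[(ev.run == row.run) & (ev.trial_index == row.trial_index)]
            v0 = int(trial.onset.iloc[0] / small_config.tr_seconds)
            assert row.volumes == (v0 + 4, v0 + 5)

    def test_per_tr_mode_emits_four_records_per_trial(self, small_config):
        ev = am.attention_design(small_config, 0)
        sel = am.attention_selection(ev, small_config, "per-tr")
        n_trials = (~ev.is_catch).sum()
        assert len(sel) == 4 * n_trials
        assert set(sel.phase) == {"TR0", "TR1", "TR2", "TR3"}

    def test_localizer_selection_counts_conserved(self, default_config):
        ev = am.localizer_design(default_config, 0)
        sel = am.localizer_selection(ev, default_config.tr_seconds)
        assert len(sel) == len(ev)  # one selected volume per stimulus
        per_block = sel[sel.label != "rest"].groupby(
            [sel.run, sel.sample_id.str.extract(r"_(\d+)_\d+$", expand=False)]
        ).size()
        assert (per_block == default_config.pictures_per_block).all()

    def test_off_grid_onset_raises_naming_trial(self, small_config):
        ev = am.attention_design(small_config, 0).copy()
        ev.loc[0, "onset"] = 1.0
        with pytest.raises(am.ValidationError, match="TR grid"):
            am.attention_selection(ev, small_config, "encoding")


class TestClassifier:
    def test_separable_toy_problem_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(4)
        centers = {"face": (4, 0), "scene": (-4, 0), "object": (0, 4),
                   "rest": (0, -4)}
        X, y = [], []
        for label, c in centers.items():
            X.append(np.array(c) + 0.1 * rng.standard_normal((10, 2)))
            y += [label] * 10
        X = np.vstack(X)
        model = am.train_classifier(X, np.array(y), C=1.0)
        assert (model.predict(X) == np.array(y)).mean() == 1.0

    def test_missing_class_raises_with_names(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        y = np.array(["face"] * 10 + ["scene"] * 10)
        with pytest.raises(am.ValidationError, match="object"):
            am.train_classifier(X, y)

    def test_duplicating_data_equals_doubling_penalty_constant(self):
        """Loss-scaling oracle: the data-fit term scales with duplication, so
        duplicated data at C equals original data at 2C."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 6))
        y = np.array((["face", "scene", "object", "rest"] * 10))
        m_dup = am.train_classifier(np.vstack([X, X]), np.concatenate([y, y]), C=0.01)
        m_2c = am.train_classifier(X, y, C=0.02)
        np.testing.assert_allclose(m_dup.weights, m_2c.weights, atol=1e-4)

    def test_probability_renormalization_sums_to_one(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 5))
        y = np.array((["face", "scene", "object", "rest"] * 8)[:30])
        # pad to ensure >=2 per class
        y[:4] = ["face", "scene", "object", "rest"]
        model = am.train_classifier(X[:28], y[:28], C=0.01)
        p = model.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_raw_outputs_renormalize_to_quarter(self):
        model = am.ClassifierModel(classes=CLASSES, weights=np.zeros((4, 5)),
                                   intercepts=np.zeros(4))
        p = model.predict_proba(np.random.default_rng(0).standard_normal((3, 5)))
        np.testing.assert_allclose(p, 0.25)


class TestLoro:
    def _localizer(self, seed, signal):
        # strong-signal condition: prototype SNR well above 1
        cfg = am.SimulationConfig(seed=seed, n_voxels_per_roi=40,
                                  noise_sd=0.25 if signal else 1.0)
        truth = am.GroundTruth(prototype_scale=1.5) if signal else am.GroundTruth(
            prototype_scale=0.0, item_scale=0.0)
        ev, runs = am.simulate_task_runs(cfg, truth, "localizer", subject=0,
                                         rois=["VTC"])
        sel = am.localizer_selection(ev, cfg.tr_seconds)
        return runs["VTC"], sel

    def test_three_runs_give_three_folds(self):
        runs, sel = self._localizer(1, signal=True)
        res = am.loro_cross_validate(runs, sel)
        assert len(res["fold_accuracies"]) == 3

    def test_strong_signal_decodes_far_above_chance(self):
        # hemodynamic overlap at block boundaries caps accuracy near 87%
        # under this timing even at very high SNR; chance is 25%
        runs, sel = self._localizer(2, signal=True)
        res = am.loro_cross_validate(runs, sel)
        assert res["mean_accuracy"] > 0.85

    def test_two_runs_minimum(self):
        runs, sel = self._localizer(1, signal=True)
        with pytest.raises(am.ValidationError):
            am.loro_cross_validate(runs[:1], sel[sel.run == 0])


@pytest.fixture(scope="module")
def records():
    cfg = am.SimulationConfig(seed=8, n_voxels_per_roi=40,
                              trials_per_attention_run=6)
    truth = am.GroundTruth()
    levs, lruns = am.simulate_task_runs(cfg, truth, "localizer", subject=0,
                                        rois=["VTC"])
    aevs, aruns = am.simulate_task_runs(cfg, truth, "attention", subject=0,
                                        rois=["VTC"])
    lsel = am.localizer_selection(levs, cfg.tr_seconds)
    lvol = am.normalize_chain(lruns["VTC"], lsel, task="localizer")
    model = am.train_classifier(lvol.data, lvol.meta.label.to_numpy())
    asel = am.attention_selection(aevs, cfg, "encoding")
    avol = am.normalize_chain(aruns["VTC"], asel, task="attention")
    return am.apply_and_sort(model, avol)


class TestEvidenceRoles:
    def test_role_probabilities_conserve_mass(self, records):
        total = records[["attended", "ignored", "other", "rest"]].fillna(0).sum(1)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_baseline_trials_have_no_ignored_role(self, records):
        base = records[records.condition == "baseline"]
        assert base.ignored.isna().all()
        assert base.attended.notna().all()

    def test_voxel_permutation_invariance(self):
        """Permuting voxels consistently in training and test leaves all
        evidence unchanged."""
        rng = np.random.default_rng(9)
        X_train = rng.standard_normal((40, 12))
        y = np.array((["face", "scene", "object", "rest"] * 10))
        X_test = rng.standard_normal((8, 12))
        perm = rng.permutation(12)
        m1 = am.train_classifier(X_train, y, C=0.01)
        m2 = am.train_classifier(X_train[:, perm], y, C=0.01)
        np.testing.assert_allclose(m1.predict_proba(X_test),
                                   m2.predict_proba(X_test[:, perm]), atol=1e-8)

    def test_identical_evidence_yields_zero_contrasts(self):
        rows = []
        for cond, att, ign in (("prospective", "PA_face_00", "PI_scene_00"),
                               ("retrospective", "RA_face_00", "RI_scene_00")):
            for k in range(2):
                rows.append(dict(subject=0, roi="VTC", trial=f"{cond}_{k}",
                                 phase="encoding", condition=cond,
                                 item_attended=att, item_ignored=ign,
                                 attended=0.25, ignored=0.25, other=0.25,
                                 rest=0.25))
        contrasts = am.evidence_contrasts(pd.DataFrame(rows))
        assert np.allclose(contrasts.value, 0.0)
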
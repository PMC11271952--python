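import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import attnmem as am

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 6 non-catch attention trials per run, 30 voxels."""
    return am.SimulationConfig(n_subjects=4, n_voxels_per_roi=30,
                               trials_per_attention_run=6, seed=11)


@pytest.fixture(scope="session")
def default_config():
    return am.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_truth():
    return am.GroundTruth()


@pytest.fixture(scope="session")
def behavior_table(default_config, default_truth):
    return am.simulate_behavior(default_config, default_truth,
                                subjects=range(6))


def make_run(data, tr=2.0, fd=None, motion=None, run=0, roi="VTC"):
    """BoldRun around a (voxels x time) array with benign nuisance traces."""
    n_t = data.shape[1]
    rng = np.random.default_rng(99)
    if motion is None:
        motion = 0.01 * rng.standard_normal((6, n_t))
    if fd is None:
        fd = 0.01 + 0.02 * rng.random(n_t)
        fd[0] = 0.0
    return am.BoldRun(roi=roi, run=run, data=np.asarray(data, float),
                      tr_seconds=tr, motion=motion, fd=fd)


def simple_recognition_events(onsets, run=0, is_old=None):
    onsets = np.asarray(onsets, dtype=float)
    if is_old is None:
        is_old = np.ones(len(onsets), bool)
    return pd.DataFrame(dict(
        run=run, item_id=[f"item_{k:02d}" for k in range(len(onsets))],
        is_old=is_old, picture_onset=onsets, onset=onsets - 2.0))
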
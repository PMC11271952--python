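"""Least-squares-separate single-trial estimation on the recognition test.

Simulates one subject's recognition-test BOLD runs, estimates a t-map per
old trial by LSS (target regressor + all-other-trials regressor + foil and
nuisance regressors, FD > 0.3 mm volumes censored), and checks how well the
estimated patterns recover the generative retrieval patterns.
"""

import numpy as np

import attnmem as am
from attnmem.simulate import recognition_patterns

config = am.SimulationConfig(seed=5)
truth = am.GroundTruth()
roi = "vLPC"

events, runs = am.simulate_task_runs(config, truth, "recognition", subject=0,
                                     rois=[roi])
patterns = am.lss_single_trial(events, runs[roi])

n_missing = sum(p.missing for p in patterns)
print(f"Estimated {len(patterns)} single-trial t-maps in {roi}; "
      f"{n_missing} flagged missing (target epoch fully censored).")

truth_maps = recognition_patterns(config, truth, 0)[roi]
correlations = [np.corrcoef(p.values, truth_maps[p.trial_id])[0, 1]
                for p in patterns if not p.missing]
print(f"Pattern recovery: mean r = {np.mean(correlations):.3f} "
      f"(min {np.min(correlations):.3f}) between LSS t-maps and the "
      f"generative retrieval patterns.")
print("Read: despite overlapping hemodynamic responses every 6 s, the "
      "per-trial estimates track each item's true voxel pattern, which is "
      "what the pair-similarity analysis consumes.")
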
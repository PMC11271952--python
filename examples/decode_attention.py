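"""Localizer-trained classifier evidence in the attention task.

For one simulated subject: train the 4-class one-vs-rest logistic classifier
(C = 0.01) on z-scored localizer volumes, report leave-one-run-out accuracy,
then decode the attention task's encoding and maintenance phases and sort
class probabilities into attended / ignored / other roles.
"""

import pandas as pd

import attnmem as am

config = am.SimulationConfig(seed=3)
truth = am.GroundTruth()
roi = "VTC"

loc_events, loc_runs = am.simulate_task_runs(config, truth, "localizer",
                                             subject=0, rois=[roi])
att_events, att_runs = am.simulate_task_runs(config, truth, "attention",
                                             subject=0, rois=[roi])

selection = am.localizer_selection(loc_events, config.tr_seconds)
cv = am.loro_cross_validate(loc_runs[roi], selection)
print(f"Leave-one-run-out accuracy in {roi}: {cv['mean_accuracy']:.1%} "
      f"(chance 25%)")

volumes = am.normalize_chain(loc_runs[roi], selection, task="localizer")
model = am.train_classifier(volumes.data, volumes.meta.label.to_numpy())

records = []
for phase in ("encoding", "maintenance"):
    sel = am.attention_selection(att_events, config, phase)
    vols = am.normalize_chain(att_runs[roi], sel, task="attention")
    records.append(am.apply_and_sort(model, vols))
records = pd.concat(records, ignore_index=True)

cells, _ = am.evidence_cell_means(records)
print("\nMean classifier evidence per cue-attention condition:")
print(cells.pivot_table(index="phase", columns="cue_attention",
                        values="evidence").round(3).to_string())
print("\nRead: evidence for the attended category (PA/RA) exceeds the "
      "ignored (PI/RI) and unpresented ('other': PO/RO/BO) categories; the "
      "attended-ignored gap is larger with a pre-stimulus (prospective) cue.")
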
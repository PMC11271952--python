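"""Behavioral memory measures on a simulated cohort.

Simulates recognition responses for 20 subjects under the default ground
truth (strong prospective filtering, weaker retrospective filtering), then
computes hit rates, confidence for remembered items, attentional modulation
and memory capacity, with within-subject error bars and the two headline
group contrasts.
"""

import attnmem as am

config = am.SimulationConfig(seed=7)
truth = am.GroundTruth()
table = am.simulate_behavior(config, truth, subjects=range(20))

rates = am.hit_and_fa_rates(table)
modulation = am.attentional_modulation(rates)
capacity = am.memory_capacity(rates)

print("Group-mean hit rates (BL/PA/PI/RA/RI) and false alarms:")
print(rates.mean().round(3).to_string())

summary = am.behavioral_summary(table)
wse = am.within_subject_sem(summary[summary.measure == "hit_rate"],
                            condition="condition")
print("\nWithin-subject SEM of the hit rates per condition:")
print(wse.round(3).to_string())

t_mod = am.paired_t(modulation["prospective"], modulation["retrospective"])
t_cap = am.paired_t(capacity["prospective"], capacity["retrospective"])
print(f"\nAttentional modulation, prospective vs retrospective: "
      f"t({t_mod.df}) = {t_mod.statistic:.2f}, p = {t_mod.p_raw:.4g}")
print(f"Memory capacity, prospective vs retrospective:        "
      f"t({t_cap.df}) = {t_cap.statistic:.2f}, p = {t_cap.p_raw:.4g}")
print("\nRead: cueing before encoding filters the distractor far better "
      "(larger modulation), while the total number of items retained "
      "(capacity) is similar across cue types.")
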
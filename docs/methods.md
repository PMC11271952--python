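# Methods

`attnmem` implements, on fully synthetic data, the analysis chain of a
selective-attention fMRI experiment: a cued attention task over pairs of
category pictures (faces, scenes, objects), a next-day recognition test, a
block-design category localizer, classifier-evidence decoding of attended
and ignored categories, single-trial response estimation at retrieval, and
pair-specific pattern-similarity ("repulsion") analysis. This note records
the generative model, the analysis conventions, and the design choices made
where the problem was genuinely open.

## Task designs

**Attention task.** Each trial is an 8-s epoch on a TR = 2 s grid: 1-s
fixation, 1-s cue, 2-s encoding (two pictures left/right, or one for
baseline), 4-s maintenance, followed by a 4-s inter-trial gap (12 s per
trial slot). Three cue conditions: *prospective* (informative cue before the
pictures), *retrospective* (informative cue only at maintenance), and
*baseline* (single picture). Default: 30 non-catch trials per run, 10 per
cue condition, 6 runs. This reproduces the reference item counts exactly:
30 items per cue-attention condition (BL, PA, PI, RA, RI; 150 learning
items), each picture presented twice, on opposite sides, in different runs,
under the same attention status, paired each time with a picture from a
different category. One-sixth of trials are catch trials (probe after
maintenance); they are flagged and excluded from every analysis. Catch
counts per run are `floor(catch_fraction x total trials)`.

The pairing schedule is deterministic: attended item *k* of category *c* is
paired on its first presentation (left side, first half of the runs) with
ignored item *k* of category *c+1*, and on its second presentation (right
side, second half of the runs) with ignored item *k* of category *c+2*
(indices mod 3). This guarantees every invariant above by construction
while leaving trial order within a run to a seeded shuffle.

**Localizer.** 9 mini-blocks per run (3 per category), 10 pictures x 2 s
per block, separated by 8-s Gabor blocks (4 Gabors x 2 s); 3 runs.
Localizer picture identities are run-specific so that cross-validated
decoding reflects category information, not item memory.

**Recognition test.** All 150 old items plus 150 novel foils in a seeded
pseudorandom order over 4 runs; each 6-s trial is a 2-s fixation plus a 4-s
picture. Responses use the 4-point scale (1 definitely old ... 4 definitely
novel).

## Generative BOLD model

Each picture event contributes an HRF-convolved boxcar times an attentional
gain times the picture's voxel pattern; runs add Gaussian noise
(`noise_sd`, default 1.0 signal units) and motion-correlated nuisance. A
picture's pattern is its category prototype (random unit direction scaled
to norm `sqrt(n_voxels)`, default scale 1.0) plus a fixed item-specific
component (`item_scale` 0.5), drawn per subject and stable across tasks so
that item identity is decodable in principle. Boxcars are sampled on the TR
grid (all onsets fall on it) and convolved with the canonical double-gamma
HRF (peak 6 s, undershoot 16 s, dispersions 1 s, ratio 6, 32-s kernel).

Gains per cue-attention condition (defaults: PA 1.0, PI 0.3, RA 0.8, RI
0.55, BL 1.0) may be scalars or per-ROI maps; the ROI map is how
distractor-filtering dissociations between visual and parietal ROIs are
injected. In the retrospective condition the effective cue arrives only at
maintenance, so both pictures carry the mean of the RA/RI gains during
encoding (divided attention); the reference experiment reports comparable
attended/ignored evidence there but no rates, so the equal-split is this
package's choice.

Motion is a 6-parameter AR(1) walk with occasional jump steps;
framewise displacement (FD) is the summed absolute parameter step, so the
jumps produce occasional FD values above the 0.3 mm censoring threshold and
the censoring path is always exercised.

**Retrieval patterns and repulsion.** Every old item's retrieval pattern is
a subject x ROI global component (`retrieval_global_scale` 1.0, the common
activation pattern that real single-trial t-maps share — without it, mean
pairwise similarity would be zero and a shrinkage manipulation could not
move it) plus its prototype and item component. Repulsion is injected at
retrieval only: each ignored item's pattern has its projection onto the
span of its attended partners' raw patterns shrunk by `1 - rho` for the
trial's cue condition. Shrinking along the partner's direction reduces the
covariance with that specific partner by exactly `1 - rho` while leaving
covariance with non-partners nearly intact; `rho = 1` makes the pair
exactly orthogonal. Shrinking only the ignored member (rather than both
symmetrically) is what preserves that exact-orthogonality property, and
matches the observation that it is the less-attended item's representation
that differentiates. A `repel_attended` flag applies the shrinkage to both
members.

**Behavior.** Responses are Bernoulli draws: old items are judged old with
the condition's hit mean (defaults BL .80, PA .80, PI .35, RA .70, RI .55 —
the qualitative ordering of the reference results: prospective filtering
enhances targets and suppresses distractors more than retrospective, with
near-equal overall capacity), novel items with the false-alarm rate (.15).
Given a hit, high confidence (response 1) is drawn with a per-condition
probability ordered PA = BL > RA; other confidences split evenly. Memory
responses are drawn independently of the neural patterns; brain-behavior
couplings are therefore null unless a test injects them explicitly.

## Analysis conventions

**Behavioral measures.** Hit = response 1 or 2 on an old item; false alarm
= 1 or 2 on a foil. Confidence is scored 2 ("definitely") or 1 ("probably")
and reported for hits only. Attentional modulation = hit(attended) -
hit(ignored). Memory capacity = hit(attended) + hit(ignored) - 2·FA
(two-item conditions, maximum 2) or hit(baseline) - FA (baseline, maximum
1), unclipped. Missing responses leave both numerator and denominator; an
empty cell is a missing value, never zero.

**GLM / LSS.** Per-voxel OLS with t = beta / SE, df = timepoints - rank.
Nuisance columns: 6 motion parameters + FD; one one-hot censor column per
volume with FD strictly above 0.3 mm (equality is not censored), which
makes censored volumes' data values provably irrelevant. Single-trial
estimation is least-squares-separate: per target trial, one target
regressor, one all-other-old-trials regressor, foil and no-response
regressors, nuisance and censor columns; the target column's t-map is the
trial's pattern. The 2-s retrieval epoch is anchored at picture onset (the
trial description — 2-s fixation then 4-s picture — makes "2-s epoch"
ambiguous; a pre-stimulus window would carry no stimulus-locked signal, so
onset anchoring is the defensible reading; `epoch_anchor="fixation"` gives
the alternative). A target whose epoch volumes are all censored yields a
pattern flagged missing. LSS equals the all-trials GLM exactly on designs
with disjoint regressor support *and the same nuisance space*; with a
shared intercept the residualizing spaces differ slightly, so the oracle
equivalence test runs both models without intercepts.

**Decoding.** Normalization chain, in order: (1) per-voxel z within run,
(2) per-volume z across voxels, (3) phase-volume selection, (4) per-voxel z
across the selected volumes of the task. Constant voxels/volumes map to
zeros with a warning. Selection: localizer and encoding use the third TR
after picture onset (onset volume + 2, covering 4-6 s post-onset; the
off-by-one alternative is the `lag_volumes` argument); maintenance averages
the two TRs starting 4 s after the second-cue onset, averaging before
classification; per-TR mode emits TR0..TR3 with the same lag. Classifiers:
four binary one-vs-rest L2 logistic regressions (liblinear, C = 0.01, the
convention that C multiplies the data-fit term), classes = 3 picture
categories + Gabor/rest — the fourth class is what makes chance 25%.
Sigmoid outputs are renormalized to sum to 1 (a `pictures` mode restricts
renormalization to the 3 picture categories). Probabilities map to roles by
the trial's categories: attended, ignored (absent for baseline, whose two
unpresented categories fold into "other" to conserve mass), other, rest.
In leave-one-run-out validation the task-wise z parameters (step 4) are
estimated on training runs only; steps 1-2 are per-run and intrinsically
fold-safe. Trial evidence is averaged over a picture's two repetitions
before condition averaging (disable with `average_repetitions=False`).

**RSA.** Within-trial pairs are all co-presented (attended, ignored) item
pairs. Each gets one between-trial control pair, built by swapping one
member for an item never co-presented with the kept member, matched exactly
on category pair, attention statuses, cue condition (flag
`same_condition`), and both members' memory outcomes, with recognition lag
within ±10 trials (configurable) of the within-trial pair's lag; greedy
selection prefers the closest lag with seeded tie-breaking, one-to-one by
default (`mode="average"` averages all candidates). Pairs with no eligible
control are excluded from both sides. Similarity is Pearson r across ROI
voxels, clipped to ±(1 - 1e-7) before Fisher z. The repulsion statistic is
mean z(WT) - mean z(BT) per subject x ROI x condition; group inference is a
paired t across subjects with BH-FDR over ROI x condition cells.
Brain-behavior couplings report Pearson r/p alongside a robust fit (IRLS,
Tukey bisquare, tuning constant 4.685 — the default of the reference
tool), with "memory performance" = mean hit rate of targets and
distractors.

**Group statistics.** Paired t tests (df = n - 1) and fully within-subject
two-way RM-ANOVA by sums-of-squares decomposition with subject x factor
error terms; a single-level factor reduces it to the one-way case, where
F = t². BH-FDR is the step-up rule computed directly (adjusted p of the
k-th smallest = min over j ≥ k of p(j)·m/j). Error bars are within-subject:
Cousineau subject-mean centering with the Morey `sqrt(c/(c-1))` inflation;
a single condition falls back to the plain SEM. Group inference
deliberately uses subject-level summaries rather than mixed-effects models,
so degrees of freedom differ from analyses that pool trials.

## Problem sizes and what the tests show

Default simulations use 60 voxels per ROI, 6 attention runs of 36 trials,
3 localizer runs, 4 recognition runs, and cohorts of 8-24 subjects; these
sizes make every property cheap to verify while preserving the full design
structure. Chance calibration uses 50 seeded signal-free replicates of the
complete normalization + classification chain and checks the mean
leave-one-run-out accuracy against the Monte-Carlo band around 25%.
Parameter-recovery tests check monotone response of the attended-ignored
evidence gap to a 5-point gain grid, the PA>PI / RA>RI ordering, the
PI-PO > 0 dissociation appearing only in the ROI where distractor signal is
injected, monotone WT-BT response to a 4-point repulsion grid, and type-I
control of the WT-BT test over 100 null cohorts.

Because the data are synthetic, passing tests demonstrate that the
implementation recovers what the generative model injects — not that the
scientific claims hold in real brains. The simulator omits, among other
things: anatomy and spatial autocorrelation, scanner drift and physiological
noise (a discrete-cosine drift basis is available but off by default),
behavioral-neural coupling (unless injected), eye movements, and any
difference in HRF shape across regions or subjects. Real-data accuracies
(50-77.5% in comparable ROI decoding) sit far below this simulator's
high-SNR regime, whose block-boundary hemodynamic overlap caps localizer
accuracy near 87% regardless of SNR.

## Numerical choices

- HRF kernel peak-normalized to 1; 32-s support.
- FD censoring is strictly greater than 0.3 mm.
- Zero-variance voxels/volumes z-map to zeros with a warning; zero-variance
  patterns yield missing similarity records.
- Correlations clipped to ±(1 - 1e-7) before atanh.
- Rank-deficient designs raise an error naming the collinear columns
  (pivoted QR); all-zero nuisance traces are dropped rather than fitted.
- RM-ANOVA treats sums of squares below 1e-12 of the total as zero so
  degenerate all-equal inputs give F = 0 rather than 0/0.
- All randomness flows from `SimulationConfig.seed` through
  `numpy.random.default_rng` with fixed stream keys per subject, task and
  item, so regeneration is bit-identical and independent of call order.
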
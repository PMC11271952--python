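"""Seeded synthetic cohorts: task designs, behavioral tables and ROI BOLD runs.

Every generator is deterministic given ``(config.seed, subject)``. Neural
signal follows a linear generative model: each picture event contributes an
HRF-convolved boxcar times an attentional gain times the picture's pattern
(category prototype + fixed item-specific component), on top of Gaussian
noise and motion-correlated nuisance. Repulsion between co-presented items
is injected into the retrieval (recognition-test) patterns only.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    CATEGORIES,
    CUE_ATTENTION_CONDITIONS,
    CUE_CONDITIONS,
    ConfigurationError,
    GroundTruth,
    SimulationConfig,
    ValidationError,
    category_prototypes,
)
from .glm import double_gamma_hrf
from .types import BoldRun, TrialEvent, events_to_frame

_TASK_CODES = {"attention": 1, "localizer": 2, "recognition": 3, "behavior": 4, "motion": 5}


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _rng(config: SimulationConfig, subject: int, task: str) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), subject, _TASK_CODES[task]])


def item_category(item_id: str) -> str:
    """Item ids embed their category, e.g. ``PA_face_03`` or ``foil_scene_11``."""
    for cat in CATEGORIES:
        if f"_{cat}_" in item_id:
            return cat
    raise ValidationError(f"cannot parse category from item id {item_id!r}")


def catch_counts(config: SimulationConfig) -> tuple[int, int]:
    """(total trials, catch trials) per attention run given the catch fraction."""
    n_noncatch = config.trials_per_attention_run
    if config.catch_fraction == 0:
        return n_noncatch, 0
    total = round(n_noncatch / (1.0 - config.catch_fraction))
    n_catch = math.floor(config.catch_fraction * total)
    return n_noncatch + n_catch, n_catch


# ---------------------------------------------------------------------------
# Attention-task design
# ---------------------------------------------------------------------------

def old_item_ids(config: SimulationConfig) -> dict[str, list[str]]:
    """Learning-set item ids per cue-attention condition, balanced over categories."""
    n_per_cond = config.trials_per_attention_run // 3 * config.n_runs_attention // 2
    if n_per_cond % len(CATEGORIES):
        raise ValidationError("items per condition must divide evenly over categories")
    per_cat = n_per_cond // len(CATEGORIES)
    out: dict[str, list[str]] = {}
    for cond in CUE_ATTENTION_CONDITIONS:
        out[cond] = [f"{cond}_{cat}_{k:02d}" for cat in CATEGORIES for k in range(per_cat)]
    return out


def attention_design(config: SimulationConfig, subject: int = 0) -> pd.DataFrame:
    """Build one subject's attention-task events.

    Each picture is presented exactly twice, on opposite sides, in different
    runs, under the same attention status, paired each time with a picture
    from a different category. Catch trials (probe after maintenance) are
    interleaved at ``catch_fraction`` and flagged.
    """
    if config.n_runs_attention % 2:
        raise ValidationError("n_runs_attention must be even (repetitions span run halves)")
    rng = _rng(config, subject, "attention")
    items = old_item_ids(config)
    n_cats = len(CATEGORIES)
    per_cat = len(items["PA"]) // n_cats
    half = config.n_runs_attention // 2
    trials_of_run: dict[int, list[dict]] = {r: [] for r in range(config.n_runs_attention)}

    def paired_trials(att_key: str, ign_key: str, condition: str) -> None:
        # presentation 1: attended item on the left, partner from the next
        # category; presentation 2: right side, partner from the previous one.
        for c in range(n_cats):
            for k in range(per_cat):
                g = c * per_cat + k
                att = f"{att_key}_{CATEGORIES[c]}_{k:02d}"
                for pres, (dcat, side) in enumerate(
                    [((c + 1) % n_cats, "left"), ((c + 2) % n_cats, "right")]
                ):
                    ign = f"{ign_key}_{CATEGORIES[dcat]}_{k:02d}"
                    run = (g % half) + (half if pres else 0)
                    trials_of_run[run].append(
                        dict(condition=condition, attended_category=CATEGORIES[c],
                             ignored_category=CATEGORIES[dcat], attended_side=side,
                             item_attended=att, item_ignored=ign, is_catch=False)
                    )

    paired_trials("PA", "PI", "prospective")
    paired_trials("RA", "RI", "retrospective")
    for c in range(n_cats):
        for k in range(per_cat):
            g = c * per_cat + k
            item = f"BL_{CATEGORIES[c]}_{k:02d}"
            for pres, side in enumerate(["left", "right"]):
                run = (g % half) + (half if pres else 0)
                trials_of_run[run].append(
                    dict(condition="baseline", attended_category=CATEGORIES[c],
                         ignored_category=None, attended_side=side,
                         item_attended=item, item_ignored=None, is_catch=False)
                )

    _, n_catch = catch_counts(config)
    catch_serial = 0
    events: list[TrialEvent] = []
    for run in range(config.n_runs_attention):
        trials = list(trials_of_run[run])
        for _ in range(n_catch):
            cond = CUE_CONDITIONS[rng.integers(len(CUE_CONDITIONS))]
            cat = int(rng.integers(n_cats))
            other = (cat + 1 + int(rng.integers(n_cats - 1))) % n_cats
            trials.append(
                dict(condition=cond, attended_category=CATEGORIES[cat],
                     ignored_category=None if cond == "baseline" else CATEGORIES[other],
                     attended_side="left" if rng.random() < 0.5 else "right",
                     item_attended=f"catch_{CATEGORIES[cat]}_{catch_serial:02d}",
                     item_ignored=None if cond == "baseline"
                     else f"catch_{CATEGORIES[other]}_{catch_serial:02d}b",
                     is_catch=True)
            )
            catch_serial += 1
        order = rng.permutation(len(trials))
        for idx, j in enumerate(order):
            events.append(TrialEvent(subject=subject, run=run, trial_index=idx,
                                     onset=idx * config.epoch_slot, **trials[j]))
    return events_to_frame(events)


# ---------------------------------------------------------------------------
# Localizer and recognition designs
# ---------------------------------------------------------------------------

def localizer_design(config: SimulationConfig, subject: int = 0) -> pd.DataFrame:
    """Block localizer events: mini-blocks of pictures with Gabor blocks between.

    Rows are individual 2-s picture (or Gabor) presentations; ``trial_type``
    is the picture category, or ``rest`` for Gabor stimuli.
    """
    rng = _rng(config, subject, "localizer")
    if config.localizer_blocks_per_run % len(CATEGORIES):
        raise ValidationError("localizer blocks per run must balance over categories")
    rows = []
    block_len = config.pictures_per_block * config.picture_duration
    for run in range(config.n_runs_localizer):
        cats = np.repeat(np.arange(len(CATEGORIES)),
                         config.localizer_blocks_per_run // len(CATEGORIES))
        rng.shuffle(cats)
        t = 0.0
        for b, c in enumerate(cats):
            cat = CATEGORIES[int(c)]
            for p in range(config.pictures_per_block):
                rows.append(dict(subject=subject, run=run, block=b, trial_type=cat,
                                 onset=t + p * config.picture_duration,
                                 duration=config.picture_duration,
                                 item_id=f"loc{run}_{cat}_{b:02d}_{p:02d}"))
            t += block_len
            if b < len(cats) - 1:
                n_gabor = int(config.gabor_block_duration // config.picture_duration)
                for p in range(n_gabor):
                    rows.append(dict(subject=subject, run=run, block=b, trial_type="rest",
                                     onset=t + p * config.picture_duration,
                                     duration=config.picture_duration,
                                     item_id=f"loc{run}_gabor_{b:02d}_{p:02d}"))
                t += config.gabor_block_duration
    return pd.DataFrame(rows)


def recognition_design(
    config: SimulationConfig,
    subject: int = 0,
    attention_events: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Recognition-test order: all old items plus an equal number of foils.

    Each 6-s trial is a 2-s fixation followed by a 4-s picture; order is a
    seeded permutation split over ``n_runs_recognition`` runs.
    """
    rng = _rng(config, subject, "recognition")
    if attention_events is None:
        attention_events = attention_design(config, subject)
    old = sorted(
        set(attention_events.loc[~attention_events.is_catch, "item_attended"])
        | set(attention_events.loc[~attention_events.is_catch, "item_ignored"].dropna())
    )
    per_cat = len(old) // len(CATEGORIES)
    foils = [f"foil_{cat}_{k:03d}" for cat in CATEGORIES for k in range(per_cat)]
    all_items = np.array(old + foils)
    order = rng.permutation(len(all_items))
    slot = 2.0 + 4.0  # fixation + picture
    per_run = math.ceil(len(all_items) / config.n_runs_recognition)
    rows = []
    for pos, j in enumerate(order):
        run, idx = divmod(pos, per_run)
        rows.append(dict(subject=subject, run=run, trial_index=idx, position=pos,
                         item_id=str(all_items[j]), is_old=bool(j < len(old)),
                         onset=idx * slot, picture_onset=idx * slot + 2.0, duration=4.0))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Behavioral simulation
# ---------------------------------------------------------------------------

def simulate_behavior(
    config: SimulationConfig,
    truth: GroundTruth,
    subjects: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Simulate the 4-point old/new recognition responses for a cohort.

    Old items are judged old (response 1 or 2) with the condition's hit mean,
    novel items with the false-alarm rate; given a hit, high confidence
    (response 1) is drawn with the condition's high-confidence probability.
    """
    for cond in CUE_ATTENTION_CONDITIONS:
        truth.hit_mean(cond)  # raises ConfigurationError if missing
    if subjects is None:
        subjects = range(config.n_subjects)
    items = old_item_ids(config)
    # one foil per old item, balanced over categories
    n_old = sum(len(v) for v in items.values())
    foils = [f"foil_{cat}_{k:03d}" for cat in CATEGORIES for k in range(n_old // len(CATEGORIES))]
    status_of = {"PA": "attended", "RA": "attended", "BL": "attended",
                 "PI": "ignored", "RI": "ignored"}
    cue_of = {"PA": "prospective", "PI": "prospective",
              "RA": "retrospective", "RI": "retrospective", "BL": "baseline"}
    rows = []
    for s in subjects:
        rng = _rng(config, s, "behavior")
        for cond in CUE_ATTENTION_CONDITIONS:
            p_hit = truth.hit_mean(cond)
            p_high = float(truth.confidence_high_prob.get(cond, 0.5))
            for item in items[cond]:
                resp: float
                if truth.no_response_prob and rng.random() < truth.no_response_prob:
                    resp = np.nan
                elif rng.random() < p_hit:
                    resp = 1.0 if rng.random() < p_high else 2.0
                else:
                    resp = 4.0 if rng.random() < 0.5 else 3.0
                rows.append(dict(subject=s, item=item, cue_condition=cue_of[cond],
                                 attention_status=status_of[cond], cue_attention=cond,
                                 response=resp))
        for item in foils:
            if truth.no_response_prob and rng.random() < truth.no_response_prob:
                resp = np.nan
            elif rng.random() < truth.false_alarm_rate:
                resp = 1.0 if rng.random() < 0.5 else 2.0
            else:
                resp = 4.0 if rng.random() < 0.5 else 3.0
            rows.append(dict(subject=s, item=item, cue_condition="novel",
                             attention_status="none", cue_attention="novel",
                             response=resp))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Voxel patterns
# ---------------------------------------------------------------------------

@dataclass
class SubjectPatterns:
    """Per-subject ground-truth voxel patterns: prototypes + item components."""

    subject: int
    seed: int
    prototypes: dict[str, np.ndarray]  # roi -> (n_categories + 1, n_voxels); last row rest
    item_scale: float
    roi_names: tuple[str, ...]
    n_voxels: int

    def item_component(self, roi: str, item_id: str) -> np.ndarray:
        """Fixed item-specific pattern, reproducible independent of call order."""
        r = np.random.default_rng(
            [self.seed % (2**31), self.subject, _stable_hash(item_id) % (2**31),
             _stable_hash(roi) % (2**31)]
        )
        return self.item_scale * r.standard_normal(self.n_voxels)

    def item_pattern(self, roi: str, item_id: str) -> np.ndarray:
        cat_idx = CATEGORIES.index(item_category(item_id))
        return self.prototypes[roi][cat_idx] + self.item_component(roi, item_id)

    def rest_pattern(self, roi: str) -> np.ndarray:
        return self.prototypes[roi][-1]

    def global_pattern(self, roi: str, scale: float) -> np.ndarray:
        """Subject x ROI component shared by all retrieval patterns."""
        r = np.random.default_rng(
            [self.seed % (2**31), self.subject, _stable_hash(roi) % (2**31), 13])
        return scale * r.standard_normal(self.n_voxels)


def draw_subject_patterns(
    config: SimulationConfig, truth: GroundTruth, subject: int = 0
) -> SubjectPatterns:
    rng = np.random.default_rng([config.seed % (2**31), subject, 7])
    protos = category_prototypes(rng, config.roi_names, config.n_voxels_per_roi,
                                 config.n_categories, scale=truth.prototype_scale)
    return SubjectPatterns(subject=subject, seed=config.seed, prototypes=protos,
                           item_scale=truth.item_scale,
                           roi_names=tuple(config.roi_names),
                           n_voxels=config.n_voxels_per_roi)


def recognition_patterns(
    config: SimulationConfig,
    truth: GroundTruth,
    subject: int = 0,
    attention_events: Optional[pd.DataFrame] = None,
    patterns: Optional[SubjectPatterns] = None,
    noise_sd: float = 0.0,
    repel_attended: bool = False,
) -> dict[str, dict[str, np.ndarray]]:
    """Ground-truth retrieval patterns per ROI and item, with repulsion applied.

    Every old item's raw retrieval pattern is the sum of a subject x ROI
    global component (shared across all single-trial maps), its category
    prototype and its item component. For each ignored item, the component of
    its pattern lying in the span of its co-presented attended partners'
    patterns is then shrunk by ``1 - rho`` for the trial's cue condition; with
    ``repel_attended`` the shrinkage is applied to both pair members.
    Shrinking along the partner's direction reduces the covariance with that
    specific partner by exactly the factor ``1 - rho`` while leaving the
    covariance with non-co-presented items nearly intact, which is what makes
    within-trial similarity drop below matched between-trial similarity.
    ``noise_sd`` adds independent measurement noise, emulating the variability
    of single-trial estimates without running the full BOLD + GLM route.
    """
    if attention_events is None:
        attention_events = attention_design(config, subject)
    if patterns is None:
        patterns = draw_subject_patterns(config, truth, subject)
    ev = attention_events.loc[~attention_events.is_catch]
    rng = np.random.default_rng([config.seed % (2**31), subject, 11])
    out: dict[str, dict[str, np.ndarray]] = {}
    partners: dict[str, list[tuple[str, str]]] = {}
    for _, row in ev.iterrows():
        if row.item_ignored is not None and not pd.isna(row.item_ignored):
            partners.setdefault(row.item_ignored, []).append(
                (row.item_attended, row.condition))
            if repel_attended:
                partners.setdefault(row.item_attended, []).append(
                    (row.item_ignored, row.condition))
    all_items = sorted(set(ev.item_attended) | set(ev.item_ignored.dropna()))
    for roi in config.roi_names:
        g = patterns.global_pattern(roi, truth.retrieval_global_scale)
        raw = {it: g + patterns.item_pattern(roi, it) for it in all_items}
        adjusted = {}
        for it in all_items:
            p = raw[it].copy()
            links = partners.get(it, [])
            if links:
                rho = float(np.mean([truth.repulsion_rho.get(cond, 0.0)
                                     for _, cond in links]))
                if rho > 0:
                    basis = np.stack([raw[other] for other, _ in links], axis=1)
                    q, _ = np.linalg.qr(basis)
                    p = p - rho * q @ (q.T @ p)
            if noise_sd > 0:
                p = p + noise_sd * rng.standard_normal(p.shape)
            adjusted[it] = p
        out[roi] = adjusted
    return out


# ---------------------------------------------------------------------------
# BOLD synthesis
# ---------------------------------------------------------------------------

def _simulate_motion(
    rng: np.random.Generator, n_vols: int, spike_prob: float = 0.03
) -> tuple[np.ndarray, np.ndarray]:
    """AR(1) motion traces with occasional jumps; FD as summed absolute step."""
    steps = 0.02 * rng.standard_normal((6, n_vols))
    spikes = rng.random(n_vols) < spike_prob
    steps[:, spikes] += 0.15 * rng.standard_normal((6, int(spikes.sum())))
    motion = np.zeros((6, n_vols))
    for t in range(1, n_vols):
        motion[:, t] = 0.95 * motion[:, t - 1] + steps[:, t]
    fd = np.zeros(n_vols)
    fd[1:] = np.abs(np.diff(motion, axis=1)).sum(axis=0)
    return motion, fd


def _build_signal(
    n_vols: int, tr: float, hrf: np.ndarray,
    regressors: list[tuple[float, float, np.ndarray]],
    n_voxels: int,
) -> np.ndarray:
    """Sum of HRF-convolved boxcars, each scaled by a voxel amplitude vector."""
    sig = np.zeros((n_voxels, n_vols))
    for onset, duration, amplitude in regressors:
        box = np.zeros(n_vols)
        i0 = int(round(onset / tr))
        i1 = min(n_vols, int(math.ceil((onset + duration) / tr)))
        if i0 >= n_vols:
            raise ValidationError("event extends past the end of the run")
        box[i0:i1] = 1.0
        conv = np.convolve(box, hrf)[:n_vols]
        sig += np.outer(amplitude, conv)
    return sig


def _trial_phase_gains(row, truth: GroundTruth, roi: str) -> list[tuple[str, float, float, float]]:
    """(item, gain, onset offset, duration) entries for one attention trial.

    Encoding shows the picture(s) for 2 s starting 2 s into the trial;
    maintenance covers the following 4 s. In the retrospective condition the
    effective cue arrives only at maintenance, so both pictures carry the
    mean of the attended/ignored gains during encoding.
    """
    fix, cue, enc, maint = 1.0, 1.0, 2.0, 4.0
    enc_on, maint_on = fix + cue, fix + cue + enc
    entries = []
    if row.condition == "baseline":
        g = truth.gain("BL", roi)
        entries.append((row.item_attended, g, enc_on, enc))
        entries.append((row.item_attended, g, maint_on, maint))
        return entries
    att_key = "PA" if row.condition == "prospective" else "RA"
    ign_key = "PI" if row.condition == "prospective" else "RI"
    g_att, g_ign = truth.gain(att_key, roi), truth.gain(ign_key, roi)
    if row.condition == "retrospective":
        g_enc = 0.5 * (g_att + g_ign)
        entries.append((row.item_attended, g_enc, enc_on, enc))
        entries.append((row.item_ignored, g_enc, enc_on, enc))
    else:
        entries.append((row.item_attended, g_att, enc_on, enc))
        entries.append((row.item_ignored, g_ign, enc_on, enc))
    entries.append((row.item_attended, g_att, maint_on, maint))
    entries.append((row.item_ignored, g_ign, maint_on, maint))
    return entries


def simulate_task_runs(
    config: SimulationConfig,
    truth: GroundTruth,
    task: str,
    subject: int = 0,
    events: Optional[pd.DataFrame] = None,
    patterns: Optional[SubjectPatterns] = None,
    rois: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, dict[str, list[BoldRun]]]:
    """Generate one subject's events and ROI BOLD runs for a task.

    ``task`` is one of ``attention``, ``localizer``, ``recognition``.
    Returns the event table and, per ROI, one :class:`BoldRun` per run.
    """
    if task not in ("attention", "localizer", "recognition"):
        raise ConfigurationError(f"unknown task {task!r}")
    if patterns is None:
        patterns = draw_subject_patterns(config, truth, subject)
    rois = list(rois if rois is not None else config.roi_names)
    tr = config.tr_seconds
    hrf = double_gamma_hrf(config.hrf_params, tr)
    rng = _rng(config, subject, task)
    noise_rng = np.random.default_rng(rng.integers(2**31))
    motion_rng = np.random.default_rng(rng.integers(2**31))

    if task == "attention":
        if events is None:
            events = attention_design(config, subject)
        run_ids = sorted(events.run.unique())
        tail = 16.0
        regress_of_run: dict[int, dict[str, list]] = {}
        n_vols_of_run: dict[int, int] = {}
        for r in run_ids:
            sub = events[events.run == r]
            n_vols_of_run[r] = int(math.ceil((sub.onset.max() + config.trial_duration + tail) / tr))
            regress_of_run[r] = {roi: [] for roi in rois}
            for _, row in sub.iterrows():
                for roi in rois:
                    for item, gain, off, dur in _trial_phase_gains(row, truth, roi):
                        regress_of_run[r][roi].append(
                            (row.onset + off, dur, gain * patterns.item_pattern(roi, item)))
    elif task == "localizer":
        if events is None:
            events = localizer_design(config, subject)
        run_ids = sorted(events.run.unique())
        tail = 16.0
        regress_of_run = {}
        n_vols_of_run = {}
        for r in run_ids:
            sub = events[events.run == r]
            n_vols_of_run[r] = int(math.ceil((sub.onset.max() + sub.duration.iloc[-1] + tail) / tr))
            regress_of_run[r] = {roi: [] for roi in rois}
            for _, row in sub.iterrows():
                for roi in rois:
                    amp = (patterns.rest_pattern(roi) if row.trial_type == "rest"
                           else patterns.item_pattern(roi, row.item_id))
                    regress_of_run[r][roi].append((row.onset, row.duration, amp))
    else:  # recognition
        if events is None:
            events = recognition_design(config, subject)
        retrieval = recognition_patterns(config, truth, subject, patterns=patterns)
        run_ids = sorted(events.run.unique())
        tail = 16.0
        regress_of_run = {}
        n_vols_of_run = {}
        for r in run_ids:
            sub = events[events.run == r]
            n_vols_of_run[r] = int(math.ceil((sub.picture_onset.max() + 4.0 + tail) / tr))
            regress_of_run[r] = {roi: [] for roi in rois}
            for _, row in sub.iterrows():
                for roi in rois:
                    amp = (retrieval[roi][row.item_id] if row.is_old
                           else patterns.item_pattern(roi, row.item_id))
                    regress_of_run[r][roi].append((row.picture_onset, row.duration, amp))

    runs: dict[str, list[BoldRun]] = {roi: [] for roi in rois}
    for r in run_ids:
        n_vols = n_vols_of_run[r]
        motion, fd = _simulate_motion(motion_rng, n_vols)
        for roi in rois:
            sig = _build_signal(n_vols, tr, hrf, regress_of_run[r][roi],
                                config.n_voxels_per_roi)
            weights = config.motion_coupling * noise_rng.standard_normal(
                (config.n_voxels_per_roi, 6))
            data = (sig + weights @ motion
                    + config.noise_sd * noise_rng.standard_normal(sig.shape))
            runs[roi].append(BoldRun(roi=roi, run=int(r), data=data, tr_seconds=tr,
                                     motion=motion, fd=fd, subject=subject, task=task))
    return events, runs


def memory_outcomes(behavior: pd.DataFrame, subject: int) -> dict[str, str]:
    """Map item id -> 'hit' / 'miss' for one subject's old items."""
    sub = behavior[(behavior.subject == subject) & (behavior.cue_condition != "novel")]
    sub = sub[sub.response.notna()]
    hit = sub.response.isin([1.0, 2.0])
    return dict(zip(sub["item"], np.where(hit, "hit", "miss")))
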
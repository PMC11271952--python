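"""Localizer-trained category decoding of the attention task.

The chain follows the standard ROI MVPA recipe: per-run voxelwise z-scoring,
per-volume z-scoring across voxels, hemodynamic-lag-aware volume selection
per task phase, task-wise voxel z-scoring of the selected volumes, four
one-vs-rest L2 logistic classifiers (3 picture categories + Gabor/rest,
C = 0.01), probability renormalization to sum 1, and sorting of class
probabilities into attended / ignored / other / rest roles per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .config import CATEGORIES, REST_CLASS, SimulationConfig, ValidationError
from .types import BoldRun, NormalizedVolumes

CLASSES = tuple(CATEGORIES) + (REST_CLASS,)

_ROLE_KEY = {("prospective", "attended"): "PA", ("prospective", "ignored"): "PI",
             ("prospective", "other"): "PO", ("retrospective", "attended"): "RA",
             ("retrospective", "ignored"): "RI", ("retrospective", "other"): "RO",
             ("baseline", "attended"): "BL", ("baseline", "other"): "BO"}


def _safe_z(x: np.ndarray, axis: int, what: str) -> np.ndarray:
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=0, keepdims=True)
    const = sd <= 0
    if np.any(const):
        warnings.warn(f"{int(const.sum())} constant {what}(s) mapped to zeros")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    return np.where(np.broadcast_to(const, z.shape), 0.0, z)


def standardize_run(run: BoldRun) -> np.ndarray:
    """Steps 1-2 of the chain on one run: voxelwise z over time, then
    volumewise z across voxels. Returns (n_volumes, n_voxels)."""
    if run.n_timepoints < 2 or run.n_voxels < 2:
        raise ValidationError("need at least 2 volumes and 2 voxels")
    z = _safe_z(run.data, axis=1, what="voxel")  # per voxel over time
    z = _safe_z(z, axis=0, what="volume")  # per volume across voxels
    return z.T


def _check_grid(onset: float, tr: float, label: str) -> int:
    vol = onset / tr
    if abs(vol - round(vol)) > 1e-9:
        raise ValidationError(f"onset of {label} not on the TR grid: {onset}")
    return int(round(vol))


def localizer_selection(events: pd.DataFrame, tr: float, lag_volumes: int = 2) -> pd.DataFrame:
    """One selected volume per localizer stimulus: the third TR after onset
    (onset volume + 2, covering 4-6 s post-onset)."""
    rows = []
    for _, row in events.iterrows():
        vol = _check_grid(row.onset, tr, row.item_id) + lag_volumes
        rows.append(dict(run=int(row.run), volumes=(vol,), label=row.trial_type,
                         sample_id=row.item_id, phase="localizer"))
    return pd.DataFrame(rows)


def attention_selection(
    events: pd.DataFrame,
    config: SimulationConfig,
    phase: str,
    lag_volumes: int = 2,
    include_catch: bool = False,
) -> pd.DataFrame:
    """Volume indices per attention trial for a task phase.

    encoding: the third TR after picture onset; maintenance: the two TRs
    starting 4 s after the second-cue onset (averaged downstream); per-tr:
    TR0..TR3 of the trial epoch, each shifted by the hemodynamic lag.
    """
    if phase not in ("encoding", "maintenance", "per-tr"):
        raise ValidationError(f"unknown phase {phase!r}")
    tr = config.tr_seconds
    fix, cue, enc, _maint = config.trial_timing
    rows = []
    for _, row in events.iterrows():
        if row.is_catch and not include_catch:
            continue
        trial_id = f"s{row.subject}_r{row.run}_t{row.trial_index}"
        v0 = _check_grid(row.onset, tr, trial_id)
        pic_vol = v0 + int(round((fix + cue) / tr))
        cue2_vol = v0 + int(round((fix + cue + enc) / tr))
        base = dict(run=int(row.run), sample_id=trial_id, condition=row.condition,
                    trial_index=int(row.trial_index), subject=int(row.subject),
                    item_attended=row.item_attended, item_ignored=row.item_ignored,
                    attended_category=row.attended_category,
                    ignored_category=row.ignored_category)
        if phase == "encoding":
            rows.append(dict(**base, volumes=(pic_vol + lag_volumes,), phase="encoding"))
        elif phase == "maintenance":
            start = cue2_vol + int(round(4.0 / tr))
            rows.append(dict(**base, volumes=(start, start + 1), phase="maintenance"))
        else:
            for k in range(4):
                rows.append(dict(**base, volumes=(v0 + k + lag_volumes,), phase=f"TR{k}"))
    return pd.DataFrame(rows)


def normalize_chain(
    runs: list[BoldRun], selection: pd.DataFrame, task: str = "", final_z: bool = True
) -> NormalizedVolumes:
    """Run the full z-scoring chain and return the selected (averaged) volumes.

    Order: per-voxel z within run, per-volume z across voxels, selection /
    averaging of the phase volumes, then per-voxel z across all selected
    volumes of the task (``final_z``).
    """
    if len(selection) < 2:
        raise ValidationError("need at least 2 selected volumes")
    std = {r.run: standardize_run(r) for r in runs}
    roi = runs[0].roi
    mat = np.stack([
        np.mean([std[int(row.run)][v] for v in row.volumes], axis=0)
        for row in selection.itertuples()
    ])
    if final_z:
        mat = _safe_z(mat, axis=0, what="voxel")
    return NormalizedVolumes(roi=roi, task=task or runs[0].task, data=mat,
                             meta=selection.reset_index(drop=True))


@dataclass
class ClassifierModel:
    """Four binary one-vs-rest L2 logistic classifiers (liblinear, C = 0.01)."""

    classes: tuple[str, ...]
    weights: np.ndarray  # (n_classes, n_voxels)
    intercepts: np.ndarray
    C: float = 0.01

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights.T + self.intercepts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class sigmoid outputs renormalized to sum to 1 per sample."""
        if X.shape[1] != self.weights.shape[1]:
            raise ValidationError("voxel dimension mismatch between model and data")
        sig = 1.0 / (1.0 + np.exp(-self.decision(X)))
        return sig / sig.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.classes)[np.argmax(self.predict_proba(X), axis=1)]


def train_classifier(
    X: np.ndarray, labels: np.ndarray, C: float = 0.01, classes: tuple[str, ...] = CLASSES
) -> ClassifierModel:
    """Fit one binary L2-penalized logistic regression per class (one vs rest)."""
    if not C > 0:
        raise ValidationError("C must be positive")
    labels = np.asarray(labels)
    missing = [c for c in classes if (labels == c).sum() < 2]
    if missing:
        raise ValidationError(f"classes with fewer than 2 examples: {missing}")
    weights, intercepts = [], []
    for c in classes:
        # default penalty is the L2 norm; liblinear matches the reference tooling
        clf = LogisticRegression(C=C, solver="liblinear", max_iter=1000)
        clf.fit(X, (labels == c).astype(int))
        sign = 1.0 if clf.classes_[1] == 1 else -1.0
        weights.append(sign * clf.coef_[0])
        intercepts.append(sign * clf.intercept_[0])
    return ClassifierModel(classes=tuple(classes), weights=np.stack(weights),
                           intercepts=np.asarray(intercepts), C=C)


def loro_cross_validate(
    runs: list[BoldRun], selection: pd.DataFrame, C: float = 0.01,
    classes: tuple[str, ...] = CLASSES,
) -> dict:
    """Leave-one-run-out accuracy of the full normalization + classifier chain.

    Per-run standardization is intrinsically fold-safe; the final task-wise
    voxel z-scoring is estimated on the training runs only and its mean/sd
    applied to the held-out run.
    """
    run_ids = sorted({r.run for r in runs})
    if len(run_ids) < 2:
        raise ValidationError("leave-one-run-out needs at least 2 runs")
    std = {r.run: standardize_run(r) for r in runs}

    def rows_for(sel: pd.DataFrame) -> np.ndarray:
        return np.stack([
            np.mean([std[int(row.run)][v] for v in row.volumes], axis=0)
            for row in sel.itertuples()
        ])

    accuracies, folds = [], []
    for held_out in run_ids:
        train_sel = selection[selection.run != held_out]
        test_sel = selection[selection.run == held_out]
        if test_sel.empty:
            continue
        train_labels = train_sel.label.to_numpy()
        if any((train_labels == c).sum() < 2 for c in classes):
            warnings.warn(f"fold {held_out} skipped: a class is missing in training")
            continue
        X_train, X_test = rows_for(train_sel), rows_for(test_sel)
        mean = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd[sd <= 0] = 1.0
        X_train = (X_train - mean) / sd
        X_test = (X_test - mean) / sd
        model = train_classifier(X_train, train_labels, C=C, classes=classes)
        acc = float(np.mean(model.predict(X_test) == test_sel.label.to_numpy()))
        accuracies.append(acc)
        folds.append(held_out)
    return {"fold_runs": folds, "fold_accuracies": accuracies,
            "mean_accuracy": float(np.mean(accuracies)) if accuracies else np.nan}


def apply_and_sort(
    model: ClassifierModel,
    volumes: NormalizedVolumes,
    renormalize: str = "four",
) -> pd.DataFrame:
    """Classifier-evidence records: renormalized class probabilities mapped to
    attended / ignored / other / rest roles per trial and phase.

    ``renormalize='pictures'`` restricts the renormalization to the three
    picture categories (rest reported as 0). Baseline trials have no ignored
    role; the two unpresented categories fold into ``other``.
    """
    probs = model.predict_proba(volumes.data)
    if renormalize == "pictures":
        pic_idx = [model.classes.index(c) for c in CATEGORIES]
        pic = probs[:, pic_idx]
        pic = pic / pic.sum(axis=1, keepdims=True)
        probs = np.zeros_like(probs)
        probs[:, pic_idx] = pic
    elif renormalize != "four":
        raise ValidationError(f"unknown renormalization mode {renormalize!r}")
    class_idx = {c: i for i, c in enumerate(model.classes)}
    records = []
    for i, row in enumerate(volumes.meta.itertuples()):
        att_cat = row.attended_category
        if att_cat not in class_idx:
            raise ValidationError(f"unknown category label {att_cat!r}")
        ign_cat = None if pd.isna(row.item_ignored) else row.ignored_category
        p = probs[i]
        attended = p[class_idx[att_cat]]
        if ign_cat:
            ignored = p[class_idx[ign_cat]]
            other_cats = [c for c in CATEGORIES if c not in (att_cat, ign_cat)]
        else:
            ignored = np.nan
            other_cats = [c for c in CATEGORIES if c != att_cat]
        other = float(sum(p[class_idx[c]] for c in other_cats))
        rest = p[class_idx[REST_CLASS]]
        records.append(dict(subject=row.subject, roi=volumes.roi, trial=row.sample_id,
                            phase=row.phase, condition=row.condition,
                            item_attended=row.item_attended, item_ignored=row.item_ignored,
                            attended=attended, ignored=ignored, other=other, rest=rest))
    return pd.DataFrame(records)


def evidence_cell_means(
    records: pd.DataFrame,
    behavior: pd.DataFrame | None = None,
    average_repetitions: bool = True,
) -> pd.DataFrame:
    """Mean classifier evidence per subject x ROI x phase x cue-attention cell.

    Evidence is first reduced to the item level (each picture's two trial
    repetitions averaged, when ``average_repetitions``); ``other`` and
    ``rest`` roles have no item identity and are averaged at the trial level.
    When a behavioral table is given, item-level evidence also splits by
    subsequent memory (hit/miss).
    """
    long_rows = []
    for role, item_col in (("attended", "item_attended"), ("ignored", "item_ignored")):
        sub = records.dropna(subset=[role]).copy()
        sub = sub[~sub[item_col].isna()] if role == "ignored" else sub
        long_rows.append(pd.DataFrame(dict(
            subject=sub.subject, roi=sub.roi, phase=sub.phase, condition=sub.condition,
            role=role, item=sub[item_col], evidence=sub[role])))
    for role in ("other", "rest"):
        sub = records.dropna(subset=[role])
        long_rows.append(pd.DataFrame(dict(
            subject=sub.subject, roi=sub.roi, phase=sub.phase, condition=sub.condition,
            role=role, item=None, evidence=sub[role])))
    long = pd.concat(long_rows, ignore_index=True)
    if average_repetitions:
        keyed = long[long.item.notna()]
        keyed = (keyed.groupby(["subject", "roi", "phase", "condition", "role", "item"],
                               as_index=False).evidence.mean())
        long = pd.concat([keyed, long[long.item.isna()]], ignore_index=True)
    if behavior is not None:
        outcome = behavior[behavior.cue_condition != "novel"].copy()
        outcome["memory"] = np.where(outcome.response.isin([1.0, 2.0]), "hit",
                                     np.where(outcome.response.isna(), None, "miss"))
        long = long.merge(outcome[["subject", "item", "memory"]],
                          on=["subject", "item"], how="left")
    else:
        long["memory"] = None
    long["cue_attention"] = [
        _ROLE_KEY.get((c, r)) for c, r in zip(long.condition, long.role)
    ]
    cells = (long[long.role != "rest"]
             .groupby(["subject", "roi", "phase", "cue_attention"], as_index=False)
             .evidence.mean())
    return cells, long


def evidence_contrasts(
    records: pd.DataFrame,
    behavior: pd.DataFrame | None = None,
    average_repetitions: bool = True,
) -> pd.DataFrame:
    """Named evidence contrasts per subject x ROI x phase.

    PA-PI / RA-RI (attentional modulation), PI-PO / RI-RO (residual distractor
    evidence), PA-PO (target enhancement), BL-PA / BL-RA (baseline shift),
    and remembered-minus-forgotten SME per cue-attention condition when a
    behavioral table is supplied. Empty cells propagate as missing values.
    """
    cells, long = evidence_cell_means(records, behavior, average_repetitions)
    wide = cells.pivot_table(index=["subject", "roi", "phase"], columns="cue_attention",
                             values="evidence", aggfunc="mean")
    pairs = {"PA-PI": ("PA", "PI"), "RA-RI": ("RA", "RI"), "PI-PO": ("PI", "PO"),
             "RI-RO": ("RI", "RO"), "PA-PO": ("PA", "PO"), "BL-PA": ("BL", "PA"),
             "BL-RA": ("BL", "RA")}
    rows = []
    for name, (a, b) in pairs.items():
        if a in wide.columns and b in wide.columns:
            diff = wide[a] - wide[b]
            for (subject, roi, phase), v in diff.items():
                rows.append(dict(subject=subject, roi=roi, phase=phase,
                                 contrast=name, value=v))
    if behavior is not None:
        sme_src = long[long.memory.notna() & long.cue_attention.notna()
                       & long.role.isin(["attended", "ignored"])]
        sme = sme_src.pivot_table(index=["subject", "roi", "phase", "cue_attention"],
                                  columns="memory", values="evidence", aggfunc="mean")
        for col in ("hit", "miss"):
            if col not in sme.columns:
                sme[col] = np.nan
        diff = sme["hit"] - sme["miss"]
        for (subject, roi, phase, cond), v in diff.items():
            rows.append(dict(subject=subject, roi=roi, phase=phase,
                             contrast=f"SME-{cond}", value=v))
    return pd.DataFrame(rows)
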
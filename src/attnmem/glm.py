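"""First-level GLM machinery: double-gamma HRF, design matrices with motion /
framewise-displacement censoring, per-voxel OLS, and least-squares-separate
(LSS) single-trial estimation.

Regressors are boxcars sampled on the TR grid and convolved with the HRF
kernel; all task onsets in this package fall on the acquisition grid, so no
oversampling is needed and GLM regressors match the generative model exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import HrfParams, ValidationError
from .types import BoldRun, TrialPattern

FD_CENSOR_THRESHOLD = 0.3  # mm; volumes with FD strictly above are censored


def double_gamma_hrf(params: HrfParams, tr: float) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the TR, peak normalized to 1.

    The kernel is the difference of two gamma densities (response and
    undershoot), the undershoot scaled down by the peak:undershoot ratio.
    """
    if not tr > 0:
        raise ValidationError("tr must be positive")
    t = np.arange(0.0, params.duration + 1e-9, tr)
    peak = sps.gamma.pdf(t, params.peak_delay / params.peak_dispersion,
                         scale=params.peak_dispersion)
    under = sps.gamma.pdf(t, params.undershoot_delay / params.undershoot_dispersion,
                          scale=params.undershoot_dispersion)
    kernel = peak - under / params.peak_undershoot_ratio
    return kernel / kernel.max()


def hrf_convolved_regressor(
    onsets: np.ndarray, durations: np.ndarray, n_vols: int, tr: float, hrf: np.ndarray
) -> np.ndarray:
    """Boxcar on the TR grid convolved with the HRF, truncated to the run."""
    box = np.zeros(n_vols)
    for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        i0 = int(round(onset / tr))
        i1 = int(np.ceil((onset + dur) / tr - 1e-9))
        if i0 >= n_vols or onset < 0:
            raise ValidationError(f"event at t={onset} falls outside the run")
        box[i0:min(i1, n_vols)] = 1.0
    return np.convolve(box, hrf)[:n_vols]


def _dct_basis(n_vols: int, tr: float, cutoff: float = 100.0) -> np.ndarray:
    """Discrete-cosine high-pass basis (drift regressors) up to the cutoff period."""
    order = int(np.floor(2 * n_vols * tr / cutoff))
    t = np.arange(n_vols)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_vols)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_vols, 0))


@dataclass
class DesignMatrix:
    """Named first-level design: task, nuisance and one-hot censor columns."""

    matrix: pd.DataFrame  # index: frame times (s)
    task_columns: list[str]
    nuisance_columns: list[str]
    censor_columns: list[str]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = list(self.matrix.columns)
        if len(set(cols)) != len(cols):
            raise ValidationError("design column names must be unique")
        for c in self.task_columns:
            if not np.any(self.matrix[c].to_numpy()):
                raise ValidationError(f"task column {c!r} is all zero")
        for c in self.censor_columns:
            v = self.matrix[c].to_numpy()
            if v.sum() != 1 or set(np.unique(v)) - {0.0, 1.0}:
                raise ValidationError(f"censor column {c!r} must be one-hot")

    @property
    def frame_times(self) -> np.ndarray:
        return self.matrix.index.to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


def censor_columns_from_fd(
    fd: np.ndarray, threshold: float = FD_CENSOR_THRESHOLD
) -> dict[str, np.ndarray]:
    """One one-hot column per volume whose FD strictly exceeds the threshold."""
    cols = {}
    for idx in np.flatnonzero(np.asarray(fd) > threshold):
        col = np.zeros(len(fd))
        col[idx] = 1.0
        cols[f"censor_{idx:04d}"] = col
    return cols


def build_design(
    events: pd.DataFrame,
    run: BoldRun,
    condition_column: str = "condition",
    onset_column: str = "onset",
    epoch_duration: float = 8.0,
    conditions: list[str] | None = None,
    include_motion: bool = True,
    include_intercept: bool = True,
    fd_threshold: float = FD_CENSOR_THRESHOLD,
    drift: bool = False,
    drift_cutoff: float = 100.0,
) -> DesignMatrix:
    """Condition-wise design for one run.

    One HRF-convolved boxcar column per condition (catch trials, when an
    ``is_catch`` column is present, go to a separate nuisance column), six
    motion parameters plus the FD trace as confounds, and a one-hot censor
    column for each volume with FD above the threshold.
    """
    tr, n_vols = run.tr_seconds, run.n_timepoints
    hrf = double_gamma_hrf(HrfParams(), tr)
    ev = events.copy()
    is_catch = ev["is_catch"].to_numpy(bool) if "is_catch" in ev else np.zeros(len(ev), bool)
    if np.any(ev[onset_column].to_numpy() + epoch_duration > n_vols * tr):
        raise ValidationError("an event epoch extends past the run end")
    notes: list[str] = []
    task: dict[str, np.ndarray] = {}
    wanted = conditions if conditions is not None else list(
        pd.unique(ev.loc[~is_catch, condition_column]))
    for cond in wanted:
        sel = (~is_catch) & (ev[condition_column] == cond)
        if not sel.any():
            msg = f"no events for condition {cond!r}; column omitted"
            warnings.warn(msg)
            notes.append(msg)
            continue
        task[str(cond)] = hrf_convolved_regressor(
            ev.loc[sel, onset_column].to_numpy(), np.full(sel.sum(), epoch_duration),
            n_vols, tr, hrf)
    nuisance: dict[str, np.ndarray] = {}
    if is_catch.any():
        nuisance["catch"] = hrf_convolved_regressor(
            ev.loc[is_catch, onset_column].to_numpy(),
            np.full(int(is_catch.sum()), epoch_duration), n_vols, tr, hrf)
    if include_motion:
        for i in range(6):
            if np.ptp(run.motion[i]) > 0:
                nuisance[f"motion_{i}"] = run.motion[i]
        if np.ptp(run.fd) > 0:
            nuisance["fd"] = run.fd
    if drift:
        for i, col in enumerate(_dct_basis(n_vols, tr, drift_cutoff).T):
            nuisance[f"drift_{i}"] = col
    if include_intercept:
        nuisance["intercept"] = np.ones(n_vols)
    censor = censor_columns_from_fd(run.fd, fd_threshold)
    frame = pd.DataFrame({**task, **nuisance, **censor},
                         index=np.arange(n_vols) * tr)
    return DesignMatrix(matrix=frame, task_columns=list(task),
                        nuisance_columns=list(nuisance),
                        censor_columns=list(censor), warnings=notes)


@dataclass
class GlmResult:
    columns: list[str]
    coefficients: np.ndarray  # (n_regressors, n_voxels)
    tstats: np.ndarray  # (n_regressors, n_voxels)
    df: int

    def coef(self, column: str) -> np.ndarray:
        return self.coefficients[self.columns.index(column)]

    def t(self, column: str) -> np.ndarray:
        return self.tstats[self.columns.index(column)]


def fit_glm(design: DesignMatrix, run: BoldRun) -> GlmResult:
    """Ordinary least squares per voxel with classical t statistics.

    t = beta / SE(beta) with residual degrees of freedom ``timepoints - rank``;
    censored volumes are absorbed by their one-hot columns, so their data
    values cannot influence any other estimate.
    """
    X = design.values
    Y = run.data.T  # (n_timepoints, n_voxels)
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("design rows must equal run timepoints")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        _, r_diag, piv = _pivoted_qr_diag(X)
        bad = [design.matrix.columns[p] for p, d in zip(piv, r_diag)
               if abs(d) < 1e-8 * max(abs(r_diag[0]), 1.0)]
        raise ValidationError(f"design is rank deficient; collinear columns: {bad}")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    df = X.shape[0] - rank
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    return GlmResult(columns=list(design.matrix.columns), coefficients=B,
                     tstats=t, df=df)


def _pivoted_qr_diag(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, np.diag(r), piv


def lss_single_trial(
    events: pd.DataFrame,
    runs: list[BoldRun],
    epoch_duration: float = 2.0,
    epoch_anchor: str = "onset",
    no_response_items: set[str] | None = None,
    fd_threshold: float = FD_CENSOR_THRESHOLD,
    include_intercept: bool = True,
    include_motion: bool = True,
    phase: str = "retrieval",
    statistic: str = "t",
) -> list[TrialPattern]:
    """Least-squares-separate t-maps for every old recognition trial.

    For each target trial a GLM is fit with (i) the target's own regressor,
    (ii) one regressor pooling all other old trials, (iii) a foil regressor,
    (iv) a no-response regressor when applicable, plus motion/FD confounds
    and FD censor columns; the target column's t-map is returned. The epoch
    is 2 s anchored at picture onset (``epoch_anchor='fixation'`` instead
    anchors it at the pre-picture fixation onset).

    ``events`` needs columns run, item_id, is_old, picture_onset, onset.
    ``statistic='beta'`` returns raw coefficients (beta series) instead of
    t-maps.
    """
    if epoch_anchor not in ("onset", "fixation"):
        raise ValidationError(f"unknown epoch anchor {epoch_anchor!r}")
    if statistic not in ("t", "beta"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    no_resp = no_response_items or set()
    onset_col = "picture_onset" if epoch_anchor == "onset" else "onset"
    run_of = {r.run: r for r in runs}
    hrf = double_gamma_hrf(HrfParams(), runs[0].tr_seconds)
    patterns: list[TrialPattern] = []
    for run_id, sub in events.groupby("run"):
        run = run_of[int(run_id)]
        tr, n_vols = run.tr_seconds, run.n_timepoints
        onsets = sub[onset_col].to_numpy(float)
        is_old = sub.is_old.to_numpy(bool)
        responded = ~sub.item_id.isin(no_resp).to_numpy()
        censor = censor_columns_from_fd(run.fd, fd_threshold)
        censored_vols = {int(k.split("_")[1]) for k in censor}
        base_cols: dict[str, np.ndarray] = {}
        foil_sel = (~is_old) & responded
        if foil_sel.any():
            base_cols["foils"] = hrf_convolved_regressor(
                onsets[foil_sel], np.full(foil_sel.sum(), epoch_duration), n_vols, tr, hrf)
        if (~responded).any():
            base_cols["no_response"] = hrf_convolved_regressor(
                onsets[~responded], np.full((~responded).sum(), epoch_duration),
                n_vols, tr, hrf)
        if include_motion:
            for i in range(6):
                if np.ptp(run.motion[i]) > 0:
                    base_cols[f"motion_{i}"] = run.motion[i]
            if np.ptp(run.fd) > 0:
                base_cols["fd"] = run.fd
        if include_intercept:
            base_cols["intercept"] = np.ones(n_vols)
        target_sel = is_old & responded
        target_idx = np.flatnonzero(target_sel)
        for j in target_idx:
            item = sub.item_id.iloc[j]
            support = set(range(int(round(onsets[j] / tr)),
                                int(np.ceil((onsets[j] + epoch_duration) / tr - 1e-9))))
            if support and support <= censored_vols:
                patterns.append(TrialPattern(trial_id=item, roi=run.roi, values=None,
                                             phase=phase, missing=True))
                continue
            cols = {"target": hrf_convolved_regressor(
                onsets[[j]], np.array([epoch_duration]), n_vols, tr, hrf)}
            others = target_sel.copy()
            others[j] = False
            if others.any():
                cols["others"] = hrf_convolved_regressor(
                    onsets[others], np.full(others.sum(), epoch_duration), n_vols, tr, hrf)
            frame = pd.DataFrame({**cols, **base_cols, **censor},
                                 index=np.arange(n_vols) * tr)
            design = DesignMatrix(matrix=frame, task_columns=list(cols),
                                  nuisance_columns=list(base_cols),
                                  censor_columns=list(censor))
            result = fit_glm(design, run)
            values = result.t("target") if statistic == "t" else result.coef("target")
            patterns.append(TrialPattern(trial_id=item, roi=run.roi,
                                         values=values, phase=phase))
    return patterns
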
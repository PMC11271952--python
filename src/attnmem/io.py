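"""File interfaces: BIDS-style events TSV, NIfTI volumes/masks, YAML configs.

Synthetic ROI data have no anatomy; voxels are laid out on a compact 3-D
grid whose nonzero mask entries define the ROI, so the NIfTI round trip
(volume + mask -> voxel x time matrix) matches real-data tooling.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .config import GroundTruth, HrfParams, SimulationConfig
from .types import BoldRun, TrialPattern


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    """Write attention-task events in BIDS style (onset, duration, trial_type...)."""
    path = Path(path)
    out = pd.DataFrame({
        "onset": events.onset,
        "duration": 8.0,
        "trial_type": events.condition,
        "side": events.attended_side,
        "item_id": events.item_attended,
        "item_ignored": events.item_ignored,
        "category": events.attended_category,
        "category_ignored": events.ignored_category,
        "is_catch": events.is_catch.astype(int),
        "run": events.run,
        "subject": events.subject,
        "trial_index": events.trial_index,
    })
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return pd.DataFrame({
        "subject": raw.subject, "run": raw.run, "trial_index": raw.trial_index,
        "condition": raw.trial_type, "attended_category": raw.category,
        "ignored_category": raw.category_ignored, "attended_side": raw.side,
        "onset": raw.onset, "item_attended": raw.item_id,
        "item_ignored": raw.item_ignored, "is_catch": raw.is_catch.astype(bool),
    })


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    nx = max(1, round(n_voxels ** (1.0 / 3.0)))
    ny = max(1, math.ceil(math.sqrt(n_voxels / nx)))
    nz = math.ceil(n_voxels / (nx * ny))
    return nx, ny, nz


def write_roi_mask(n_voxels: int, path: str | Path) -> Path:
    """Binary ROI mask on the compact voxel grid."""
    shape = _grid_shape(n_voxels)
    flat = np.zeros(int(np.prod(shape)), dtype=np.int16)
    flat[:n_voxels] = 1
    nib.save(nib.Nifti1Image(flat.reshape(shape), np.eye(4)), str(path))
    return Path(path)


def write_bold_nifti(run: BoldRun, path: str | Path) -> Path:
    """ROI voxel x time matrix as a 4-D NIfTI on the compact grid."""
    shape = _grid_shape(run.n_voxels)
    vol = np.zeros((int(np.prod(shape)), run.n_timepoints), dtype=np.float32)
    vol[:run.n_voxels] = run.data
    img = nib.Nifti1Image(vol.reshape(*shape, run.n_timepoints), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr_seconds))
    nib.save(img, str(path))
    return Path(path)


def read_bold_nifti(
    path: str | Path, mask_path: str | Path, run: int = 0, roi: str = "",
    motion: np.ndarray | None = None, fd: np.ndarray | None = None,
    subject: int = 0, task: str = "",
) -> BoldRun:
    img = nib.load(str(path))
    mask = nib.load(str(mask_path)).get_fdata().astype(bool)
    data = img.get_fdata()[mask]  # (n_voxels, n_timepoints)
    n_t = data.shape[1]
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
    return BoldRun(roi=roi, run=run, data=data, tr_seconds=tr,
                   motion=motion if motion is not None else np.zeros((6, n_t)),
                   fd=fd if fd is not None else np.zeros(n_t),
                   subject=subject, task=task)


def write_trial_patterns(
    patterns: list[TrialPattern], path: str | Path, manifest_path: str | Path
) -> tuple[Path, Path]:
    """Per-trial t-maps as a 4-D NIfTI (trial on the 4th axis) + CSV manifest."""
    present = [p for p in patterns if not p.missing]
    if not present:
        raise ValueError("no non-missing trial patterns to write")
    n_vox = len(present[0].values)
    shape = _grid_shape(n_vox)
    vol = np.zeros((int(np.prod(shape)), len(present)), dtype=np.float32)
    rows = []
    for j, p in enumerate(present):
        vol[:n_vox, j] = p.values
        rows.append(dict(volume_index=j, trial_id=p.trial_id, roi=p.roi, phase=p.phase))
    for p in patterns:
        if p.missing:
            rows.append(dict(volume_index=-1, trial_id=p.trial_id, roi=p.roi,
                             phase=p.phase))
    nib.save(nib.Nifti1Image(vol.reshape(*shape, len(present)), np.eye(4)), str(path))
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return Path(path), Path(manifest_path)


def read_trial_patterns(path: str | Path, manifest_path: str | Path,
                        n_voxels: int) -> list[TrialPattern]:
    img = nib.load(str(path))
    flat = img.get_fdata().reshape(-1, img.shape[3])
    manifest = pd.read_csv(manifest_path)
    out = []
    for _, row in manifest.iterrows():
        if row.volume_index < 0:
            out.append(TrialPattern(trial_id=row.trial_id, roi=row.roi, values=None,
                                    phase=row.phase, missing=True))
        else:
            out.append(TrialPattern(trial_id=row.trial_id, roi=row.roi,
                                    values=flat[:n_voxels, int(row.volume_index)],
                                    phase=row.phase))
    return out


def config_to_yaml(config: SimulationConfig, truth: GroundTruth,
                   path: str | Path) -> Path:
    payload = {"config": asdict(config), "truth": asdict(truth)}
    payload["config"]["roi_names"] = list(config.roi_names)
    payload["config"]["trial_timing"] = list(config.trial_timing)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(payload), fh, sort_keys=False)
    return Path(path)


def config_from_yaml(path: str | Path) -> tuple[SimulationConfig, GroundTruth]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    cfg = dict(payload["config"])
    cfg["trial_timing"] = tuple(cfg["trial_timing"])
    cfg["roi_names"] = tuple(cfg["roi_names"])
    cfg["hrf_params"] = HrfParams(**cfg["hrf_params"])
    return SimulationConfig(**cfg), GroundTruth(**payload["truth"])


def _plain(obj):
    """Recursively convert numpy scalars/containers to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
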
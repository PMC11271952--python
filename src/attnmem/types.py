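"""Shared data containers used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ValidationError


@dataclass
class TrialEvent:
    """One attention-task trial: cue condition, picture assignment and timing."""

    subject: int
    run: int
    trial_index: int
    condition: str  # prospective | retrospective | baseline
    attended_category: str
    ignored_category: Optional[str]
    attended_side: str  # left | right
    onset: float
    item_attended: str
    item_ignored: Optional[str]
    is_catch: bool = False

    def __post_init__(self) -> None:
        if self.ignored_category is not None and self.attended_category == self.ignored_category:
            raise ValidationError("attended and ignored categories must differ")
        if self.attended_side not in ("left", "right"):
            raise ValidationError(f"bad side {self.attended_side!r}")


def events_to_frame(events: Sequence[TrialEvent]) -> pd.DataFrame:
    frame = pd.DataFrame([asdict(e) for e in events])
    return frame.sort_values(["run", "onset"]).reset_index(drop=True)


@dataclass
class BoldRun:
    """ROI-restricted voxel x time BOLD matrix with nuisance traces."""

    roi: str
    run: int
    data: np.ndarray  # (n_voxels, n_timepoints)
    tr_seconds: float
    motion: np.ndarray  # (6, n_timepoints)
    fd: np.ndarray  # (n_timepoints,)
    subject: int = 0
    task: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("BOLD data must be finite")
        n_t = self.data.shape[1]
        if self.motion.shape != (6, n_t) or self.fd.shape != (n_t,):
            raise ValidationError("motion/FD traces must match the timepoint count")
        if np.any(self.fd < 0):
            raise ValidationError("framewise displacement must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialPattern:
    """Single-trial voxel vector of t-statistics from the LSS GLM."""

    trial_id: str
    roi: str
    values: Optional[np.ndarray]
    phase: str = "retrieval"
    missing: bool = False

    def __post_init__(self) -> None:
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if not np.all(np.isfinite(self.values)):
                raise ValidationError(f"non-finite t-values in trial {self.trial_id}")


@dataclass
class NormalizedVolumes:
    """Output of the z-scoring chain: selected volumes x voxels plus metadata."""

    roi: str
    task: str
    data: np.ndarray  # (n_selected, n_voxels)
    meta: pd.DataFrame  # one row per selected volume (trial, phase, run, ...)

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.meta):
            raise ValidationError("metadata rows must match selected volume count")


@dataclass(frozen=True)
class PairSpec:
    """A within-trial pair or its matched between-trial control pair."""

    pair_id: str
    kind: str  # within_trial | between_trial
    item_attended: str
    item_ignored: str
    condition: str
    matched_to: Optional[str] = None
    category_pair: tuple[str, str] = ("", "")
    side: str = ""
    outcomes: tuple[str, str] = ("", "")
    lag: float = np.nan
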
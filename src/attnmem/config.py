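"""Configuration and ground-truth containers for the synthetic cohort simulator.

The simulator emulates a selective-attention fMRI experiment: an event-related
attention task (prospective / retrospective / baseline cues over pairs of
category pictures), a block-design category localizer with interleaved Gabor
blocks, and a next-day recognition test. Ground-truth parameters (attentional
gains, pair-specific repulsion, per-condition hit rates) encode the effects the
downstream analysis stages are meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

# The five cue-attention conditions: baseline, prospective-attended,
# prospective-ignored, retrospective-attended, retrospective-ignored.
CUE_ATTENTION_CONDITIONS = ("BL", "PA", "PI", "RA", "RI")
CUE_CONDITIONS = ("prospective", "retrospective", "baseline")
DEFAULT_ROIS = ("dLPC", "vLPC", "VTC")
CATEGORIES = ("face", "scene", "object")
REST_CLASS = "rest"


class ValidationError(ValueError):
    """Raised when a configuration or ground-truth value is out of range."""


class ConfigurationError(ValueError):
    """Raised when a required configuration entry is missing."""


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma hemodynamic response function parameters.

    Defaults are the SPM/FSL convention: response peak at 6 s, undershoot at
    16 s, unit dispersions, peak:undershoot ratio 6, sampled over 32 s.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValidationError(f"HRF parameter {name!r} must be positive, got {value}")
        if self.duration < 30.0:
            raise ValidationError("HRF kernel must cover at least 30 s")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level design parameters for one simulated cohort.

    Timing follows the task design: each attention trial is a 1-s fixation,
    1-s cue, 2-s encoding (two pictures, or one for baseline) and 4-s
    maintenance epoch on a TR = 2 s grid; one-sixth of trials are catch
    trials with a probe; the localizer presents mini-blocks of 10 pictures
    (2 s each) separated by 8-s Gabor blocks.
    """

    n_subjects: int = 24
    n_voxels_per_roi: int = 60
    roi_names: Sequence[str] = DEFAULT_ROIS
    n_categories: int = 3
    n_runs_attention: int = 6
    n_runs_localizer: int = 3
    n_runs_recognition: int = 4
    tr_seconds: float = 2.0
    # fixation, first cue, encoding, maintenance durations (s)
    trial_timing: tuple[float, float, float, float] = (1.0, 1.0, 2.0, 4.0)
    catch_fraction: float = 1.0 / 6.0
    # non-catch attention trials per run, split evenly over the 3 cue conditions
    trials_per_attention_run: int = 30
    localizer_blocks_per_run: int = 9
    pictures_per_block: int = 10
    picture_duration: float = 2.0
    gabor_block_duration: float = 8.0
    inter_trial_interval: float = 4.0
    noise_sd: float = 1.0
    # scale of motion-correlated nuisance mixed into the BOLD signal
    motion_coupling: float = 0.1
    hrf_params: HrfParams = field(default_factory=HrfParams)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_voxels_per_roi": self.n_voxels_per_roi,
            "n_runs_attention": self.n_runs_attention,
            "n_runs_localizer": self.n_runs_localizer,
            "n_runs_recognition": self.n_runs_recognition,
            "trials_per_attention_run": self.trials_per_attention_run,
            "localizer_blocks_per_run": self.localizer_blocks_per_run,
            "pictures_per_block": self.pictures_per_block,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValidationError(f"{name} must be >= 1, got {value}")
        if self.n_categories < 2:
            raise ValidationError("need at least 2 stimulus categories")
        if not (0.0 <= self.catch_fraction < 1.0):
            raise ValidationError("catch_fraction must lie in [0, 1)")
        if not self.tr_seconds > 0:
            raise ValidationError("tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.trials_per_attention_run % len(CUE_CONDITIONS):
            raise ValidationError(
                "trials_per_attention_run must divide evenly over the 3 cue conditions"
            )

    @property
    def trial_duration(self) -> float:
        """Length of the modeled 8-s trial epoch."""
        return float(sum(self.trial_timing))

    @property
    def epoch_slot(self) -> float:
        """Seconds allocated per attention trial including the inter-trial gap."""
        return self.trial_duration + self.inter_trial_interval


def _as_condition_map(value, conditions, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [c for c in conditions if c not in value]
        if missing:
            raise ConfigurationError(f"{name} missing conditions: {missing}")
        return {c: float(value[c]) for c in conditions}
    return {c: float(value) for c in conditions}


@dataclass
class GroundTruth:
    """Generative parameters: what the pipeline should recover.

    ``gain_attended`` / ``gain_ignored`` scale the neural response of the
    cued / uncued picture per condition (keys PA, RA and PI, RI); either a
    scalar per condition or a per-ROI mapping ``{condition: {roi: gain}}``.
    ``repulsion_rho`` shrinks, at retrieval, the component of an ignored
    item's pattern lying in the span of its attended partners' patterns.
    ``behavior_hit_means`` are per cue-attention condition recognition hit
    probabilities; ``confidence_high_prob`` is the chance a hit is reported
    with high confidence.
    """

    gain_attended: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {"PA": 1.0, "RA": 0.8}
    )
    gain_ignored: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {"PI": 0.3, "RI": 0.55}
    )
    gain_baseline: float | Mapping[str, float] = 1.0
    repulsion_rho: Mapping[str, float] = field(
        default_factory=lambda: {"prospective": 0.5, "retrospective": 0.0}
    )
    behavior_hit_means: Mapping[str, float] = field(
        default_factory=lambda: {"BL": 0.80, "PA": 0.80, "PI": 0.35, "RA": 0.70, "RI": 0.55}
    )
    false_alarm_rate: float = 0.15
    confidence_high_prob: Mapping[str, float] = field(
        default_factory=lambda: {"BL": 0.75, "PA": 0.75, "PI": 0.45, "RA": 0.60, "RI": 0.50}
    )
    prototype_scale: float = 1.0
    item_scale: float = 0.5
    # subject x ROI pattern common to all single-trial retrieval maps; gives
    # item pairs the positive baseline similarity real t-maps share
    retrieval_global_scale: float = 1.0
    no_response_prob: float = 0.0

    def __post_init__(self) -> None:
        hits = _as_condition_map(self.behavior_hit_means, CUE_ATTENTION_CONDITIONS,
                                 "behavior_hit_means")
        for cond, p in {**hits, "false_alarm": self.false_alarm_rate}.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability for {cond!r} must be in [0,1], got {p}")
        for cond, rho in dict(self.repulsion_rho).items():
            if not (0.0 <= rho <= 1.0):
                raise ValidationError(f"repulsion_rho[{cond!r}] must be in [0,1], got {rho}")
        for cond, g in list(self.gain_attended.items()) + list(self.gain_ignored.items()):
            vals = g.values() if isinstance(g, Mapping) else [g]
            if any(v < 0 for v in vals):
                raise ValidationError(f"gain for {cond!r} must be >= 0")
        if not (0.0 <= self.no_response_prob < 1.0):
            raise ValidationError("no_response_prob must be in [0,1)")

    def gain(self, cue_attention: str, roi: str) -> float:
        """Resolve the neural gain for a cue-attention condition in one ROI."""
        if cue_attention == "BL":
            src = self.gain_baseline
        elif cue_attention in self.gain_attended:
            src = self.gain_attended[cue_attention]
        elif cue_attention in self.gain_ignored:
            src = self.gain_ignored[cue_attention]
        else:
            raise ConfigurationError(f"no gain defined for condition {cue_attention!r}")
        if isinstance(src, Mapping):
            if roi not in src:
                raise ConfigurationError(f"gain for {cue_attention!r} missing ROI {roi!r}")
            return float(src[roi])
        return float(src)

    def hit_mean(self, cue_attention: str) -> float:
        try:
            return float(self.behavior_hit_means[cue_attention])
        except KeyError as exc:
            raise ConfigurationError(
                f"behavior_hit_means missing condition {cue_attention!r}"
            ) from exc


def category_prototypes(
    rng: np.random.Generator,
    roi_names: Sequence[str],
    n_voxels: int,
    n_categories: int,
    scale: float = 1.0,
    include_rest: bool = True,
) -> dict[str, np.ndarray]:
    """Draw per-ROI category prototype patterns (rows: categories [+ rest]).

    Gaussian draws in ``n_voxels`` dimensions are linearly independent with
    probability 1 and near-orthogonal for realistic voxel counts.
    """
    n_rows = n_categories + int(include_rest)
    out: dict[str, np.ndarray] = {}
    for roi in roi_names:
        protos = rng.standard_normal((n_rows, n_voxels))
        protos /= np.linalg.norm(protos, axis=1, keepdims=True)
        out[roi] = protos * scale * np.sqrt(n_voxels)
    return out
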
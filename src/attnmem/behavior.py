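"""Behavioral memory measures from the 4-point old/new recognition responses.

Responses: 1 = definitely old, 2 = probably old, 3 = probably novel,
4 = definitely novel. An old item judged 1 or 2 is a hit; a novel item judged
1 or 2 is a false alarm. Confidence is scored 2 for "definitely" and 1 for
"probably" responses and reported for remembered (hit) items only.

Per-condition measures:
    attentional modulation = hit(attended) - hit(ignored)
    memory capacity        = hit(attended) + hit(ignored) - 2 * FA   (two items)
                           = hit(baseline) - FA                       (baseline)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ValidationError

_CUE_ATTENTION = {("prospective", "attended"): "PA", ("prospective", "ignored"): "PI",
                  ("retrospective", "attended"): "RA", ("retrospective", "ignored"): "RI",
                  ("baseline", "attended"): "BL"}


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    responses = t.response.dropna()
    if not responses.isin([1.0, 2.0, 3.0, 4.0]).all():
        raise ValidationError("responses must be in {1,2,3,4} or missing")
    if "is_catch" in t.columns:  # catch items never enter behavioral measures
        t = t[~t.is_catch.astype(bool)]
    if "cue_attention" not in t.columns:
        t["cue_attention"] = [
            "novel" if c == "novel" else _CUE_ATTENTION[(c, s)]
            for c, s in zip(t.cue_condition, t.attention_status)
        ]
    return t


def hit_and_fa_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject hit rate per cue-attention condition plus false-alarm rate.

    Missing responses are excluded from the denominator; an empty cell is a
    missing value, never zero.
    """
    t = _validate(table)
    t = t[t.response.notna()]
    t["old_judgment"] = t.response.isin([1.0, 2.0])
    rates = (t.groupby(["subject", "cue_attention"]).old_judgment.mean()
             .unstack("cue_attention"))
    rates = rates.rename(columns={"novel": "FA"})
    return rates


def confidence_remembered(table: pd.DataFrame) -> pd.DataFrame:
    """Mean confidence (1 = probably, 2 = definitely) over hits, per condition.

    Only remembered old items enter; a cell with no hits is missing.
    """
    t = _validate(table)
    hits = t[(t.cue_attention != "novel") & t.response.isin([1.0, 2.0])].copy()
    hits["confidence"] = np.where(hits.response == 1.0, 2.0, 1.0)
    return (hits.groupby(["subject", "cue_attention"]).confidence.mean()
            .unstack("cue_attention"))


def attentional_modulation(rates: pd.DataFrame) -> pd.DataFrame:
    """hit(attended) - hit(ignored) per cue condition; positive = better target
    memory. Missing input rates propagate as missing values."""
    out = pd.DataFrame(index=rates.index)
    for cond, att, ign in (("prospective", "PA", "PI"), ("retrospective", "RA", "RI")):
        if att in rates.columns and ign in rates.columns:
            out[cond] = rates[att] - rates[ign]
        else:
            out[cond] = np.nan
    return out


def memory_capacity(rates: pd.DataFrame) -> pd.DataFrame:
    """Number of items per trial retained in long-term memory, per condition.

    Two-item conditions: hit(attended) + hit(ignored) - 2*FA (maximum 2);
    baseline: hit(baseline) - FA (maximum 1). No clipping is applied.
    """
    if "FA" not in rates.columns:
        raise ValidationError("false-alarm rate (column 'FA') is required")
    out = pd.DataFrame(index=rates.index)
    for cond, att, ign in (("prospective", "PA", "PI"), ("retrospective", "RA", "RI")):
        if att in rates.columns and ign in rates.columns:
            out[cond] = rates[att] + rates[ign] - 2.0 * rates["FA"]
        else:
            out[cond] = np.nan
    out["baseline"] = (rates["BL"] - rates["FA"]) if "BL" in rates.columns else np.nan
    return out


def behavioral_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-subject summary: hit rates, confidence, modulation, capacity."""
    rates = hit_and_fa_rates(table)
    conf = confidence_remembered(table)
    mod = attentional_modulation(rates)
    cap = memory_capacity(rates)
    pieces = []
    for measure, frame in (("hit_rate", rates), ("confidence", conf),
                           ("attentional_modulation", mod), ("memory_capacity", cap)):
        melted = frame.reset_index().melt(id_vars="subject", var_name="condition",
                                          value_name="value")
        melted["measure"] = measure
        pieces.append(melted)
    return pd.concat(pieces, ignore_index=True)[
        ["subject", "measure", "condition", "value"]]
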
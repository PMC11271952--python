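"""Pair-specific pattern similarity at retrieval.

Within-trial (WT) pairs are the target/distractor picture pairs that were
co-presented in one attention trial; each WT pair is matched one-to-one to a
between-trial (BT) pair that shares the stimulus-category pair, spatial
assignment and memory outcomes and has a recognition lag within tolerance.
Similarity is the Pearson correlation of the two items' single-trial t-maps
across ROI voxels, Fisher-z transformed; mean z(WT) - mean z(BT) below zero
indicates representational repulsion between co-presented items.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .config import ValidationError
from .types import PairSpec
from . import stats as group_stats

R_CLIP = 1.0 - 1e-7  # keeps Fisher z finite on degenerate inputs


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def build_matched_pairs(
    attention_events: pd.DataFrame,
    outcomes: Mapping[str, str],
    recognition_order: Mapping[str, int],
    lag_tolerance: int = 10,
    same_condition: bool = True,
    mode: str = "one-to-one",
    seed: int = 0,
) -> list[PairSpec]:
    """Enumerate WT pairs and deterministically match BT control pairs.

    BT candidates keep one member of the WT pair and swap the other for an
    item never co-presented with it, with the same category, attention status,
    cue condition (when ``same_condition``) and memory outcome, and a
    recognition lag within ``lag_tolerance`` trials of the WT pair's lag.
    Greedy selection prefers the closest lag; ties break by a seeded draw.
    WT pairs with no eligible candidate are excluded from both sides.
    """
    if mode not in ("one-to-one", "average"):
        raise ValidationError(f"unknown matching mode {mode!r}")
    rng = np.random.default_rng(seed)
    ev = attention_events[
        ~attention_events.is_catch & attention_events.item_ignored.notna()
    ]
    copresented: dict[str, set[str]] = {}
    for _, row in ev.iterrows():
        copresented.setdefault(row.item_attended, set()).add(row.item_ignored)
        copresented.setdefault(row.item_ignored, set()).add(row.item_attended)

    def lag(a: str, b: str) -> float:
        if a not in recognition_order or b not in recognition_order:
            return np.nan
        return abs(recognition_order[a] - recognition_order[b])

    def outcome(item: str) -> Optional[str]:
        return outcomes.get(item)

    from .simulate import item_category

    wt_rows = []
    for idx, row in ev.reset_index(drop=True).iterrows():
        a, i = row.item_attended, row.item_ignored
        if outcome(a) is None or outcome(i) is None:
            continue
        wt_rows.append(dict(
            wt_id=f"WT_{idx:03d}", attended=a, ignored=i, condition=row.condition,
            cats=(item_category(a), item_category(i)), side=row.attended_side,
            outs=(outcome(a), outcome(i)), lag=lag(a, i)))

    att_pool = sorted({r["attended"] for r in wt_rows})
    ign_pool = sorted({r["ignored"] for r in wt_rows})
    cond_of = {}
    for r in wt_rows:
        cond_of[r["attended"]] = r["condition"]
        cond_of[r["ignored"]] = r["condition"]

    pairs: list[PairSpec] = []
    used_bt: set[frozenset] = set()
    excluded: list[str] = []
    for r in sorted(wt_rows, key=lambda d: d["wt_id"]):
        a, i = r["attended"], r["ignored"]
        candidates = []
        for i2 in ign_pool:  # swap the ignored member
            if i2 == i or i2 in copresented.get(a, set()):
                continue
            if same_condition and cond_of[i2] != r["condition"]:
                continue
            if item_category(i2) != r["cats"][1] or outcome(i2) != r["outs"][1]:
                continue
            lg = lag(a, i2)
            if np.isnan(lg) or abs(lg - r["lag"]) > lag_tolerance:
                continue
            candidates.append((a, i2, lg))
        for a2 in att_pool:  # swap the attended member
            if a2 == a or a2 in copresented.get(i, set()):
                continue
            if same_condition and cond_of[a2] != r["condition"]:
                continue
            if item_category(a2) != r["cats"][0] or outcome(a2) != r["outs"][0]:
                continue
            lg = lag(a2, i)
            if np.isnan(lg) or abs(lg - r["lag"]) > lag_tolerance:
                continue
            candidates.append((a2, i, lg))
        if mode == "one-to-one":
            candidates = [c for c in candidates
                          if frozenset((c[0], c[1])) not in used_bt]
        if not candidates:
            excluded.append(r["wt_id"])
            continue
        wt = PairSpec(pair_id=r["wt_id"], kind="within_trial", item_attended=a,
                      item_ignored=i, condition=r["condition"],
                      category_pair=r["cats"], side=r["side"], outcomes=r["outs"],
                      lag=r["lag"])
        pairs.append(wt)
        if mode == "one-to-one":
            best = min(abs(c[2] - r["lag"]) for c in candidates)
            ties = [c for c in candidates if abs(c[2] - r["lag"]) == best]
            a2, i2, lg = ties[int(rng.integers(len(ties)))]
            used_bt.add(frozenset((a2, i2)))
            pairs.append(PairSpec(pair_id=f"BT_{r['wt_id'][3:]}", kind="between_trial",
                                  item_attended=a2, item_ignored=i2,
                                  condition=r["condition"], matched_to=r["wt_id"],
                                  category_pair=r["cats"], side=r["side"],
                                  outcomes=r["outs"], lag=lg))
        else:
            for n, (a2, i2, lg) in enumerate(candidates):
                pairs.append(PairSpec(pair_id=f"BT_{r['wt_id'][3:]}_{n:02d}",
                                      kind="between_trial", item_attended=a2,
                                      item_ignored=i2, condition=r["condition"],
                                      matched_to=r["wt_id"], category_pair=r["cats"],
                                      side=r["side"], outcomes=r["outs"], lag=lg))
    if excluded:
        warnings.warn(f"{len(excluded)} within-trial pair(s) excluded: "
                      f"no eligible between-trial match (e.g. {excluded[0]})")
    return pairs


def pairwise_similarity(
    patterns: Mapping[str, np.ndarray],
    pairs: Sequence[PairSpec],
    subject: int = 0,
    roi: str = "",
) -> pd.DataFrame:
    """Pearson correlation across voxels for each pair, Fisher-z transformed.

    Pairs with a missing or zero-variance pattern propagate as missing
    records (r and z NaN) with a warning.
    """
    rows = []
    for pair in pairs:
        pa = patterns.get(pair.item_attended)
        pi = patterns.get(pair.item_ignored)
        r = np.nan
        if pa is None or pi is None:
            warnings.warn(f"pair {pair.pair_id}: missing pattern")
        elif np.std(pa) == 0 or np.std(pi) == 0:
            warnings.warn(f"pair {pair.pair_id}: zero-variance pattern")
        else:
            r = float(np.corrcoef(pa, pi)[0, 1])
        rows.append(dict(subject=subject, roi=roi, condition=pair.condition,
                         pair_id=pair.pair_id, kind=pair.kind, matched_to=pair.matched_to,
                         r=r, z=float(fisher_z(r)) if np.isfinite(r) else np.nan))
    return pd.DataFrame(rows)


def wt_bt_statistic(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per subject x ROI x condition mean z(WT) - mean z(BT), plus group tests.

    Negative values indicate repulsion. Group inference is a paired t test of
    the per-subject WT and BT means across subjects, FDR-corrected over
    ROI x condition cells.
    """
    ok = records[records.z.notna()]
    cell = (ok.groupby(["subject", "roi", "condition", "kind"]).z.mean()
            .unstack("kind"))
    for col in ("within_trial", "between_trial"):
        if col not in cell.columns:
            cell[col] = np.nan
    cell["wt_minus_bt"] = cell["within_trial"] - cell["between_trial"]
    subject_stats = cell.reset_index()
    group_rows = []
    for (roi, cond), sub in subject_stats.groupby(["roi", "condition"]):
        complete = sub.dropna(subset=["within_trial", "between_trial"])
        if len(complete) < 3:
            group_rows.append(dict(roi=roi, condition=cond, mean_wt_minus_bt=np.nan,
                                   t=np.nan, df=np.nan, p=np.nan))
            continue
        res = group_stats.paired_t(complete.within_trial.to_numpy(),
                                   complete.between_trial.to_numpy(),
                                   name=f"{roi}:{cond}")
        group_rows.append(dict(roi=roi, condition=cond,
                               mean_wt_minus_bt=float(complete.wt_minus_bt.mean()),
                               t=res.statistic, df=res.df, p=res.p_raw))
    group = pd.DataFrame(group_rows)
    valid = group.p.notna()
    if valid.any():
        group.loc[valid, "p_fdr"] = group_stats.fdr_bh(group.loc[valid, "p"].to_numpy())
    else:
        group["p_fdr"] = np.nan
    return subject_stats, group


def brain_behavior_correlation(
    statistic: np.ndarray, behavior: np.ndarray
) -> dict[str, float]:
    """Pearson correlation plus a bisquare-weighted robust regression.

    Returns r and its two-sided p, the OLS slope, and the robust (IRLS,
    Tukey bisquare with tuning constant 4.685) slope with its t and p, as
    reported side by side in the figures. Fewer than 5 complete subject
    pairs or a zero-variance input yields missing values.
    """
    x = np.asarray(statistic, dtype=float)
    y = np.asarray(behavior, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    out = dict(r=np.nan, p=np.nan, slope=np.nan, robust_slope=np.nan,
               robust_t=np.nan, robust_p=np.nan, n=int(keep.sum()))
    if len(x) < 5 or np.std(x) == 0 or np.std(y) == 0:
        return out
    r, p = sps.pearsonr(x, y)
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
    df = len(x) - 2
    robust_t = float(rlm.params[1] / rlm.bse[1])
    out.update(r=float(r), p=float(p), slope=float(ols.params[1]),
               robust_slope=float(rlm.params[1]), robust_t=robust_t,
               robust_p=float(2 * sps.t.sf(abs(robust_t), df)))
    return out
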
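"""Group inference and reporting utilities shared by all pipeline stages.

Group-level inference operates on per-subject summary values: classical
paired t tests, fully within-subject two-way repeated-measures ANOVA,
Benjamini-Hochberg FDR adjustment within declared families, and
Cousineau-Morey within-subject error bars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ValidationError


@dataclass
class GroupResult:
    contrast: str
    statistic: float
    df: float
    p_raw: float
    p_fdr: float | None = None
    family: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_raw) and not (0.0 <= self.p_raw <= 1.0):
            raise ValidationError("p value outside [0, 1]")


def paired_t(a: np.ndarray, b: np.ndarray, name: str = "") -> GroupResult:
    """Classical two-sided paired t test with df = n - 1.

    Identical inputs give t = 0, p = 1; zero variance of a non-zero mean
    difference is an error (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    n = len(d)
    if n < 3:
        raise ValidationError("paired t test needs at least 3 complete pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return GroupResult(contrast=name, statistic=0.0, df=n - 1, p_raw=1.0)
        raise ValidationError("zero variance of differences with non-zero mean")
    t = mean / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return GroupResult(contrast=name, statistic=float(t), df=n - 1, p_raw=p)


def rm_anova_2way(data: pd.DataFrame, subject: str = "subject", factor_a: str = "A",
                  factor_b: str = "B", value: str = "value") -> pd.DataFrame:
    """Two-way fully repeated-measures ANOVA by within-subject SS decomposition.

    Requires one observation per subject x A x B cell (no imputation). Error
    terms are the subject-by-factor interactions; a factor with a single
    level is dropped from the output (its SS is identically zero), which
    also gives the one-way repeated-measures reduction.
    """
    d = data[[subject, factor_a, factor_b, value]].dropna()
    a_levels = sorted(d[factor_a].unique())
    b_levels = sorted(d[factor_b].unique())
    subjects = sorted(d[subject].unique())
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    cube = d.pivot_table(index=subject, columns=[factor_a, factor_b], values=value,
                         aggfunc="mean")
    if cube.isna().any().any() or cube.shape != (n, a * b):
        raise ValidationError("incomplete subject x A x B design (no imputation)")
    y = cube.to_numpy().reshape(n, a, b)
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sab = ((y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
               + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
               - grand) ** 2).sum()
    rows = []
    # numerical floor relative to the data's overall scale, so exactly-equal
    # cells give F = 0 instead of 0/0 noise
    tiny = 1e-12 * max(float(((y - grand) ** 2).sum()), 1.0) + 1e-300

    def effect(name, ss, df1, ss_err, df2):
        if df1 == 0:
            return
        ms, ms_err = ss / df1, ss_err / df2
        if ms_err > tiny:
            f = ms / ms_err
        else:
            f = 0.0 if ms <= tiny else np.inf
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        rows.append(dict(effect=name, F=float(f), df1=df1, df2=df2, p=p,
                         ss=float(ss), ss_error=float(ss_err)))

    effect(factor_a, ss_a, a - 1, ss_sa, (n - 1) * (a - 1))
    effect(factor_b, ss_b, b - 1, ss_sb, (n - 1) * (b - 1))
    effect(f"{factor_a}:{factor_b}", ss_ab, (a - 1) * (b - 1),
           ss_sab, (n - 1) * (a - 1) * (b - 1))
    return pd.DataFrame(rows)


def fdr_bh(p_values: np.ndarray, family: str = "") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1).

    adjusted p of the k-th smallest value is min over j >= k of p_(j) * m / j.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def within_subject_sem(data: pd.DataFrame, subject: str = "subject",
                       condition: str = "condition", value: str = "value") -> pd.Series:
    """Within-subject standard errors (Cousineau normalization, Morey correction).

    Values are centered on each subject's mean (plus the grand mean), the
    per-condition SEM is computed on the centered values and inflated by
    sqrt(c / (c - 1)) for c conditions. A single condition falls back to the
    plain between-subject SEM.
    """
    wide = data.pivot_table(index=subject, columns=condition, values=value,
                            aggfunc="mean")
    if wide.isna().any().any():
        raise ValidationError("within-subject error bars need complete data")
    c = wide.shape[1]
    if c == 1:
        return wide.sem(ddof=1)
    centered = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    return centered.sem(ddof=1) * np.sqrt(c / (c - 1))


def report_contrast_table(
    results: list[GroupResult], family: str = ""
) -> pd.DataFrame:
    """Assemble GroupResults into a tidy table with family-wise FDR adjustment."""
    frame = pd.DataFrame([dict(contrast=r.contrast, statistic=r.statistic, df=r.df,
                               p=r.p_raw) for r in results])
    if len(frame):
        frame["p_fdr"] = fdr_bh(frame.p.to_numpy(), family)
        frame["family"] = family
    return frame
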
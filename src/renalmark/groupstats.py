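"""One-way ANOVA (from raw values or printed summaries), Fisher LSD, chi-square.

Immunohistochemistry intensity comparisons in this pipeline are
reported as per-group (n, mean, SD) summaries, so the ANOVA here is
implemented directly from sufficient statistics:

    grand mean  = sum(n_i * m_i) / sum(n_i)
    SS_between  = sum(n_i * (m_i - grand)^2)
    SS_within   = sum((n_i - 1) * s_i^2)
    F           = (SS_between / (g-1)) / (SS_within / (N-g))

with SD always on the n-1 denominator. `anova_from_raw` computes the
summaries and delegates, so the two routes agree exactly.

Fisher LSD post-hoc tests are unadjusted pairwise t-tests pooling the
omnibus within-group mean square:

    t = (m_a - m_b) / sqrt(MS_within * (1/n_a + 1/n_b)),  df = N - g

with two-sided p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "LSDResult",
    "summarize_groups",
    "anova_from_summary",
    "anova_from_raw",
    "lsd_pairwise",
    "chisq_contingency",
]


@dataclass
class GroupSummary:
    """Per-group sufficient statistics: n, mean, SD (n-1), SEM = SD/sqrt(n)."""

    group: str
    n: int
    mean: float
    sd: float

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)


@dataclass
class AnovaResult:
    """One-way ANOVA outcome plus the pooled pieces LSD needs."""

    groups: list[GroupSummary]
    F: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    ms_between: float

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g.group, "n": g.n, "mean": g.mean, "sd": g.sd, "sem": g.sem}
            for g in self.groups
        ]
        return pd.DataFrame(rows)


@dataclass
class LSDResult:
    """Unadjusted pairwise comparison using the omnibus pooled variance."""

    group_a: str
    group_b: str
    mean_diff: float
    t: float
    df: int
    p_value: float


def summarize_groups(values, labels) -> list[GroupSummary]:
    """Compute (n, mean, SD) per group from raw per-sample values."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    out = []
    for g in pd.unique(labels):
        v = values[labels == g]
        out.append(GroupSummary(group=str(g), n=len(v), mean=float(np.mean(v)),
                                sd=float(np.std(v, ddof=1)) if len(v) > 1 else 0.0))
    return out


def anova_from_summary(summaries: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, SD) sufficient statistics.

    Requires >= 2 groups with n >= 2 each. The degenerate all-equal,
    zero-variance case returns F = 0, p = 1.
    """
    if len(summaries) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for s in summaries:
        if s.n < 2:
            raise ValueError(f"group {s.group!r} has n={s.n} < 2")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    n_total = ns.sum()
    g = len(summaries)
    grand = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = g - 1
    df_within = int(n_total) - g
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ss_between == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = math.inf, 0.0
    else:
        F = ms_between / ms_within
        p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(groups=list(summaries), F=F, df_between=df_between,
                       df_within=df_within, p_value=p,
                       ms_within=ms_within, ms_between=ms_between)


def anova_from_raw(values, labels) -> AnovaResult:
    """One-way ANOVA from per-sample values and group labels.

    Summarizes each group and delegates to :func:`anova_from_summary`,
    so raw and summary routes agree exactly on the same data.
    """
    return anova_from_summary(summarize_groups(values, labels))


def lsd_pairwise(result: AnovaResult) -> list[LSDResult]:
    """Fisher LSD: all unordered pairs, two-sided, no multiplicity adjustment."""
    out = []
    for a, b in combinations(result.groups, 2):
        diff = a.mean - b.mean
        se = math.sqrt(result.ms_within * (1.0 / a.n + 1.0 / b.n))
        if se == 0.0:
            t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), result.df_within))
        out.append(LSDResult(group_a=a.group, group_b=b.group, mean_diff=diff,
                             t=t, df=result.df_within, p_value=p))
    return out


def chisq_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns (statistic, df, p) with df = (r-1)(c-1). All marginals
    must be positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)
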
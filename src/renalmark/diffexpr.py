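"""Differential expression between groups, per-stage summaries, trend tests.

The calling rule is a joint threshold: a feature passes when its raw
fold change is at least `gene_fc_cutoff` (or at most its reciprocal)
AND its test p-value is at most `gene_p_cutoff`. The default test is
Welch's two-sample t on log2(x+1); fold change is always the plain
ratio of raw group means (optionally stabilized by a pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .dataio import ExpressionMatrix
from .groupstats import GroupSummary

__all__ = [
    "DifferentialCall",
    "fold_change",
    "de_test",
    "calls_to_frame",
    "group_summaries",
    "stage_trend",
]


@dataclass
class DifferentialCall:
    """Per-feature differential-expression outcome."""

    feature: str
    mean_case: float
    mean_control: float
    fc: float
    p_value: float
    direction: str  # up / down / unchanged
    passes: bool


def fold_change(mean_case: float, mean_control: float, pseudocount: float = 0.0) -> float:
    """Plain ratio of group means: (case + pc) / (control + pc).

    A positive pseudocount is required when the control mean is zero.
    """
    if mean_case < 0 or mean_control < 0:
        raise ValueError("means must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if mean_control + pseudocount == 0:
        raise ValueError("control mean and pseudocount are both zero; ratio undefined")
    return (mean_case + pseudocount) / (mean_control + pseudocount)


def _direction(fc: float, cutoff: float) -> str:
    if fc >= cutoff:
        return "up"
    if fc <= 1.0 / cutoff:
        return "down"
    return "unchanged"


def de_test(
    matrix: ExpressionMatrix,
    case_group: str,
    control_group: str,
    config: PipelineConfig | None = None,
    pseudocount: float = 0.0,
) -> list[DifferentialCall]:
    """Per-feature differential test between two annotated groups.

    Welch t-test on log2(value+1) by default (Mann-Whitney U when
    config.de_method == "mannwhitney"); fold change on raw means.
    Features with zero variance in both groups get p = 1. Direction
    is thresholded at the configured fold-change cutoff; ``passes``
    additionally requires p <= gene_p_cutoff.
    """
    config = config or PipelineConfig()
    case_samples = matrix.samples_in_group(case_group)
    ctrl_samples = matrix.samples_in_group(control_group)
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError(
            f"groups {case_group!r} ({len(case_samples)}) and {control_group!r} "
            f"({len(ctrl_samples)}) must each have >= 2 samples"
        )
    case = matrix.values[case_samples].to_numpy(dtype=float)
    ctrl = matrix.values[ctrl_samples].to_numpy(dtype=float)

    if config.de_method == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(
                np.log2(case + 1.0), np.log2(ctrl + 1.0), axis=1, equal_var=False
            )
    else:
        pvals = np.empty(case.shape[0])
        for i in range(case.shape[0]):
            if np.ptp(case[i]) == 0 and np.ptp(ctrl[i]) == 0 and case[i, 0] == ctrl[i, 0]:
                pvals[i] = np.nan
                continue
            pvals[i] = stats.mannwhitneyu(case[i], ctrl[i], alternative="two-sided").pvalue
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero variance in both groups

    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    calls = []
    for feat, mc, m0, p in zip(matrix.features, mean_case, mean_ctrl, pvals):
        fc = fold_change(float(mc), float(m0), pseudocount)
        direction = _direction(fc, config.gene_fc_cutoff)
        passes = direction != "unchanged" and p <= config.gene_p_cutoff
        calls.append(
            DifferentialCall(
                feature=str(feat),
                mean_case=float(mc),
                mean_control=float(m0),
                fc=fc,
                p_value=float(p),
                direction=direction,
                passes=bool(passes),
            )
        )
    return calls


def calls_to_frame(calls: list[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [c.feature for c in calls],
            "mean_case": [c.mean_case for c in calls],
            "mean_control": [c.mean_control for c in calls],
            "fc": [c.fc for c in calls],
            "p": [c.p_value for c in calls],
            "direction": [c.direction for c in calls],
            "passes": [c.passes for c in calls],
        }
    )


def group_summaries(matrix: ExpressionMatrix, feature: str, groups: list[str]) -> list[GroupSummary]:
    """Per-group n / mean / SD / SEM for one feature (SD on n-1)."""
    if feature not in matrix.values.index:
        raise KeyError(f"feature {feature!r} not in matrix")
    row = matrix.values.loc[feature]
    out = []
    for g in groups:
        samples = matrix.samples_in_group(g)
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
        v = row[samples].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        out.append(GroupSummary(group=g, n=len(v), mean=float(np.mean(v)), sd=sd))
    return out


def stage_trend(
    matrix: ExpressionMatrix,
    feature: str,
    ordered_groups: list[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monotone-trend test: Spearman correlation of expression with stage rank.

    The two-sided p-value comes from a seeded permutation null
    (expression values shuffled against ranks). Flat data returns
    (0, 1) rather than an error.
    """
    if len(ordered_groups) < 3:
        raise ValueError("need at least 3 ordered groups for a trend test")
    values, ranks = [], []
    for rank, g in enumerate(ordered_groups):
        samples = matrix.samples_in_group(g)
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
        r = matrix.ordinal_rank.get(g, rank)
        for s in samples:
            values.append(float(matrix.values.loc[feature, s]))
            ranks.append(r)
    values = np.asarray(values)
    ranks = np.asarray(ranks, dtype=float)
    if np.ptp(values) == 0:
        return 0.0, 1.0
    rho = float(stats.spearmanr(values, ranks).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(values)
        if abs(float(stats.spearmanr(perm, ranks).statistic)) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return rho, float(p)
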
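"""Group-level summaries and significance tests for section means.

The design: several mice per treatment group, each mouse's tissue
sections measured with at least two technical replicates. Technical
replicates are averaged per mouse *before* any group statistic, so the
biological n is the number of mice; pooling technical replicates as
independent observations is deliberately not offered. Groups are
summarized as mean ± SEM and compared pairwise by unpaired two-tailed
Student's t (pooled variance, df = nA + nB - 2), with the usual star
conventions (* p<0.05, ** p<0.01, *** p<0.001) and no multiple-testing
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "collapse_technical",
    "summarize_group",
    "student_t_from_data",
    "student_t_from_summary",
    "fold_change",
    "significance_stars",
]

#: p-value below which exact-zero pooled variance with unequal means is
#: reported; flagged degenerate rather than a literal zero.
_DEGENERATE_P = 1e-300


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    """One group's per-mouse values with mean ± SEM."""

    label: str
    values: tuple[float, ...]
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class GroupComparison:
    """Pairwise unpaired Student's t result between groups A and B."""

    pair: tuple[str, str]
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    stars: str
    fold_change: float | None  # mean_B / mean_A; None when mean_A <= 0
    degenerate: bool = False


def collapse_technical(sections: Mapping[str, Sequence[float]]
                       ) -> dict[str, float]:
    """Average technical-replicate section values per mouse.

    ``sections`` maps mouse id -> section means; returns one value per
    mouse, the unit of biological replication.
    """
    out = {}
    for mouse, vals in sections.items():
        vals = list(vals)
        if not vals:
            raise ValueError(f"mouse {mouse!r} has no section values")
        out[mouse] = float(np.mean(vals))
    return out


def summarize_group(label: str, values: Sequence[float]) -> GroupSummary:
    """Mean ± SEM (sample SD / sqrt(n)) of per-mouse values; n >= 2."""
    vals = tuple(float(v) for v in values)
    n = len(vals)
    if n < 2:
        raise ValueError(f"group {label!r} needs >= 2 values, got {n}")
    arr = np.asarray(vals)
    return GroupSummary(label=label, values=vals, n=n,
                        mean=float(arr.mean()),
                        sem=float(arr.std(ddof=1)) / math.sqrt(n))


def _comparison(pair: tuple[str, str], meanA: float, sdA: float, nA: int,
                meanB: float, sdB: float, nB: int) -> GroupComparison:
    df = nA + nB - 2
    pooled_var = ((nA - 1) * sdA**2 + (nB - 1) * sdB**2) / df
    fold = meanB / meanA if meanA > 0 else None
    if pooled_var == 0:
        # all observations identical within groups
        if meanA == meanB:
            return GroupComparison(pair, 0.0, df, 1.0, "ns", fold)
        return GroupComparison(pair, math.inf if meanB > meanA else -math.inf,
                               df, _DEGENERATE_P, "***", fold, degenerate=True)
    t, p = sps.ttest_ind_from_stats(meanA, sdA, nA, meanB, sdB, nB,
                                    equal_var=True)
    # orient t as B vs A so sign matches the fold direction
    t = float(-t)
    p = float(p)
    return GroupComparison(pair, t, df, p, significance_stars(p), fold)


def student_t_from_data(labelA: str, valuesA: Sequence[float],
                        labelB: str, valuesB: Sequence[float]
                        ) -> GroupComparison:
    """Pooled-variance two-tailed t test from raw per-mouse values."""
    a = summarize_group(labelA, valuesA)
    b = summarize_group(labelB, valuesB)
    return _comparison((labelA, labelB),
                       a.mean, a.sem * math.sqrt(a.n), a.n,
                       b.mean, b.sem * math.sqrt(b.n), b.n)


def student_t_from_summary(meanA: float, semA: float, nA: int,
                           meanB: float, semB: float, nB: int,
                           pair: tuple[str, str] = ("A", "B")
                           ) -> GroupComparison:
    """Same test reconstructed from published mean ± SEM summaries.

    SDs are recovered as ``sem * sqrt(n)``; agrees exactly with
    :func:`student_t_from_data` when the summary came from the same data.
    """
    if nA < 2 or nB < 2:
        raise ValueError("both groups need n >= 2")
    return _comparison(pair, meanA, semA * math.sqrt(nA), nA,
                       meanB, semB * math.sqrt(nB), nB)


def fold_change(summaryA: GroupSummary, summaryB: GroupSummary) -> float:
    """Ratio of group means, B relative to A."""
    if summaryA.mean <= 0:
        raise ValueError("fold change undefined: reference mean <= 0")
    return summaryB.mean / summaryA.mean


def pairwise_comparisons(summaries: Sequence[GroupSummary]
                         ) -> list[GroupComparison]:
    """All ordered adjacent-and-reference comparisons among groups.

    For groups in the given order, compares each later group against the
    first (reference) and each group against its predecessor, without
    duplicates — the comparisons such multi-group designs report.
    """
    out = []
    seen = set()
    for i in range(1, len(summaries)):
        for j in (0, i - 1):
            key = (summaries[j].label, summaries[i].label)
            if j < i and key not in seen:
                seen.add(key)
                a, b = summaries[j], summaries[i]
                out.append(student_t_from_data(a.label, a.values,
                                               b.label, b.values))
    return out
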
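"""Group-level comparison statistics across raters.

Summarizes each metric across a group of raters by its mean, range
(max − min) and *population* standard deviation (divisor ``n``, the
convention of the reported group tables), orders raters best-to-worst with
tie groups, and computes relative outperformance — the percentage
improvement of one rater's aggregate over a baseline's,
``100 * (a - b) / b``.

All statistics are computed on unrounded aggregates; rounding (half-up, one
decimal for means/ranges, integer for SDs) is applied only when rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .metrics import RaterSummary

__all__ = [
    "GroupSummary",
    "group_mean",
    "group_range",
    "population_sd",
    "relative_outperformance",
    "group_summary",
    "ordering",
    "ordering_table",
    "summaries_frame",
]


def group_mean(values: Sequence[float]) -> float:
    """Arithmetic mean of a group's percentages (unrounded)."""
    if not values:
        raise ValueError("cannot average an empty group")
    return sum(values) / len(values)


def group_range(values: Sequence[float]) -> float:
    """max − min of a group's percentages."""
    if not values:
        raise ValueError("cannot take the range of an empty group")
    return max(values) - min(values)


def population_sd(values: Sequence[float]) -> float:
    """Population standard deviation (divisor n, not n − 1)."""
    if not values:
        raise ValueError("cannot take the SD of an empty group")
    mu = group_mean(values)
    return math.sqrt(sum((x - mu) ** 2 for x in values) / len(values))


def relative_outperformance(a: float, b: float) -> float:
    """Percentage improvement of ``a`` relative to baseline ``b``: 100·(a−b)/b.

    Always baseline-denominated; compute on unrounded aggregates.
    """
    if b <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (a - b) / b


@dataclass(frozen=True)
class GroupSummary:
    """One metric summarized across a group of raters."""

    metric: str
    members: tuple[tuple[str, float], ...]  # (rater_id, unrounded percentage)
    mean: float
    range: float
    sd: float
    ordering: tuple[tuple[str, ...], ...]  # best-to-worst; inner tuples are tie groups


def ordering(members: Mapping[str, float], tie_decimals: int = 1) -> tuple[tuple[str, ...], ...]:
    """Best-to-worst ordering with tie groups.

    Sorting uses unrounded values; raters whose values coincide once rounded
    to ``tie_decimals`` (the reported precision) form a tie group.
    """
    ranked = sorted(members.items(), key=lambda kv: (-kv[1], kv[0]))
    groups: list[list[str]] = []
    last_rounded: Optional[float] = None
    for rater, value in ranked:
        r = round_half_up(value, tie_decimals)
        if groups and r == last_rounded:
            groups[-1].append(rater)
        else:
            groups.append([rater])
        last_rounded = r
    return tuple(tuple(g) for g in groups)


def group_summary(metric: str, members: Mapping[str, float]) -> GroupSummary:
    """Mean, range, population SD and best-to-worst ordering for one metric."""
    if not members:
        raise ValueError("group has no members")
    values = list(members.values())
    return GroupSummary(
        metric=metric,
        members=tuple(members.items()),
        mean=group_mean(values),
        range=group_range(values),
        sd=population_sd(values),
        ordering=ordering(members),
    )


def _render_ordering(groups: tuple[tuple[str, ...], ...]) -> str:
    parts = []
    for g in groups:
        if len(g) == 1:
            parts.append(g[0])
        else:
            parts.append(" and ".join(g) + " (a tie)")
    return ", ".join(parts)


METRIC_LABELS = {
    "m1_pct": "M1%",
    "m3_pct": "M3%",
    "m5_pct": "M5%",
    "avg_recall_pct": "Average recall",
    "avg_precision_pct": "Average precision",
    "f1_pct": "Average F1-measure",
    "avg_ndcg_pct": "Average NDCG",
}


def ordering_table(
    summaries: Mapping[str, RaterSummary],
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Best-to-worst report across all raters, one row per metric.

    ``groups`` optionally names rater subgroups (e.g. symptom checkers vs
    physicians); each gets its own range and SD columns, rounded per the
    reporting convention (range to one decimal, SD to integer).  The
    ordering itself always spans every rater.
    """
    if not summaries:
        raise ValueError("no rater summaries given")
    if groups is None:
        groups = {"all": list(summaries)}
    for gname, members in groups.items():
        missing = [r for r in members if r not in summaries]
        if missing:
            raise ValueError(f"group {gname!r} names unknown raters: {missing}")
    rows = []
    for metric in RaterSummary.METRICS:
        values = {rater: getattr(s, metric) for rater, s in summaries.items()}
        row: dict[str, object] = {
            "metric": METRIC_LABELS[metric],
            "ordering": _render_ordering(ordering(values)),
        }
        for gname, members in groups.items():
            sub = [values[r] for r in members]
            row[f"{gname}_range"] = round_half_up(group_range(sub), 1)
            row[f"{gname}_sd"] = int(round_half_up(population_sd(sub), 0))
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_frame(summaries: Sequence[RaterSummary], decimals: int = 1) -> pd.DataFrame:
    """Rater-by-metric table of reported (half-up rounded) percentages."""
    rows = []
    for s in summaries:
        row = {"rater_id": s.rater_id, "n_vignettes": s.n_vignettes}
        row.update({m: round_half_up(v, decimals) for m, v in s.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)
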
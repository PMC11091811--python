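"""Per-vignette and aggregate accuracy metrics for ranked differentials.

Seven metrics quantify a rater's diagnostic accuracy against a gold ranked
list of ``n`` diseases (main diagnosis first):

* **M1/M3/M5** — indicator that the gold main diagnosis appears within the
  top 1/3/5 positions of the rater's differential; reported as the
  percentage of vignettes satisfying it.
* **recall** — fraction of gold diseases that appear anywhere in the
  differential (each gold disease credited at most once).
* **precision** — fraction of differential entries that match some gold
  disease (duplicates inflate the denominator; a gold disease grants at most
  one credit).
* **F1** — harmonic mean of the *aggregate* average recall and precision.
* **NDCG** — discounted cumulative gain with graded relevance ``n - i + 1``
  for the disease at gold position ``i`` (a 2-disease gold list carries
  relevancies 2 and 1), discount ``log2(position + 1)``, normalized by the
  gold list's own DCG.  A gold disease's relevance is consumed by the first
  differential entry that matches it.

All per-vignette values are fractions in [0, 1]; aggregation multiplies by
100.  Reporting rounds half-up to one decimal; stored aggregates stay
unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .lexicon import DiseaseLexicon, _keys_match, match_rank, normalize_label

__all__ = [
    "VignetteMetrics",
    "RaterSummary",
    "m_at_k",
    "vignette_recall",
    "vignette_precision",
    "gold_dcg",
    "dcg",
    "ndcg",
    "score_vignette",
    "aggregate_rater",
    "harmonic_f1",
]


@dataclass(frozen=True)
class VignetteMetrics:
    """One rater's scores on one vignette."""

    vignette_id: str
    m1: int
    m3: int
    m5: int
    recall: float
    precision: float
    ndcg: float

    def __post_init__(self) -> None:
        if not (self.m1 <= self.m3 <= self.m5):
            raise ValueError("top-k indicators must be monotone: m1 <= m3 <= m5")
        for name in ("m1", "m3", "m5", "recall", "precision", "ndcg"):
            val = getattr(self, name)
            if not 0 <= val <= 1 + 1e-12:
                raise ValueError(f"{name}={val} outside [0, 1]")

    @classmethod
    def zero(cls, vignette_id: str) -> "VignetteMetrics":
        """The all-zero score assigned to failed or empty sessions."""
        return cls(vignette_id, 0, 0, 0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class RaterSummary:
    """A rater's aggregate metric vector (percentages, unrounded)."""

    rater_id: str
    n_vignettes: int
    m1_pct: float
    m3_pct: float
    m5_pct: float
    avg_recall_pct: float
    avg_precision_pct: float
    f1_pct: float
    avg_ndcg_pct: float

    METRICS = (
        "m1_pct",
        "m3_pct",
        "m5_pct",
        "avg_recall_pct",
        "avg_precision_pct",
        "f1_pct",
        "avg_ndcg_pct",
    )

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in self.METRICS}


def m_at_k(
    ddx: Sequence[str],
    gold_main: str,
    k: int,
    lexicon: Optional[DiseaseLexicon] = None,
) -> int:
    """1 iff the gold main diagnosis is matched within the top ``k`` entries."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rank = match_rank(ddx, gold_main, lexicon)
    return int(rank is not None and rank <= k)


def _canonical_lists(
    ddx: Iterable[str], gold_list: Iterable[str], lexicon: Optional[DiseaseLexicon]
) -> tuple[list[str], list[str]]:
    return (
        [normalize_label(d, lexicon) for d in ddx],
        [normalize_label(g, lexicon) for g in gold_list],
    )


def vignette_recall(
    ddx: Sequence[str],
    gold_list: Sequence[str],
    lexicon: Optional[DiseaseLexicon] = None,
) -> float:
    """Fraction of gold diseases matched by at least one differential entry."""
    if not gold_list:
        raise ValueError("gold list must be non-empty")
    c_ddx, c_gold = _canonical_lists(ddx, gold_list, lexicon)
    hit = sum(1 for g in c_gold if any(_keys_match(p, g, lexicon) for p in c_ddx))
    return hit / len(c_gold)


def vignette_precision(
    ddx: Sequence[str],
    gold_list: Sequence[str],
    lexicon: Optional[DiseaseLexicon] = None,
) -> float:
    """Fraction of differential entries matching a gold disease.

    Every entry (duplicates included) counts in the denominator; each gold
    disease can justify at most one numerator credit.  Empty differential
    scores 0 by convention.
    """
    if not ddx:
        return 0.0
    c_ddx, c_gold = _canonical_lists(ddx, gold_list, lexicon)
    consumed = [False] * len(c_gold)
    credit = 0
    for p in c_ddx:
        for j, g in enumerate(c_gold):
            if not consumed[j] and _keys_match(p, g, lexicon):
                consumed[j] = True
                credit += 1
                break
    return credit / len(c_ddx)


def gold_dcg(gold_list: Sequence[str]) -> float:
    """DCG of the gold ranked list itself: relevance ``n - i + 1`` at position ``i``."""
    n = len(gold_list)
    if n == 0:
        raise ValueError("gold list must be non-empty")
    return sum((n - i + 1) / math.log2(i + 1) for i in range(1, n + 1))


def dcg(
    ddx: Sequence[str],
    gold_list: Sequence[str],
    lexicon: Optional[DiseaseLexicon] = None,
) -> float:
    """Discounted cumulative gain of a differential against the gold ranking.

    The entry at (1-based) position ``i`` earns ``(n - j + 1) / log2(i + 1)``
    when it matches the not-yet-consumed gold disease at position ``j``;
    unmatched and duplicate entries earn nothing.
    """
    c_ddx, c_gold = _canonical_lists(ddx, gold_list, lexicon)
    n = len(c_gold)
    consumed = [False] * n
    total = 0.0
    for i, p in enumerate(c_ddx, start=1):
        for j, g in enumerate(c_gold):
            if not consumed[j] and _keys_match(p, g, lexicon):
                consumed[j] = True
                total += (n - j) / math.log2(i + 1)  # relevance n - (j+1) + 1
                break
    return total


def ndcg(
    ddx: Sequence[str],
    gold_list: Sequence[str],
    lexicon: Optional[DiseaseLexicon] = None,
) -> float:
    """NDCG in [0, 1]: the rater's DCG over the gold list's own DCG."""
    return dcg(ddx, gold_list, lexicon) / gold_dcg(gold_list)


def score_vignette(
    vignette_id: str,
    ddx: Sequence[str],
    gold_list: Sequence[str],
    lexicon: Optional[DiseaseLexicon] = None,
) -> VignetteMetrics:
    """All seven per-vignette quantities in one pass.

    ``gold_list`` is the gold ranked list, main diagnosis first.  An empty
    differential scores zero on everything.
    """
    if not gold_list:
        raise ValueError("gold list must be non-empty")
    if not ddx:
        return VignetteMetrics.zero(vignette_id)
    c_ddx, c_gold = _canonical_lists(ddx, gold_list, lexicon)
    n = len(c_gold)

    # rank of the main diagnosis (gold position 1)
    main_rank = None
    for i, p in enumerate(c_ddx, start=1):
        if _keys_match(p, c_gold[0], lexicon):
            main_rank = i
            break

    # recall: each gold disease credited once if matched anywhere
    hit = sum(1 for g in c_gold if any(_keys_match(p, g, lexicon) for p in c_ddx))

    # precision + DCG share the consumption scan
    consumed = [False] * n
    credit = 0
    dcg_total = 0.0
    for i, p in enumerate(c_ddx, start=1):
        for j, g in enumerate(c_gold):
            if not consumed[j] and _keys_match(p, g, lexicon):
                consumed[j] = True
                credit += 1
                dcg_total += (n - j) / math.log2(i + 1)
                break

    return VignetteMetrics(
        vignette_id=vignette_id,
        m1=int(main_rank is not None and main_rank <= 1),
        m3=int(main_rank is not None and main_rank <= 3),
        m5=int(main_rank is not None and main_rank <= 5),
        recall=hit / n,
        precision=credit / len(c_ddx),
        ndcg=dcg_total / gold_dcg(c_gold),
    )


def harmonic_f1(recall_pct: float, precision_pct: float) -> float:
    """Harmonic mean 2RP/(R+P) of aggregate recall and precision; 0 when both are 0."""
    if recall_pct == 0 and precision_pct == 0:
        return 0.0
    return 2 * recall_pct * precision_pct / (recall_pct + precision_pct)


def aggregate_rater(
    per_vignette: Sequence[VignetteMetrics], rater_id: str = ""
) -> RaterSummary:
    """Aggregate per-vignette scores into a rater's summary percentages.

    F1 is the harmonic mean of the *aggregate* average recall and average
    precision (not a per-vignette average) — the convention under which each
    rater's printed F1 follows from their printed recall and precision.
    """
    if not per_vignette:
        raise ValueError("cannot aggregate an empty list of vignette scores")
    n = len(per_vignette)

    def pct(attr: str) -> float:
        return 100.0 * sum(getattr(m, attr) for m in per_vignette) / n

    recall, precision = pct("recall"), pct("precision")
    return RaterSummary(
        rater_id=rater_id,
        n_vignettes=n,
        m1_pct=pct("m1"),
        m3_pct=pct("m3"),
        m5_pct=pct("m5"),
        avg_recall_pct=recall,
        avg_precision_pct=precision,
        f1_pct=harmonic_f1(recall, precision),
        avg_ndcg_pct=pct("ndcg"),
    )
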
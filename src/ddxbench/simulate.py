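"""Synthetic suites, lexicons and simulated raters with known ground truth.

The generator emulates the statistical structure the evaluation pipeline
assumes: a 400-vignette suite spread over 14 body systems with the
benchmark's weightages, gold differentials of varying length, a lexicon
giving some diseases alternative and umbrella names, and raters whose
behaviour is controlled by a small skill profile — cumulative probabilities
of placing the main diagnosis in the top 1/3/5, a per-disease recall
probability for the rest of the gold list, a distractor-count distribution,
and rates for the four session-failure categories.  Because every parameter
is known, the scoring pipeline can be checked against closed-form
expectations (binomial sampling theory, law of total probability over
failure categories).

Determinism: one master integer seed; each rater and replicate draws from
an independent substream derived by hashing its id into the seed sequence,
so adding a rater never perturbs another rater's draws.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lexicon import DiseaseLexicon, normalize_label
from .metrics import RaterSummary
from .regimes import RaterOutput, regime_all
from .vignettes import BODY_SYSTEMS, Vignette

__all__ = [
    "BENCHMARK_SYSTEM_COUNTS",
    "RaterSkillProfile",
    "SimulationConfig",
    "generate_suite",
    "simulate_rater",
    "RecoveryReport",
    "recovery_report",
]

#: Vignette counts per body system in the 400-vignette benchmark suite;
#: normalized, these are the default body-system weightages.
BENCHMARK_SYSTEM_COUNTS: dict[str, int] = {
    "hematology": 23,
    "cardiovascular": 46,
    "neurology": 22,
    "endocrine": 20,
    "ent": 23,
    "gastrointestinal": 44,
    "obstetrics_gynecology": 54,
    "infectious": 23,
    "respiratory": 37,
    "orthopedics_rheumatology": 32,
    "ophthalmology": 18,
    "dermatology": 12,
    "urology": 14,
    "nephrology": 32,
}

#: fraction of benchmark vignettes covering common (vs less-common) diseases
_COMMON_FRACTION = 222 / 400


def _validate_pmf(pmf: Mapping[int, float], name: str, min_support: int = 0) -> None:
    if not pmf:
        raise ValueError(f"{name} must be non-empty")
    for k, p in pmf.items():
        if k < min_support or p < 0:
            raise ValueError(f"{name} has invalid entry {k}: {p}")
    if abs(sum(pmf.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must sum to 1")


@dataclass(frozen=True)
class RaterSkillProfile:
    """Controls a simulated rater.

    ``p_top1 <= p_top3 <= p_top5`` are *cumulative* probabilities that the
    main diagnosis lands within ranks 1, 3 and 5 of an ok session (defaults
    emulate a strong rater); with probability ``1 - p_top5`` it is omitted.
    Within a band (ranks 2–3 or 4–5) the rank is uniform.  Each non-main
    gold disease is included independently with probability
    ``gold_recall_q``; ``n_distractors`` is a pmf over counts of non-gold
    diseases appended; ``failure_rates`` are mutually exclusive
    probabilities for the four session-failure categories.
    """

    p_top1: float = 0.6
    p_top3: float = 0.8
    p_top5: float = 0.9
    gold_recall_q: float = 0.5
    n_distractors: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.25, 3: 0.5, 4: 0.25}
    )
    failure_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_top1 <= self.p_top3 <= self.p_top5 <= 1:
            raise ValueError("need 0 <= p_top1 <= p_top3 <= p_top5 <= 1")
        if not 0 <= self.gold_recall_q <= 1:
            raise ValueError("gold_recall_q must be in [0, 1]")
        _validate_pmf(self.n_distractors, "n_distractors")
        allowed = {"search_limit", "age_limit", "crash", "no_ddx"}
        unknown = set(self.failure_rates) - allowed
        if unknown:
            raise ValueError(f"unknown failure categories: {sorted(unknown)}")
        if any(p < 0 for p in self.failure_rates.values()):
            raise ValueError("failure rates must be non-negative")
        if sum(self.failure_rates.values()) >= 1:
            raise ValueError("failure rates must sum to < 1")

    @property
    def total_failure_rate(self) -> float:
        return sum(self.failure_rates.values())


@dataclass(frozen=True)
class SimulationConfig:
    """Shape of the synthetic study: suite size, gold-differential length
    distribution, body-system weightages (default: the benchmark suite's),
    lexicon coverage, and the label-noise rate of simulated raters."""

    n_vignettes: int = 400
    seed: int = 0
    diff_len_pmf: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.25, 3: 0.30, 4: 0.20, 5: 0.10}
    )
    system_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            s: c / 400 for s, c in BENCHMARK_SYSTEM_COUNTS.items()
        }
    )
    common_fraction: float = _COMMON_FRACTION
    synonym_fraction: float = 0.3
    umbrella_fraction: float = 0.15
    label_noise: float = 0.0
    deterministic_proportions: bool = False

    def __post_init__(self) -> None:
        if self.n_vignettes < 1:
            raise ValueError("n_vignettes must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        _validate_pmf(self.diff_len_pmf, "diff_len_pmf", min_support=1)
        unknown = set(self.system_weights) - set(BODY_SYSTEMS)
        if unknown:
            raise ValueError(f"unknown body systems: {sorted(unknown)}")
        if any(w < 0 for w in self.system_weights.values()):
            raise ValueError("system weights must be non-negative")
        if abs(sum(self.system_weights.values()) - 1.0) > 1e-9:
            raise ValueError("system weights must sum to 1")
        for name in ("common_fraction", "synonym_fraction", "umbrella_fraction", "label_noise"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _substream(master_seed: int, label: str) -> np.random.Generator:
    """Independent generator for one rater/replicate, stable under additions."""
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([master_seed, *words]))


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    raw = [w * total for w in weights]
    counts = [int(math.floor(x)) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _sample_pmf(rng: np.random.Generator, pmf: Mapping[int, float]) -> int:
    keys = sorted(pmf)
    probs = np.array([pmf[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


_FINDINGS = [f"finding {i:02d}" for i in range(1, 41)]


def generate_suite(config: SimulationConfig) -> tuple[list[Vignette], DiseaseLexicon]:
    """Generate a gold-status vignette suite plus a matching disease lexicon.

    Each body system carries its own synthetic disease pool; a configurable
    fraction of diseases receives a synonym ("… (alt name)") and an umbrella
    entry ("… spectrum") in the lexicon.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    systems = [s for s in BODY_SYSTEMS if config.system_weights.get(s, 0) > 0]
    weights = [config.system_weights[s] for s in systems]
    if config.deterministic_proportions:
        counts = _largest_remainder(weights, config.n_vignettes)
    else:
        counts = list(rng.multinomial(config.n_vignettes, np.array(weights) / sum(weights)))

    max_len = max(config.diff_len_pmf)
    pools: dict[str, list[str]] = {}
    for s, c in zip(systems, counts):
        # enough diseases per system to fill differentials without exhausting the pool
        pool_size = max(max_len + 2, int(math.ceil(2 * c / 3)) + max_len)
        pools[s] = [f"{s} disease {i:03d}" for i in range(1, pool_size + 1)]

    suite: list[Vignette] = []
    vid = 0
    for s, c in zip(systems, counts):
        pool = pools[s]
        for _ in range(c):
            vid += 1
            main = pool[int(rng.integers(len(pool)))]
            others = [d for d in pool if d != main]
            d_len = min(_sample_pmf(rng, config.diff_len_pmf), len(others))
            differential = [str(x) for x in rng.choice(others, size=d_len, replace=False)]
            n_cc = int(rng.integers(1, 4))
            cc = [str(x) for x in rng.choice(_FINDINGS, size=n_cc, replace=False)]
            present = [str(x) for x in rng.choice(_FINDINGS, size=4, replace=False)]
            absent = [str(x) for x in rng.choice(_FINDINGS, size=2, replace=False)]
            suite.append(
                Vignette(
                    id=f"v{vid:04d}",
                    age=float(rng.integers(1, 91)),
                    sex="female" if rng.random() < 0.5 else "male",
                    chief_complaints=cc,
                    present_findings=present,
                    absent_findings=absent,
                    basic_findings=[],
                    past_history=[],
                    family_history=[],
                    body_system=s,
                    commonness="common" if rng.random() < config.common_fraction else "less_common",
                    gold_main=main,
                    gold_differential=differential,
                    status="gold",
                )
            )

    entries: dict[str, dict[str, list[str]]] = {}
    for s in systems:
        for disease in pools[s]:
            rel: dict[str, list[str]] = {"synonyms": [], "umbrella_of": [], "related": []}
            if rng.random() < config.synonym_fraction:
                rel["synonyms"].append(f"{disease} (alt name)")
            if rng.random() < config.umbrella_fraction:
                entries[f"{disease} spectrum"] = {
                    "synonyms": [],
                    "umbrella_of": [disease],
                    "related": [],
                }
            if rel["synonyms"]:
                entries[disease] = rel
    lexicon = DiseaseLexicon.from_dict(entries)
    return suite, lexicon


def _variant_index(lexicon: DiseaseLexicon) -> dict[str, list[str]]:
    """canonical disease -> emittable alternative labels (synonyms, umbrella terms)."""
    variants: dict[str, list[str]] = {}
    for canonical, syns in lexicon.synonyms.items():
        if syns:
            variants.setdefault(canonical, []).extend(sorted(syns))
    for umbrella, subsumed in lexicon.umbrella_of.items():
        for disease in subsumed:
            variants.setdefault(disease, []).append(umbrella)
    return variants


_FAILURE_ORDER = ("search_limit", "age_limit", "crash", "no_ddx")


def simulate_rater(
    suite: Sequence[Vignette],
    lexicon: Optional[DiseaseLexicon],
    profile: RaterSkillProfile,
    seed: int,
    rater_id: str = "sim_rater",
    label_noise: float = 0.0,
) -> list[RaterOutput]:
    """Simulate one rater's sessions over a suite.

    Per vignette: draw a failure category (mutually exclusive) or an ok
    session; in ok sessions place the main diagnosis at a rank consistent
    with the cumulative top-1/3/5 probabilities (uniform within the 2–3 and
    4–5 bands) or omit it, include each remaining gold disease with
    probability ``gold_recall_q``, append distractors drawn from the suite's
    other diseases, and — at rate ``label_noise`` — emit a synonym or
    umbrella label in place of the canonical one.
    """
    rng = _substream(seed, f"rater:{rater_id}")
    variants = _variant_index(lexicon) if lexicon is not None else {}
    all_diseases = sorted(
        {v.gold_main for v in suite} | {d for v in suite for d in v.gold_differential}
    )
    thresholds = []
    acc = 0.0
    for cat in _FAILURE_ORDER:
        acc += profile.failure_rates.get(cat, 0.0)
        thresholds.append(acc)

    outputs: list[RaterOutput] = []
    filler_counter = 0
    for v in suite:
        u = float(rng.random())
        status = "ok"
        for cat, t in zip(_FAILURE_ORDER, thresholds):
            if u < t:
                status = cat
                break
        if status in ("search_limit", "age_limit", "crash"):
            outputs.append(
                RaterOutput(
                    rater_id=rater_id,
                    vignette_id=v.id,
                    status=status,
                    ddx=[],
                    questions_asked=None,
                )
            )
            continue
        questions = int(rng.poisson(25))
        if status == "no_ddx":
            outputs.append(
                RaterOutput(
                    rater_id=rater_id,
                    vignette_id=v.id,
                    status="no_ddx",
                    ddx=[],
                    questions_asked=questions,
                )
            )
            continue

        # rank of the main diagnosis, or None when omitted
        w = float(rng.random())
        if w < profile.p_top1:
            rank: Optional[int] = 1
        elif w < profile.p_top3:
            rank = int(rng.integers(2, 4))
        elif w < profile.p_top5:
            rank = int(rng.integers(4, 6))
        else:
            rank = None

        included = [d for d in v.gold_differential if rng.random() < profile.gold_recall_q]
        gold_keys = {normalize_label(d) for d in (v.gold_main, *v.gold_differential)}
        n_extra = _sample_pmf(rng, profile.n_distractors)
        candidates = [d for d in all_diseases if normalize_label(d) not in gold_keys]
        n_extra = min(n_extra, len(candidates))
        distractors = (
            [candidates[i] for i in rng.choice(len(candidates), size=n_extra, replace=False)]
            if n_extra
            else []
        )
        # included gold diseases keep their gold relative order (a rater who
        # recalls the whole list in order earns NDCG exactly 1); distractors
        # are interleaved at random positions
        total = len(included) + len(distractors)
        body: list[str] = [""] * total
        if distractors:
            slots = set(rng.choice(total, size=len(distractors), replace=False).tolist())
            shuffled = [distractors[i] for i in rng.permutation(len(distractors))]
        else:
            slots, shuffled = set(), []
        it_inc = iter(included)
        it_dis = iter(shuffled)
        for i in range(total):
            body[i] = next(it_dis) if i in slots else next(it_inc)
        if rank is not None:
            while len(body) < rank - 1:
                filler_counter += 1
                body.append(f"nonspecific condition {filler_counter:04d}")
            body.insert(rank - 1, v.gold_main)
        if not body:
            filler_counter += 1
            body.append(f"nonspecific condition {filler_counter:04d}")
        if label_noise > 0 and variants:
            emitted = []
            for d in body:
                alts = variants.get(normalize_label(d))
                if alts and rng.random() < label_noise:
                    emitted.append(alts[int(rng.integers(len(alts)))])
                else:
                    emitted.append(d)
            body = emitted
        outputs.append(
            RaterOutput(
                rater_id=rater_id,
                vignette_id=v.id,
                status="ok",
                ddx=body,
                questions_asked=questions,
            )
        )
    return outputs


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery check: simulated raters re-scored by the pipeline."""

    table: pd.DataFrame  # parameter, truth, estimate, se, flagged
    replicates: list[RaterSummary]

    @property
    def any_flagged(self) -> bool:
        return bool(self.table["flagged"].any())


def recovery_report(
    profile: RaterSkillProfile,
    config: SimulationConfig,
    n_replicates: int,
    seed: int,
) -> RecoveryReport:
    """Simulate ``n_replicates`` independent raters on one suite, score each
    with the all-vignettes regime, and compare the pooled estimates with
    their closed-form expectations.

    Under the all-vignettes regime the expected M@k fraction is
    ``p_topk * (1 - f)`` where ``f`` is the total failure rate, and the
    expected recall of a vignette with gold length ``n`` is
    ``(p_top5 + (n - 1) * q) / n * (1 - f)``.  A parameter is flagged when
    its pooled estimate falls more than 3 standard errors (SE of the
    replicate mean) from the expectation.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    suite, lexicon = generate_suite(config)
    summaries: list[RaterSummary] = []
    for r in range(n_replicates):
        outputs = simulate_rater(
            suite, lexicon, profile, seed, rater_id=f"replicate:{r}",
            label_noise=config.label_noise,
        )
        summaries.append(regime_all(outputs, suite, lexicon))

    f = profile.total_failure_rate
    truths = {
        "p_top1": profile.p_top1 * (1 - f),
        "p_top3": profile.p_top3 * (1 - f),
        "p_top5": profile.p_top5 * (1 - f),
        "gold_recall": (1 - f)
        * float(
            np.mean(
                [
                    (profile.p_top5 + len(v.gold_differential) * profile.gold_recall_q)
                    / (1 + len(v.gold_differential))
                    for v in suite
                ]
            )
        ),
    }
    observed = {
        "p_top1": np.array([s.m1_pct for s in summaries]) / 100,
        "p_top3": np.array([s.m3_pct for s in summaries]) / 100,
        "p_top5": np.array([s.m5_pct for s in summaries]) / 100,
        "gold_recall": np.array([s.avg_recall_pct for s in summaries]) / 100,
    }
    rows = []
    for name, truth in truths.items():
        xs = observed[name]
        est = float(xs.mean())
        se = float(xs.std(ddof=1) / math.sqrt(len(xs)))
        tol = 3 * se if se > 0 else 1e-12
        rows.append(
            {
                "parameter": name,
                "truth": truth,
                "estimate": est,
                "se": se,
                "flagged": abs(est - truth) > tol,
            }
        )
    return RecoveryReport(table=pd.DataFrame(rows), replicates=summaries)
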
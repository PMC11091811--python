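"""Session-failure taxonomy and the three evaluation regimes.

A diagnostic session can fail in four ways: the chief complaints are not
searchable in the tool (``search_limit``), the patient's age is refused
(``age_limit``), the tool crashes (``crash``), or the session concludes
without a differential (``no_ddx``).  Raters are compared under three
scoring populations:

* **all** — every gold vignette counts; any failure scores zero, so a rater
  is penalized for sessions it could not complete.
* **succeeded** — sessions blocked before producing output (search/age
  limits, crashes) are excluded from the denominator; sessions that finished
  without a differential stay in and score zero.
* **intersection** — only vignettes on which *every* compared rater produced
  a differential, so all raters are scored on an identical case set.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .lexicon import DiseaseLexicon
from .metrics import RaterSummary, VignetteMetrics, aggregate_rater, score_vignette
from .vignettes import Vignette, gold_ranked_list

__all__ = [
    "STATUSES",
    "HARD_FAILURES",
    "RaterOutput",
    "FailureTable",
    "EmptyIntersectionError",
    "failure_table",
    "regime_all",
    "regime_succeeded",
    "regime_intersection",
    "read_outputs",
    "write_outputs",
]

STATUSES = ("ok", "no_ddx", "crash", "search_limit", "age_limit")
#: failures that prevented the session from producing any output; excluded
#: from the denominator under the succeeded-only regime
HARD_FAILURES = ("search_limit", "age_limit", "crash")


class RaterOutput(BaseModel):
    """One (rater, vignette) session: a status and, when ok, an ordered differential."""

    rater_id: str = Field(min_length=1)
    vignette_id: str = Field(min_length=1)
    status: Literal[STATUSES]  # type: ignore[valid-type]
    ddx: list[str] = Field(default_factory=list)
    questions_asked: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _ddx_consistent(self) -> "RaterOutput":
        if self.status == "ok" and not self.ddx:
            raise ValueError("status 'ok' requires a non-empty differential")
        if self.status != "ok" and self.ddx:
            raise ValueError(f"status {self.status!r} must have an empty differential")
        return self


@dataclass(frozen=True)
class FailureTable:
    """Failure-category counts for one rater plus question-count statistics.

    The five counts always sum to the suite size.  ``questions_mean`` and
    ``questions_sd`` (sample SD) are computed over non-crashed sessions where
    the count was recorded; they are descriptive only.
    """

    rater_id: str
    search_limit: int
    age_limit: int
    crash: int
    no_ddx: int
    ok: int
    questions_mean: Optional[float]
    questions_sd: Optional[float]

    @property
    def suite_size(self) -> int:
        return self.search_limit + self.age_limit + self.crash + self.no_ddx + self.ok


def _check_coverage(outputs: Sequence[RaterOutput], vignette_ids: Iterable[str]) -> dict[str, RaterOutput]:
    by_id: dict[str, RaterOutput] = {}
    dupes = []
    for out in outputs:
        if out.vignette_id in by_id:
            dupes.append(out.vignette_id)
        by_id[out.vignette_id] = out
    if dupes:
        raise ValueError(f"duplicate outputs for vignettes: {sorted(set(dupes))}")
    missing = [vid for vid in vignette_ids if vid not in by_id]
    if missing:
        raise ValueError(f"missing outputs for vignettes: {missing}")
    return by_id


def failure_table(outputs: Sequence[RaterOutput], suite_size: int) -> FailureTable:
    """Tally session outcomes for one rater; requires exactly one output per vignette."""
    if len(outputs) != suite_size:
        raise ValueError(f"expected {suite_size} outputs, got {len(outputs)}")
    seen = set()
    for out in outputs:
        if out.vignette_id in seen:
            raise ValueError(f"duplicate output for vignette {out.vignette_id!r}")
        seen.add(out.vignette_id)
    counts = {s: 0 for s in STATUSES}
    for out in outputs:
        counts[out.status] += 1
    qs = [
        out.questions_asked
        for out in outputs
        if out.status != "crash" and out.questions_asked is not None
    ]
    mean = sum(qs) / len(qs) if qs else None
    if len(qs) >= 2:
        sd = math.sqrt(sum((q - mean) ** 2 for q in qs) / (len(qs) - 1))
    else:
        sd = None
    rater = outputs[0].rater_id if outputs else ""
    return FailureTable(
        rater_id=rater,
        search_limit=counts["search_limit"],
        age_limit=counts["age_limit"],
        crash=counts["crash"],
        no_ddx=counts["no_ddx"],
        ok=suite_size - sum(counts[s] for s in STATUSES if s != "ok"),
        questions_mean=mean,
        questions_sd=sd,
    )


def _score(
    out: RaterOutput,
    vignette: Vignette,
    lexicon: Optional[DiseaseLexicon],
    include_main: bool,
) -> VignetteMetrics:
    if out.status != "ok":
        return VignetteMetrics.zero(vignette.id)
    return score_vignette(
        vignette.id, out.ddx, gold_ranked_list(vignette, include_main), lexicon
    )


def regime_all(
    outputs: Sequence[RaterOutput],
    suite: Sequence[Vignette],
    lexicon: Optional[DiseaseLexicon] = None,
    include_main: bool = True,
) -> RaterSummary:
    """Score every vignette; failed sessions contribute all-zero metrics."""
    by_id = _check_coverage(outputs, [v.id for v in suite])
    scores = [_score(by_id[v.id], v, lexicon, include_main) for v in suite]
    rater = outputs[0].rater_id if outputs else ""
    return aggregate_rater(scores, rater_id=rater)


def regime_succeeded(
    outputs: Sequence[RaterOutput],
    suite: Sequence[Vignette],
    lexicon: Optional[DiseaseLexicon] = None,
    include_main: bool = True,
) -> RaterSummary:
    """Score only sessions the rater could run: search/age-limited and crashed
    sessions leave the denominator; no-differential sessions stay and score zero."""
    by_id = _check_coverage(outputs, [v.id for v in suite])
    kept = [v for v in suite if by_id[v.id].status not in HARD_FAILURES]
    if not kept:
        raise ValueError("no succeeded sessions to score")
    scores = [_score(by_id[v.id], v, lexicon, include_main) for v in kept]
    rater = outputs[0].rater_id if outputs else ""
    return aggregate_rater(scores, rater_id=rater)


class EmptyIntersectionError(ValueError):
    """No vignette was completed with a differential by every included rater."""


def regime_intersection(
    outputs_by_rater: Mapping[str, Sequence[RaterOutput]],
    suite: Sequence[Vignette],
    lexicon: Optional[DiseaseLexicon] = None,
    include: Optional[Sequence[str]] = None,
    include_main: bool = True,
) -> dict[str, RaterSummary]:
    """Score the included raters on the vignettes all of them completed with a
    differential.  High-failure raters can be left out of ``include`` so they
    do not collapse the shared evaluation set (they are then not scored)."""
    raters = list(include) if include is not None else list(outputs_by_rater)
    if not raters:
        raise ValueError("include must name at least one rater")
    missing = [r for r in raters if r not in outputs_by_rater]
    if missing:
        raise ValueError(f"no outputs for raters: {missing}")
    maps = {r: _check_coverage(outputs_by_rater[r], [v.id for v in suite]) for r in raters}
    shared = [v for v in suite if all(maps[r][v.id].status == "ok" for r in raters)]
    if not shared:
        raise EmptyIntersectionError(
            f"no vignette was completed with a differential by all of: {raters}"
        )
    return {
        r: aggregate_rater(
            [_score(maps[r][v.id], v, lexicon, include_main) for v in shared],
            rater_id=r,
        )
        for r in raters
    }


# ---------------------------------------------------------------------------
# rater-output I/O: JSON lines or CSV with "|"-joined differentials


def read_outputs(path: str | Path) -> list[RaterOutput]:
    path = Path(path)
    records: list[dict] = []
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with open(path, encoding="utf-8") as fh:
            records = [json.loads(line) for line in fh if line.strip()]
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                rec = dict(row)
                rec["ddx"] = [p for p in (row.get("ddx") or "").split("|") if p]
                q = row.get("questions_asked")
                rec["questions_asked"] = int(q) if q not in (None, "", "NA") else None
                records.append(rec)
    return [RaterOutput.model_validate(rec) for rec in records]


def write_outputs(outputs: Iterable[RaterOutput], path: str | Path) -> None:
    path = Path(path)
    outputs = list(outputs)
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        with open(path, "w", encoding="utf-8") as fh:
            for out in outputs:
                fh.write(json.dumps(out.model_dump(), ensure_ascii=False) + "\n")
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["rater_id", "vignette_id", "status", "ddx", "questions_asked"]
        )
        writer.writeheader()
        for out in outputs:
            writer.writerow(
                {
                    "rater_id": out.rater_id,
                    "vignette_id": out.vignette_id,
                    "status": out.status,
                    "ddx": "|".join(out.ddx),
                    "questions_asked": "" if out.questions_asked is None else out.questions_asked,
                }
            )
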
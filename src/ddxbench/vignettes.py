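"""Clinical vignette schema, suite I/O, supermajority standardization and
suite-composition reporting.

A vignette is a standardized written clinical case acting as a proxy for a
real patient.  Each carries eight components: patient age and sex, up to
three chief complaints, present findings, absent findings, basic
(physical-exam level) findings, past medical history, family history, and
the adjudicated main + differential diagnoses.  Vignettes become *gold
standard* only after a supermajority of an independent review panel accepts
them (default: at least 5 of 7 reviewers).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .lexicon import normalize_label

__all__ = [
    "BODY_SYSTEMS",
    "Vignette",
    "Vote",
    "ReviewRound",
    "SuiteComposition",
    "SuiteValidationError",
    "read_suite",
    "write_suite",
    "standardize",
    "suite_composition",
    "gold_ranked_list",
]

SCHEMA_VERSION = 1

#: The 14 body systems of the benchmark suite.
BODY_SYSTEMS = (
    "hematology",
    "cardiovascular",
    "neurology",
    "endocrine",
    "ent",
    "gastrointestinal",
    "obstetrics_gynecology",
    "infectious",
    "respiratory",
    "orthopedics_rheumatology",
    "ophthalmology",
    "dermatology",
    "urology",
    "nephrology",
)

_LIST_FIELDS = (
    "chief_complaints",
    "present_findings",
    "absent_findings",
    "basic_findings",
    "past_history",
    "family_history",
    "gold_differential",
)


class SuiteValidationError(ValueError):
    """Aggregated schema violations for a vignette suite; ``errors`` lists all of them."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid vignette suite:\n" + "\n".join(self.errors))


class Vignette(BaseModel):
    """One standardized clinical case with its gold diagnoses."""

    id: str = Field(min_length=1)
    age: float = Field(ge=0)
    sex: Literal["female", "male"]
    chief_complaints: list[str] = Field(min_length=1, max_length=3)
    present_findings: list[str] = Field(default_factory=list)
    absent_findings: list[str] = Field(default_factory=list)
    basic_findings: list[str] = Field(default_factory=list)
    past_history: list[str] = Field(default_factory=list)
    family_history: list[str] = Field(default_factory=list)
    body_system: Literal[BODY_SYSTEMS]  # type: ignore[valid-type]
    commonness: Literal["common", "less_common"]
    gold_main: str = Field(min_length=1)
    gold_differential: list[str] = Field(default_factory=list)
    status: Literal["draft", "under_review", "gold", "revision"] = "gold"

    @model_validator(mode="after")
    def _gold_list_consistent(self) -> "Vignette":
        main = normalize_label(self.gold_main)
        seen: set[str] = set()
        for d in self.gold_differential:
            key = normalize_label(d)
            if key == main:
                raise ValueError(
                    f"gold_main {self.gold_main!r} repeated in gold_differential"
                )
            if key in seen:
                raise ValueError(f"duplicate disease {d!r} in gold_differential")
            seen.add(key)
        return self


def gold_ranked_list(vignette: Vignette, include_main: bool = True) -> list[str]:
    """The gold ranked diagnosis list: main diagnosis first, then the stored
    differential order.  ``include_main=False`` restricts to the differential
    (for recall variants that score the differential alone); the list must
    remain non-empty."""
    if include_main:
        return [vignette.gold_main, *vignette.gold_differential]
    if not vignette.gold_differential:
        raise ValueError(
            f"vignette {vignette.id!r} has no differential; cannot exclude the main diagnosis"
        )
    return list(vignette.gold_differential)


# ---------------------------------------------------------------------------
# suite I/O


def read_suite(path: str | Path) -> list[Vignette]:
    """Read a vignette suite from canonical JSON or the CSV dialect.

    All records are validated; on failure a :class:`SuiteValidationError`
    carrying the full violation list (with vignette ids) is raised.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        records = _read_csv_records(path)
    else:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if not isinstance(payload, dict) or "vignettes" not in payload:
            raise SuiteValidationError(["top level must be {schema_version, vignettes:[...]}"])
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise SuiteValidationError(
                [f"unsupported schema_version {payload.get('schema_version')!r}"]
            )
        records = payload["vignettes"]

    errors: list[str] = []
    vignettes: list[Vignette] = []
    seen_ids: set[str] = set()
    for i, rec in enumerate(records):
        vid = rec.get("id", f"<record {i}>") if isinstance(rec, dict) else f"<record {i}>"
        try:
            v = Vignette.model_validate(rec)
        except (ValidationError, ValueError) as exc:
            for line in _describe(exc):
                errors.append(f"vignette {vid}: {line}")
            continue
        if v.id in seen_ids:
            errors.append(f"vignette {v.id}: duplicate vignette id")
            continue
        seen_ids.add(v.id)
        vignettes.append(v)
    if errors:
        raise SuiteValidationError(errors)
    return vignettes


def _describe(exc: Exception) -> list[str]:
    if isinstance(exc, ValidationError):
        out = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<record>"
            out.append(f"{loc}: {err['msg']}")
        return out
    return [str(exc)]


def _read_csv_records(path: Path) -> list[dict]:
    records: list[dict] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rec: dict = {}
            for key, value in row.items():
                if key is None:
                    continue
                value = "" if value is None else value
                if key in _LIST_FIELDS:
                    rec[key] = [p for p in value.split("|") if p] if value else []
                elif key == "age":
                    try:
                        rec[key] = float(value)
                    except ValueError:
                        rec[key] = value
                else:
                    rec[key] = value
            records.append(rec)
    return records


def write_suite(suite: Iterable[Vignette], path: str | Path) -> None:
    """Write a suite; format chosen by extension (.json canonical, .csv dialect).

    The JSON form is canonical: fixed field order, 2-space indent, trailing
    newline — so read/write round-trips are byte-stable.
    """
    path = Path(path)
    suite = list(suite)
    if path.suffix.lower() == ".csv":
        fields = list(Vignette.model_fields)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for v in suite:
                row = v.model_dump()
                for f in _LIST_FIELDS:
                    row[f] = "|".join(row[f])
                writer.writerow(row)
        return
    payload = {
        "schema_version": SCHEMA_VERSION,
        "vignettes": [v.model_dump() for v in suite],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, ensure_ascii=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# supermajority standardization


class Vote(BaseModel):
    reviewer_id: str = Field(min_length=1)
    verdict: Literal["accept", "reject"]
    comment: str = ""


class ReviewRound(BaseModel):
    """One full-panel peer-review round for a vignette."""

    vignette_id: str
    round: int = Field(ge=1)
    votes: list[Vote]


def standardize(
    rounds: Sequence[ReviewRound],
    accept_threshold: int = 5,
    panel_size: int = 7,
) -> Literal["gold", "revision"]:
    """Supermajority adjudication of the latest review round.

    A vignette becomes gold standard iff the number of accept votes in its
    most recent round reaches ``accept_threshold`` (default 5 of a 7-member
    panel).  Every round must carry exactly ``panel_size`` votes from
    distinct reviewers; a revised vignette requires a fresh full-panel round.
    """
    if not rounds:
        raise ValueError("at least one review round is required")
    if not 0 < accept_threshold <= panel_size:
        raise ValueError("accept_threshold must satisfy 0 < threshold <= panel_size")
    for rnd in rounds:
        if len(rnd.votes) != panel_size:
            raise ValueError(
                f"round {rnd.round} of vignette {rnd.vignette_id!r} has "
                f"{len(rnd.votes)} votes; expected {panel_size}"
            )
        reviewers = [v.reviewer_id for v in rnd.votes]
        if len(set(reviewers)) != len(reviewers):
            raise ValueError(
                f"round {rnd.round} of vignette {rnd.vignette_id!r} has duplicate reviewers"
            )
    latest = max(rounds, key=lambda r: r.round)
    accepts = sum(1 for v in latest.votes if v.verdict == "accept")
    return "gold" if accepts >= accept_threshold else "revision"


# ---------------------------------------------------------------------------
# suite composition (per body system)


@dataclass(frozen=True)
class SystemComposition:
    body_system: str
    n_vignettes: int
    weightage: float  # fraction of the suite
    common_fraction: Optional[float]  # of this system's vignettes; None if empty
    less_common_fraction: Optional[float]
    diseases_covered: int  # distinct main diagnoses in this system


@dataclass(frozen=True)
class SuiteComposition:
    """Per-body-system breakdown of a gold suite: counts, weightage fractions,
    common/less-common splits, and distinct diseases covered."""

    systems: tuple[SystemComposition, ...]
    total_vignettes: int
    total_diseases: int  # distinct main diagnoses across the whole suite

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "body_system": s.body_system,
                    "n_vignettes": s.n_vignettes,
                    "weightage_pct": 100 * s.weightage,
                    "common_pct": None if s.common_fraction is None else 100 * s.common_fraction,
                    "less_common_pct": (
                        None if s.less_common_fraction is None else 100 * s.less_common_fraction
                    ),
                    "diseases_covered": s.diseases_covered,
                }
                for s in self.systems
            ]
        )


def suite_composition(suite: Sequence[Vignette]) -> SuiteComposition:
    """Compute the per-system composition of a gold suite.

    All 14 body systems are reported; systems without vignettes get weightage
    0 and undefined common/less-common fractions.
    """
    if not suite:
        raise ValueError("suite is empty")
    non_gold = [v.id for v in suite if v.status != "gold"]
    if non_gold:
        raise ValueError(f"composition requires gold vignettes; non-gold: {non_gold}")
    total = len(suite)
    all_mains: set[str] = set()
    rows = []
    for system in BODY_SYSTEMS:
        members = [v for v in suite if v.body_system == system]
        n = len(members)
        mains = {normalize_label(v.gold_main) for v in members}
        all_mains |= mains
        common = sum(1 for v in members if v.commonness == "common")
        rows.append(
            SystemComposition(
                body_system=system,
                n_vignettes=n,
                weightage=n / total,
                common_fraction=common / n if n else None,
                less_common_fraction=(n - common) / n if n else None,
                diseases_covered=len(mains),
            )
        )
    return SuiteComposition(
        systems=tuple(rows), total_vignettes=total, total_diseases=len(all_mains)
    )
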
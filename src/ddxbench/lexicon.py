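"""Disease-label canonicalization and reasonable-match adjudication.

Different raters (symptom checkers, physicians) name the same disease
differently.  A predicted disease counts as a *reasonable match* to a gold
disease when it is the same disease (after normalization / synonym
resolution), an umbrella term that subsumes the gold disease, or a disease
directly related to it.  Matching is one hop only: umbrella-of-umbrella or
related-of-related chains never match.

Umbrella matching is directional — a broad *prediction* matches a specific
gold disease, but a specific prediction does not match an umbrella gold label
unless the lexicon lists the pair as related.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "DiseaseLexicon",
    "LexiconError",
    "normalize_label",
    "is_reasonable_match",
    "match_rank",
]

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


class LexiconError(ValueError):
    """Raised for structurally invalid lexicons (overlapping synonyms, umbrella cycles)."""


@lru_cache(maxsize=65536)
def _canonical_form(text: str) -> str:
    # NFKC fold, lowercase, strip punctuation, collapse whitespace
    s = unicodedata.normalize("NFKC", text).casefold()
    s = _PUNCT.sub(" ", s)
    return _WS.sub(" ", s).strip()


@dataclass
class DiseaseLexicon:
    """Canonical disease labels with synonym / umbrella / related relations.

    ``entries`` maps a canonical label to its relation sets.  On construction
    the lexicon is normalized: every label is reduced to canonical string
    form, ``related`` is symmetrized, synonym sets are checked for disjointness
    and the umbrella relation for acyclicity.
    """

    synonyms: dict[str, set[str]] = field(default_factory=dict)
    umbrella_of: dict[str, set[str]] = field(default_factory=dict)
    related: dict[str, set[str]] = field(default_factory=dict)
    _synonym_index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rebuild()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, entries: Mapping[str, Mapping[str, Iterable[str]]]) -> "DiseaseLexicon":
        syn: dict[str, set[str]] = {}
        umb: dict[str, set[str]] = {}
        rel: dict[str, set[str]] = {}
        for canonical, relations in entries.items():
            key = _canonical_form(canonical)
            syn.setdefault(key, set()).update(
                _canonical_form(s) for s in relations.get("synonyms", ())
            )
            umb.setdefault(key, set()).update(
                _canonical_form(s) for s in relations.get("umbrella_of", ())
            )
            rel.setdefault(key, set()).update(
                _canonical_form(s) for s in relations.get("related", ())
            )
        return cls(synonyms=syn, umbrella_of=umb, related=rel)

    @classmethod
    def from_json(cls, path: str | Path) -> "DiseaseLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiseaseLexicon":
        """4-column TSV: canonical, relation (synonym|umbrella_of|related), target, note."""
        entries: dict[str, dict[str, list[str]]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise LexiconError(f"line {lineno}: expected >=3 tab-separated columns")
                canonical, relation, target = parts[0], parts[1], parts[2]
                if relation not in ("synonym", "umbrella_of", "related"):
                    raise LexiconError(f"line {lineno}: unknown relation {relation!r}")
                slot = {"synonym": "synonyms", "umbrella_of": "umbrella_of", "related": "related"}[relation]
                entries.setdefault(canonical, {"synonyms": [], "umbrella_of": [], "related": []})[
                    slot
                ].append(target)
        return cls.from_dict(entries)

    def to_dict(self) -> dict[str, dict[str, list[str]]]:
        keys = set(self.synonyms) | set(self.umbrella_of) | set(self.related)
        return {
            k: {
                "synonyms": sorted(self.synonyms.get(k, ())),
                "umbrella_of": sorted(self.umbrella_of.get(k, ())),
                "related": sorted(self.related.get(k, ())),
            }
            for k in sorted(keys)
        }

    # -- normalization & validation ---------------------------------------

    def _rebuild(self) -> None:
        keys = set(self.synonyms) | set(self.umbrella_of) | set(self.related)
        for mapping in (self.synonyms, self.umbrella_of, self.related):
            for k in keys:
                mapping.setdefault(k, set())
        # related is symmetric
        for a, partners in list(self.related.items()):
            for b in partners:
                self.related.setdefault(b, set()).add(a)
                self.synonyms.setdefault(b, set())
                self.umbrella_of.setdefault(b, set())
        # synonym sets disjoint across entries
        index: dict[str, str] = {}
        for canonical, syns in self.synonyms.items():
            for s in syns:
                if s in index and index[s] != canonical:
                    raise LexiconError(
                        f"synonym {s!r} claimed by both {index[s]!r} and {canonical!r}"
                    )
                index[s] = canonical
        self._synonym_index = index
        self._check_umbrella_acyclic()

    def _check_umbrella_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color: dict[str, int] = {}

        def visit(node: str) -> None:
            color[node] = GREY
            for child in self.umbrella_of.get(node, ()):
                state = color.get(child, WHITE)
                if state == GREY:
                    raise LexiconError(f"umbrella_of cycle through {child!r}")
                if state == WHITE:
                    visit(child)
            color[node] = BLACK

        for node in list(self.umbrella_of):
            if color.get(node, WHITE) == WHITE:
                visit(node)

    # -- lookup ------------------------------------------------------------

    def resolve(self, key: str) -> str:
        """Map a canonical-form string through the synonym table."""
        return self._synonym_index.get(key, key)


def normalize_label(text: str, lexicon: Optional[DiseaseLexicon] = None) -> str:
    """Reduce a free-text disease name to its canonical key.

    Lowercases, folds Unicode compatibility forms, strips punctuation and
    collapses whitespace; when a lexicon is given, resolves through its
    synonym table.  Idempotent.
    """
    if text is None or not text.strip():
        raise ValueError("disease label must be a non-empty string")
    key = _canonical_form(text)
    if not key:
        raise ValueError(f"label {text!r} is empty after normalization")
    return lexicon.resolve(key) if lexicon is not None else key


def _keys_match(pred_key: str, gold_key: str, lexicon: Optional[DiseaseLexicon]) -> bool:
    """Reasonable-match test on already-normalized keys (internal fast path)."""
    if pred_key == gold_key:
        return True
    if lexicon is None:
        return False
    if gold_key in lexicon.umbrella_of.get(pred_key, ()):
        return True
    return gold_key in lexicon.related.get(pred_key, ())


def is_reasonable_match(
    pred: str, gold: str, lexicon: Optional[DiseaseLexicon] = None
) -> bool:
    """True iff ``pred`` reasonably matches ``gold``: same canonical disease,
    ``pred`` is an umbrella term subsuming ``gold``, or the two are directly
    related.  One hop only; with no lexicon, exact canonical-string equality.
    """
    return _keys_match(normalize_label(pred, lexicon), normalize_label(gold, lexicon), lexicon)


def match_rank(
    ddx: Iterable[str], gold: str, lexicon: Optional[DiseaseLexicon] = None
) -> Optional[int]:
    """1-based position of the first differential entry matching ``gold``; None if absent."""
    gold_key = normalize_label(gold, lexicon)
    for i, pred in enumerate(ddx, start=1):
        if _keys_match(normalize_label(pred, lexicon), gold_key, lexicon):
            return i
    return None
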
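"""Medical lexicon: canonical disease/drug/symptom terms with synonyms,
token-based matching against query text, and per-user term-count vectors.

Matching is on token boundaries, never substrings, so "hives" does not
match "HIV". Synonyms fold into their canonical term: a query for "heart
attack" counts as a mention of "myocardial infarction". On overlapping
matches the longest token span wins; remaining ties break lexicographically
on the canonical name, which keeps matching deterministic.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from ._text import normalize, tokenize
from .datamodel import QueryLog

KINDS = ("disease", "drug", "symptom")


@dataclass
class Lexicon:
    """Canonical terms partitioned into kinds, plus a synonym map.

    ``terms`` maps canonical (normalized) name -> kind; ``synonym_map`` maps
    each normalized synonym to its canonical name. Canonical names act as
    their own surface forms.
    """

    terms: dict[str, str]
    synonym_map: dict[str, str] = field(default_factory=dict)

    # phrase-token table built lazily: token tuple -> (canonical, kind)
    _table: dict[tuple[str, ...], tuple[str, str]] = field(
        default_factory=dict, repr=False
    )
    _max_len: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        for canon, kind in self.terms.items():
            if kind not in KINDS:
                raise ValueError(f"unknown kind {kind!r} for {canon!r}")
        for syn, canon in self.synonym_map.items():
            if canon not in self.terms:
                raise ValueError(f"synonym {syn!r} maps to unknown term {canon!r}")
        self._rebuild()

    def _rebuild(self) -> None:
        self._table = {}
        for canon, kind in self.terms.items():
            self._table[tuple(tokenize(canon))] = (canon, kind)
        for syn, canon in self.synonym_map.items():
            toks = tuple(tokenize(syn))
            # a canonical surface form always beats a clashing synonym
            if toks not in self._table:
                self._table[toks] = (canon, self.terms[canon])
        self._max_len = max((len(t) for t in self._table), default=0)

    def lookup(self, surface: str) -> tuple[str, str] | None:
        """Exact lookup of a full surface form (canonical or synonym)."""
        return self._table.get(tuple(tokenize(surface)))

    def of_kind(self, kind: str) -> list[str]:
        return sorted(c for c, k in self.terms.items() if k == kind)


@dataclass(frozen=True)
class TermCountVector:
    user_id: str
    counts: dict[str, int]


def match_spans(text: str, lexicon: Lexicon) -> list[tuple[int, int, str, str]]:
    """All non-overlapping term matches as (start, end, canonical, kind).

    Candidate spans are every token run that equals a surface form; overlap
    is resolved longest-span-first, ties lexicographically on canonical.
    Returned in text order.
    """
    tokens = tokenize(text)
    n = len(tokens)
    candidates: list[tuple[int, int, str, str]] = []
    max_len = lexicon._max_len
    for i in range(n):
        for span in range(min(max_len, n - i), 0, -1):
            hit = lexicon._table.get(tuple(tokens[i : i + span]))
            if hit is not None:
                candidates.append((i, i + span, hit[0], hit[1]))
    chosen: list[tuple[int, int, str, str]] = []
    occupied = [False] * n
    for cand in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[2], c[0])):
        if not any(occupied[cand[0] : cand[1]]):
            chosen.append(cand)
            for j in range(cand[0], cand[1]):
                occupied[j] = True
    return sorted(chosen)


def match_terms(text: str, lexicon: Lexicon) -> list[tuple[str, str]]:
    """Canonical terms mentioned in ``text``, each reported at most once,
    in order of first appearance."""
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    for _, _, canon, kind in match_spans(text, lexicon):
        if canon not in seen:
            seen.add(canon)
            out.append((canon, kind))
    return out


def build_term_vectors(log: QueryLog, lexicon: Lexicon) -> list[TermCountVector]:
    """One count vector per user: mentions of each canonical term across the
    user's queries, synonyms counted with the original term."""
    per_user: dict[str, Counter] = {}
    for rec in log.records:
        hits = match_terms(rec.text, lexicon)
        if not hits:
            continue
        counter = per_user.setdefault(rec.user_id, Counter())
        for canon, _ in hits:
            counter[canon] += 1
    return [
        TermCountVector(uid, dict(per_user[uid])) for uid in sorted(per_user)
    ]


def load_lexicon(path: Union[str, Path]) -> Lexicon:
    """Read a lexicon file: TSV with columns canonical, kind, synonyms
    (pipe-separated, may be empty)."""
    terms: dict[str, str] = {}
    synonym_map: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            canon = normalize(row["canonical"])
            terms[canon] = row["kind"].strip()
            for syn in (row.get("synonyms") or "").split("|"):
                syn = normalize(syn)
                if syn:
                    synonym_map[syn] = canon
    return Lexicon(terms, synonym_map)


def save_lexicon(lexicon: Lexicon, path: Union[str, Path]) -> None:
    by_canon: dict[str, list[str]] = {c: [] for c in lexicon.terms}
    for syn, canon in lexicon.synonym_map.items():
        by_canon[canon].append(syn)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["canonical", "kind", "synonyms"])
        for canon in sorted(lexicon.terms):
            w.writerow(
                [canon, lexicon.terms[canon], "|".join(sorted(by_canon[canon]))]
            )
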
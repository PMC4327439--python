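"""Self-identified users (SIUs).

A user self-identifies when a single query combines a trigger phrase ("i
have", "i suffer from", "living with", "i was diagnosed with") with a
disease name from the lexicon. The day of the first such query is taken as
the event day — the working assumption being that onset or diagnosis
happened at or near that first self-identifying query. No negation handling
is attempted; "i don't have cancer" would still match, a known limitation
of the trigger-phrase heuristic.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._text import contains_phrase, normalize
from .datamodel import IncidenceTable, QueryLog, SIURecord
from .lexicon import Lexicon, match_spans

TRIGGER_PHRASES = (
    "i have",
    "i suffer from",
    "living with",
    "i was diagnosed with",
)


class InsufficientDataError(ValueError):
    pass


def _self_identified_condition(text: str, lexicon: Lexicon) -> str | None:
    """The disease a trigger query self-identifies, or None.

    If the query names several diseases the longest token span wins, then
    lexicographic order on the canonical name.
    """
    diseases = [
        (end - start, canon)
        for start, end, canon, kind in match_spans(text, lexicon)
        if kind == "disease"
    ]
    if not diseases:
        return None
    diseases.sort(key=lambda d: (-d[0], d[1]))
    return diseases[0][1]


def detect_sius(
    log: QueryLog,
    lexicon: Lexicon,
    trigger_phrases: Sequence[str] = TRIGGER_PHRASES,
) -> list[SIURecord]:
    """Scan the log for self-identifying queries.

    Returns one record per (user, condition) with the earliest qualifying
    day; the user's primary condition (the one self-identified first) is
    flagged. Output is sorted and independent of record order.
    """
    phrases = [normalize(p) for p in trigger_phrases]
    earliest: dict[tuple[str, str], int] = {}
    for rec in log.records:
        if not any(contains_phrase(rec.text, p) for p in phrases):
            continue
        condition = _self_identified_condition(rec.text, lexicon)
        if condition is None:
            continue
        key = (rec.user_id, condition)
        if key not in earliest or rec.day < earliest[key]:
            earliest[key] = rec.day
    primary: dict[str, tuple[int, str]] = {}
    for (uid, cond), day in earliest.items():
        best = primary.get(uid)
        if best is None or (day, cond) < best:
            primary[uid] = (day, cond)
    return [
        SIURecord(uid, cond, day, primary=(primary[uid] == (day, cond)))
        for (uid, cond), day in sorted(earliest.items())
    ]


def filter_conditions(
    sius: Iterable[SIURecord], min_count: int = 25
) -> tuple[list[str], list[SIURecord]]:
    """Keep conditions self-identified by at least ``min_count`` users."""
    sius = list(sius)
    counts = Counter(r.condition for r in sius)
    retained = sorted(c for c, n in counts.items() if n >= min_count)
    keep = set(retained)
    return retained, [r for r in sius if r.condition in keep]


def incidence_rank_correlation(
    fractions: Mapping[str, float], incidence: IncidenceTable
) -> tuple[float, float]:
    """Spearman rho (average-rank ties) between observed per-condition
    fractions and reference incidence, over the overlapping conditions."""
    ref = incidence.as_dict()
    common = sorted(set(fractions) & set(ref))
    if len(common) < 3:
        raise InsufficientDataError(
            f"need >=3 overlapping conditions, got {len(common)}"
        )
    obs = np.array([fractions[c] for c in common])
    exp = np.array([ref[c] for c in common])
    rho, p = stats.spearmanr(obs, exp)
    return float(rho), float(p)


def siu_incidence_check(
    sius: Iterable[SIURecord], n_users: int, incidence: IncidenceTable
) -> tuple[float, float]:
    """Validity check on the SIU population: rank-correlate SIU fractions
    (primary conditions only) against reference incidence."""
    counts = Counter(r.condition for r in sius if r.primary)
    fractions = {c: n / n_users for c, n in counts.items()}
    return incidence_rank_correlation(fractions, incidence)
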
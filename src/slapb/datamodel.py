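"""Core in-memory data model.

The pipeline moves a query log through three stages — identify users with a
health event, generalize their queries into categories, estimate
per-category relative hazards — and these are the containers the stages
exchange. Everything is day-resolved: a record's ``day`` is a 0-based index
into a shared observation window (default 183 days, roughly six months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

DEFAULT_OBSERVATION_LENGTH = 183


@dataclass(frozen=True)
class QueryRecord:
    """One search event: who, when, what, and which pages were clicked."""

    user_id: str
    day: int
    text: str
    clicked_pages: tuple[str, ...] = ()
    region: Optional[str] = None
    birth_year: Optional[int] = None


@dataclass
class QueryLog:
    """A collection of query records over a common observation window.

    A single shared window replaces per-user observation spans; records
    outside ``[0, observation_length)`` are invalid and dropped at ingest.
    """

    records: list[QueryRecord]
    observation_length: int = DEFAULT_OBSERVATION_LENGTH
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for rec in self.records:
            if not (0 <= rec.day < self.observation_length):
                raise ValueError(
                    f"record day {rec.day} outside [0, {self.observation_length})"
                )
            if not rec.text:
                raise ValueError("query text must be non-empty")

    def user_ids(self) -> list[str]:
        return sorted({r.user_id for r in self.records})

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class IncidenceTable:
    """Reference incidence per condition, as fractions of the population."""

    rows: list[tuple[str, float]]

    def __post_init__(self) -> None:
        seen = set()
        for cond, inc in self.rows:
            if not (0.0 < inc < 1.0):
                raise ValueError(f"incidence for {cond!r} outside (0,1): {inc}")
            if cond in seen:
                raise ValueError(f"duplicate condition {cond!r}")
            seen.add(cond)

    def as_dict(self) -> dict[str, float]:
        return dict(self.rows)

    def conditions(self) -> list[str]:
        return [c for c, _ in self.rows]


@dataclass(frozen=True)
class SIURecord:
    """A self-identified user: condition plus the day of the first
    self-identifying query, taken as the event day."""

    user_id: str
    condition: str
    event_day: int
    primary: bool = True


@dataclass(frozen=True)
class CohortMember:
    """A user in the event cohort for a condition, either because they
    self-identified (``source='siu'``) or because the classifier assigned
    them their most frequently queried disease (``source='classified'``)."""

    user_id: str
    condition: str
    event_day: int
    source: str  # 'siu' | 'classified'


@dataclass(frozen=True)
class PrecursorRow:
    """One reported precursor: a category or literal query whose occurrence
    precedes the event with an elevated relative hazard."""

    condition: str
    precursor_label: str
    label_kind: str  # 'category' | 'query'
    relative_hazard: float
    p_value: float
    fdr_significant: bool
    n_users_exposed: int

    def __post_init__(self) -> None:
        if self.relative_hazard <= 0:
            raise ValueError("relative hazard must be positive")
        if self.label_kind not in ("category", "query"):
            raise ValueError(f"unknown label kind {self.label_kind!r}")


@dataclass
class PrecursorReport:
    """Final report: rows sorted by condition, then descending hazard."""

    rows: list[PrecursorRow] = field(default_factory=list)

    def sort(self) -> "PrecursorReport":
        self.rows.sort(
            key=lambda r: (r.condition, -r.relative_hazard, r.precursor_label)
        )
        return self


def label_key(label: str, kind: str) -> tuple[str, str]:
    """Canonical (kind, label) key used wherever labels index dictionaries.

    A category name and a literal query with the same text are distinct
    labels, so the kind is part of the key.
    """
    return (kind, label)
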
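"""Query generalization through click statistics on encyclopedia pages.

A query is generalized by the page users most often click for it, provided
the (query, page) association is stable — clicked at least
``min_monthly_clicks`` times in every month of the span ("min" mode; an
average-per-month reading is available as "mean"). The winning page's
subject categories become labels for the query. Queries without a stable
page mapping are not generalized: their literal text is the only label.
Every query additionally carries its own text as a label of kind "query",
so screening can surface both broad categories and specific query terms.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from ._text import normalize
from .datamodel import QueryLog, label_key


@dataclass(frozen=True)
class ClickRecord:
    query: str
    page: str
    month: int
    clicks: int

    def __post_init__(self) -> None:
        if self.clicks < 0:
            raise ValueError("click count must be nonnegative")


# query text -> (page id, categories)
CategoryMap = dict[str, tuple[str, tuple[str, ...]]]


def build_category_map(
    clicks: Iterable[ClickRecord],
    page_categories: Mapping[str, Sequence[str]],
    min_monthly_clicks: int = 10,
    mode: str = "min",
) -> CategoryMap:
    """Derive the query -> page -> categories map from click records.

    mode="min": a (query, page) pair survives only if clicked at least the
    threshold in every month of the observed span. mode="mean": the
    per-month average must reach the threshold. Among surviving pages for a
    query the highest total click count wins; ties break to the
    lexicographically smaller page id. Pages without categories drop their
    queries from the map (those queries fall back to raw text downstream).
    """
    if mode not in ("min", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    monthly: dict[tuple[str, str], dict[int, int]] = defaultdict(dict)
    months: set[int] = set()
    for rec in clicks:
        months.add(rec.month)
        q = normalize(rec.query)
        cell = monthly[(q, rec.page)]
        cell[rec.month] = cell.get(rec.month, 0) + rec.clicks
    span = sorted(months)
    best: dict[str, tuple[int, str]] = {}
    for (q, page), per_month in monthly.items():
        total = sum(per_month.values())
        if mode == "min":
            ok = all(per_month.get(m, 0) >= min_monthly_clicks for m in span)
        else:
            ok = span and total / len(span) >= min_monthly_clicks
        if not ok:
            continue
        # higher total wins; tie -> lexicographically smaller page id
        cand = (-total, page)
        if q not in best or cand < best[q]:
            best[q] = cand
    out: CategoryMap = {}
    for q, (_, page) in sorted(best.items()):
        cats = tuple(page_categories.get(page, ()))
        if cats:
            out[q] = (page, cats)
    return out


def annotate(query_text: str, cmap: CategoryMap) -> list[tuple[str, str]]:
    """Labels for one query: its mapped categories (kind 'category'), if
    any, plus always the literal query text (kind 'query')."""
    text = normalize(query_text)
    labels: list[tuple[str, str]] = []
    mapped = cmap.get(text)
    if mapped is not None:
        labels.extend((c, "category") for c in mapped[1])
    labels.append((text, "query"))
    return labels


@dataclass
class AnnotatedLog:
    """A query log with per-record label lists, parallel to ``log.records``."""

    log: QueryLog
    labels: list[list[tuple[str, str]]]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.log.records):
            raise ValueError("labels must parallel log records")

    def label_user_days(self) -> dict[tuple[str, str], dict[str, set[int]]]:
        """Index (kind, label) -> user -> set of days the user issued a
        query carrying that label. This is the exposure-day index both
        candidate selection and case-series building run on."""
        idx: dict[tuple[str, str], dict[str, set[int]]] = {}
        for rec, labs in zip(self.log.records, self.labels):
            for lab, kind in labs:
                idx.setdefault(label_key(lab, kind), {}).setdefault(
                    rec.user_id, set()
                ).add(rec.day)
        return idx


def annotate_log(log: QueryLog, cmap: CategoryMap) -> AnnotatedLog:
    # memoized per distinct text: logs repeat query strings heavily
    cache: dict[str, list[tuple[str, str]]] = {}
    labels = []
    for rec in log.records:
        labs = cache.get(rec.text)
        if labs is None:
            labs = annotate(rec.text, cmap)
            cache[rec.text] = labs
        labels.append(labs)
    return AnnotatedLog(log, labels)


def load_category_map(path: Union[str, Path]) -> CategoryMap:
    out: CategoryMap = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cats = tuple(c for c in row["categories"].split("|") if c)
            if cats:
                out[normalize(row["query"])] = (row["page"], cats)
    return out


def save_category_map(cmap: CategoryMap, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query", "page", "categories"])
        for q in sorted(cmap):
            page, cats = cmap[q]
            w.writerow([q, page, "|".join(cats)])
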
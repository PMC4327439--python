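"""Readers and writers for the delimited text formats the pipeline uses.

Everything is tab-separated with a header row. Query logs carry one record
per line; the precursor report mirrors the usual tabular presentation of
SCCS screens (condition, label, label kind, relative hazard to two
decimals) plus p-value and exposure-count columns.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from pathlib import Path
from typing import Union

import pandas as pd

from ._text import normalize
from .datamodel import (
    DEFAULT_OBSERVATION_LENGTH,
    IncidenceTable,
    PrecursorReport,
    PrecursorRow,
    QueryLog,
    QueryRecord,
)

PathLike = Union[str, Path]

_MANDATORY_LOG_COLUMNS = ("user_id", "day", "text", "clicked_pages")


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


def read_querylog(
    path: PathLike, observation_length: int = DEFAULT_OBSERVATION_LENGTH
) -> QueryLog:
    """Read a TSV query log, normalizing text and enforcing the day window.

    Rows whose day falls outside ``[0, observation_length)`` or whose text
    normalizes to the empty string are dropped; the count of dropped rows is
    reported in a warning and stored on the returned log.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    for col in _MANDATORY_LOG_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"query log is missing mandatory column {col!r}")
    records: list[QueryRecord] = []
    dropped = 0
    has_region = "region" in df.columns
    has_birth = "birth_year" in df.columns
    for row in df.itertuples(index=False):
        day = int(getattr(row, "day"))
        text = normalize(getattr(row, "text"))
        if not (0 <= day < observation_length) or not text:
            dropped += 1
            continue
        pages_raw = getattr(row, "clicked_pages")
        pages = tuple(p for p in pages_raw.split("|") if p) if pages_raw else ()
        region = getattr(row, "region") if has_region else ""
        birth = getattr(row, "birth_year") if has_birth else ""
        records.append(
            QueryRecord(
                user_id=getattr(row, "user_id"),
                day=day,
                text=text,
                clicked_pages=pages,
                region=region or None,
                birth_year=int(birth) if birth else None,
            )
        )
    if dropped:
        warnings.warn(
            f"dropped {dropped} record(s) outside the observation window "
            f"or with empty text",
            stacklevel=2,
        )
    return QueryLog(records, observation_length, n_dropped=dropped)


def write_querylog(log: QueryLog, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["user_id", "day", "text", "clicked_pages", "region", "birth_year"])
        for r in log.records:
            w.writerow(
                [
                    r.user_id,
                    r.day,
                    r.text,
                    "|".join(r.clicked_pages),
                    r.region or "",
                    r.birth_year if r.birth_year is not None else "",
                ]
            )


def read_incidence_table(path: PathLike) -> IncidenceTable:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str, "incidence": float})
    for col in ("condition", "incidence"):
        if col not in df.columns:
            raise FormatError(f"incidence table is missing column {col!r}")
    return IncidenceTable(list(zip(df["condition"], df["incidence"])))


def write_incidence_table(table: IncidenceTable, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["condition", "incidence"])
        for cond, inc in table.rows:
            w.writerow([cond, repr(inc)])


_REPORT_HEADER = [
    "condition",
    "precursor",
    "kind",
    "relative_hazard",
    "p_value",
    "fdr_significant",
    "n_users_exposed",
]


def write_report(report: PrecursorReport, path: PathLike) -> None:
    """Write the precursor report, relative hazards printed to two decimals."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_REPORT_HEADER)
        for r in report.rows:
            w.writerow(
                [
                    r.condition,
                    r.precursor_label,
                    r.label_kind.capitalize(),
                    f"{r.relative_hazard:.2f}",
                    f"{r.p_value:.3g}",
                    int(r.fdr_significant),
                    r.n_users_exposed,
                ]
            )


def read_report(path: PathLike) -> PrecursorReport:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = [
        PrecursorRow(
            condition=r.condition,
            precursor_label=r.precursor,
            label_kind=r.kind.lower(),
            relative_hazard=float(r.relative_hazard),
            p_value=float(r.p_value),
            fdr_significant=bool(int(r.fdr_significant)),
            n_users_exposed=int(r.n_users_exposed),
        )
        for r in df.itertuples(index=False)
    ]
    return PrecursorReport(rows)


def write_sius(sius, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["user_id", "condition", "event_day", "primary"])
        for r in sius:
            w.writerow([r.user_id, r.condition, r.event_day, int(r.primary)])


def read_sius(path: PathLike):
    from .datamodel import SIURecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SIURecord(r.user_id, r.condition, int(r.event_day), bool(int(r.primary)))
        for r in df.itertuples(index=False)
    ]


def write_cohort(members, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["user_id", "condition", "event_day", "source"])
        for m in members:
            w.writerow([m.user_id, m.condition, m.event_day, m.source])


def read_cohort(path: PathLike):
    from .datamodel import CohortMember

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        CohortMember(r.user_id, r.condition, int(r.event_day), r.source)
        for r in df.itertuples(index=False)
    ]


def read_clicks(path: PathLike):
    from .categorize import ClickRecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("query", "page", "month", "clicks"):
        if col not in df.columns:
            raise FormatError(f"click file is missing column {col!r}")
    return [
        ClickRecord(r.query, r.page, int(r.month), int(r.clicks))
        for r in df.itertuples(index=False)
    ]


def write_clicks(clicks, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query", "page", "month", "clicks"])
        for c in clicks:
            w.writerow([c.query, c.page, c.month, c.clicks])


def read_page_categories(path: PathLike) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        r.page: [c for c in r.categories.split("|") if c]
        for r in df.itertuples(index=False)
    }


def write_page_categories(page_categories, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["page", "categories"])
        for page in sorted(page_categories):
            w.writerow([page, "|".join(page_categories[page])])


def load_reference_incidence() -> pd.DataFrame:
    """Bundled reference table: US incidence for 29 diseases alongside the
    percentage of self-identified users observed for each in a large
    search-log cohort. Columns: condition, siu_percent, us_incidence."""
    ref = importlib.resources.files("slapb.data").joinpath(
        "us_incidence_siu_reference.tsv"
    )
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")
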
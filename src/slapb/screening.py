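"""Per-condition precursor screening.

For one condition's event cohort the screen (1) selects candidate labels
queried by at least a minimum fraction of the cohort, (2) rejects labels
whose daily counts in the cohort track their daily counts in a background
user sample — shared spikes point to external drivers such as news events,
not individual risk — (3) fits the SCCS model to each surviving candidate,
and (4) reports the candidates whose likelihood-ratio p-values survive
Benjamini-Hochberg FDR control, sorted by descending relative hazard.

Labels that themselves name the target condition (or contain it, or a
synonym) are excluded up front: post-event queries about one's own
condition would otherwise show up as tautological "precursors".
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .categorize import AnnotatedLog
from .datamodel import CohortMember, PrecursorRow, label_key
from .lexicon import Lexicon, match_terms
from . import sccs

LabelKey = tuple[str, str]  # (kind, label)


@dataclass(frozen=True)
class CandidateLabel:
    label: str
    kind: str
    n_cohort_users: int
    fraction: float

    @property
    def key(self) -> LabelKey:
        return label_key(self.label, self.kind)


def _names_condition(label: str, condition: str, lexicon: Lexicon | None) -> bool:
    if label == condition:
        return True
    if lexicon is None:
        return False
    return any(canon == condition for canon, _ in match_terms(label, lexicon))


def select_candidates(
    cohort: Sequence[CohortMember],
    alog: AnnotatedLog,
    min_fraction: float = 0.01,
    condition: str | None = None,
    lexicon: Lexicon | None = None,
    label_user_days: Mapping[LabelKey, Mapping[str, set[int]]] | None = None,
) -> list[CandidateLabel]:
    """Labels queried by at least ``min_fraction`` of the cohort (boundary
    inclusive). Labels naming the condition are dropped when a condition
    (and optionally a lexicon, for synonym folding) is given."""
    if not cohort:
        raise ValueError("empty cohort")
    if label_user_days is None:
        label_user_days = alog.label_user_days()
    cohort_users = {m.user_id for m in cohort}
    n = len(cohort_users)
    out = []
    for (kind, label), user_days in sorted(label_user_days.items()):
        n_users = sum(1 for u in user_days if u in cohort_users)
        if n_users / n < min_fraction:
            continue
        if condition is not None and _names_condition(label, condition, lexicon):
            continue
        out.append(CandidateLabel(label, kind, n_users, n_users / n))
    return out


def build_temporal_profiles(
    alog: AnnotatedLog,
    candidates: Sequence[CandidateLabel],
    cohort_users: set[str],
    background_users: set[str],
) -> dict[LabelKey, tuple[np.ndarray, np.ndarray]]:
    """Daily count series per candidate label, in the cohort and in the
    background sample (the two populations must be disjoint)."""
    if cohort_users & background_users:
        raise ValueError("background sample must be disjoint from the cohort")
    wanted = {c.key for c in candidates}
    n_days = alog.log.observation_length
    profiles = {
        k: (np.zeros(n_days), np.zeros(n_days)) for k in sorted(wanted)
    }
    for rec, labs in zip(alog.log.records, alog.labels):
        in_cohort = rec.user_id in cohort_users
        in_bg = not in_cohort and rec.user_id in background_users
        if not (in_cohort or in_bg):
            continue
        for lab, kind in labs:
            key = label_key(lab, kind)
            if key in wanted:
                profiles[key][0 if in_cohort else 1][rec.day] += 1
    return profiles


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: sort p ascending, find the largest k with
    p_(k) <= k q / m, reject hypotheses 1..k. Returns a boolean flag array
    aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    flags = np.zeros(p.size, dtype=bool)
    if p.size == 0:
        return flags
    order = np.argsort(p, kind="mergesort")
    below = p[order] <= q * np.arange(1, p.size + 1) / p.size
    if below.any():
        k = int(np.max(np.nonzero(below)[0])) + 1
        flags[order[:k]] = True
    return flags


def temporal_filter(
    profiles: Mapping[LabelKey, tuple[np.ndarray, np.ndarray]],
    q: float = 0.05,
    method: str = "pearson",
) -> tuple[list[LabelKey], list[LabelKey], dict[LabelKey, tuple[float, float]]]:
    """Reject labels whose cohort and background daily-count series are
    significantly correlated (BH at level q across labels).

    Constant series leave the correlation undefined; such labels are kept —
    a flat profile is no evidence of a shared external driver. Returns
    (rejected, kept, per-label (r, p))."""
    keys = sorted(profiles)
    stats_out: dict[LabelKey, tuple[float, float]] = {}
    testable: list[LabelKey] = []
    pvals: list[float] = []
    for key in keys:
        a, b = profiles[key]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            stats_out[key] = (math.nan, math.nan)
            continue
        if method == "pearson":
            r, p = stats.pearsonr(a, b)
        elif method == "spearman":
            r, p = stats.spearmanr(a, b)
        else:
            raise ValueError(f"unknown method {method!r}")
        stats_out[key] = (float(r), float(p))
        testable.append(key)
        pvals.append(float(p))
    flags = bh_fdr(pvals, q)
    rejected = [k for k, f in zip(testable, flags) if f]
    kept = [k for k in keys if k not in set(rejected)]
    return rejected, kept, stats_out


@dataclass
class ScreenDiagnostics:
    """Counts and per-label notes from one run of the screen, kept so every
    report row can be traced back through the filters."""

    n_candidates: int = 0
    temporal_rejected: list[LabelKey] = field(default_factory=list)
    skipped: dict[LabelKey, str] = field(default_factory=dict)
    fits: dict[LabelKey, sccs.SCCSFit] = field(default_factory=dict)


def run_screen(
    condition: str,
    cohort: Sequence[CohortMember],
    alog: AnnotatedLog,
    background_users: Iterable[str],
    lexicon: Lexicon | None = None,
    q: float = 0.05,
    window: int = 15,
    min_fraction: float = 0.01,
    label_user_days: Mapping[LabelKey, Mapping[str, set[int]]] | None = None,
) -> tuple[list[PrecursorRow], ScreenDiagnostics]:
    """Full screen for one condition; returns FDR-significant rows sorted by
    descending relative hazard, plus diagnostics."""
    diag = ScreenDiagnostics()
    if label_user_days is None:
        label_user_days = alog.label_user_days()
    candidates = select_candidates(
        cohort, alog, min_fraction, condition, lexicon, label_user_days
    )
    diag.n_candidates = len(candidates)
    cohort_users = {m.user_id for m in cohort}
    bg = set(background_users) - cohort_users
    profiles = build_temporal_profiles(alog, candidates, cohort_users, bg)
    rejected, kept, _ = temporal_filter(profiles, q)
    diag.temporal_rejected = rejected
    kept_set = set(kept)

    fitted: list[tuple[CandidateLabel, sccs.SCCSFit]] = []
    for cand in candidates:
        if cand.key not in kept_set:
            continue
        series = sccs.build_case_series(
            cohort,
            alog,
            (cand.label, cand.kind),
            window,
            label_user_days=label_user_days,
        )
        try:
            result = sccs.fit(series)
        except sccs.DegenerateSeriesError:
            diag.skipped[cand.key] = "no informative users"
            continue
        diag.fits[cand.key] = result
        if not result.converged:
            diag.skipped[cand.key] = "fit did not converge (boundary estimate)"
            continue
        fitted.append((cand, result))

    flags = bh_fdr([f.lrt_p for _, f in fitted], q)
    rows = [
        PrecursorRow(
            condition=condition,
            precursor_label=cand.label,
            label_kind=cand.kind,
            relative_hazard=f.relative_hazard,
            p_value=f.lrt_p,
            fdr_significant=True,
            n_users_exposed=f.n_exposed_users,
        )
        for (cand, f), sig in zip(fitted, flags)
        if sig
    ]
    rows.sort(key=lambda r: (-r.relative_hazard, r.precursor_label))
    return rows, diag


def gradient_check(
    label: tuple[str, str],
    condition_users: set[str],
    alog: AnnotatedLog,
    strata: Sequence[int] = (1, 2, 3, 4),
    label_user_days: Mapping[LabelKey, Mapping[str, set[int]]] | None = None,
) -> tuple[str, float]:
    """Dose-response check for one precursor.

    Users who queried the label are stratified by how many days they did so
    (counts at or above the last stratum pool into it). A Spearman rho >= .5
    between stratum index and the fraction of stratum members who have the
    condition is 'positive' (supporting evidence of a gradient), rho <= -.5
    with fewer than that 'negative'; anything else — including fewer than
    three populated strata — is 'undetermined'.
    """
    if label_user_days is None:
        label_user_days = alog.label_user_days()
    per_user = label_user_days.get(label_key(*label), {})
    strata = sorted(strata)
    top = strata[-1]
    frac: list[float] = []
    idx: list[int] = []
    by_stratum: dict[int, list[str]] = defaultdict(list)
    for uid, days in per_user.items():
        count = min(len(days), top)
        if count in strata:
            by_stratum[count].append(uid)
    for s in strata:
        members = by_stratum.get(s)
        if members:
            idx.append(s)
            frac.append(sum(1 for u in members if u in condition_users) / len(members))
    if len(idx) < 3:
        return "undetermined", math.nan
    rho = float(stats.spearmanr(idx, frac).statistic)
    if rho >= 0.5:
        return "positive", rho
    if rho <= -0.5:
        return "negative", rho
    return "undetermined", rho
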
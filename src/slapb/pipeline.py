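"""End-to-end driver: detect SIUs, expand the cohort, annotate queries,
screen each retained condition for precursors.

Every stage's in/out counts are collected so each report row can be audited
back through the filters, and all randomness (CV folds, background
sampling) flows from one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cohort as cohort_mod
from . import screening
from .categorize import CategoryMap, annotate_log
from .datamodel import (
    CohortMember,
    IncidenceTable,
    PrecursorReport,
    QueryLog,
)
from .lexicon import Lexicon, build_term_vectors
from .siu import InsufficientDataError, detect_sius, filter_conditions

log = logging.getLogger("slapb")

DEFAULT_THRESHOLD_GRID = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9)


@dataclass
class PipelineParams:
    min_siu: int = 25
    min_fraction: float = 0.01
    window: int = 15
    q: float = 0.05
    min_monthly_clicks: int = 10
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    rho_target: float = 0.3
    background_multiple: int = 10
    cv_folds: int = 5
    use_forward_selection: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    report: PrecursorReport
    sius: list = field(default_factory=list)
    cohort: list[CohortMember] = field(default_factory=list)
    threshold: float = 0.0
    cv_auc: float = float("nan")
    threshold_curve: object = None
    counts: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def run_all(
    qlog: QueryLog,
    lexicon: Lexicon,
    cmap: CategoryMap,
    incidence: IncidenceTable,
    params: PipelineParams | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    counts: dict[str, int] = {"records": len(qlog), "users": len(qlog.user_ids())}

    # stage 1a: self-identified users
    sius = detect_sius(qlog, lexicon)
    retained_conditions, retained_sius = filter_conditions(sius, params.min_siu)
    counts["siu_records"] = len(sius)
    counts["siu_conditions_retained"] = len(retained_conditions)
    counts["siu_records_retained"] = len(retained_sius)
    log.info(
        "SIU detection: %d records, %d conditions retained at min_siu=%d",
        len(sius),
        len(retained_conditions),
        params.min_siu,
    )

    # stage 1b: classifier-based cohort expansion; any failure (degenerate
    # labels, too few conditions for the incidence correlation) falls back
    # to the SIU-only cohort
    vectors = build_term_vectors(qlog, lexicon)
    features = cohort_mod.compute_features(vectors, lexicon)
    threshold, auc, curve, scorer = 0.0, float("nan"), None, None
    try:
        labels = cohort_mod.label_training(sius, features)
        columns = cohort_mod.FEATURE_COLUMNS
        if params.use_forward_selection:
            columns, _ = cohort_mod.forward_select(
                features, labels, params.cv_folds, params.seed
            )
        scorer, auc = cohort_mod.train_and_cv(
            features, labels, params.cv_folds, params.seed, columns
        )
        threshold, curve = cohort_mod.tune_threshold(
            scorer,
            features,
            sius,
            counts["users"],
            incidence,
            params.threshold_grid,
            params.rho_target,
        )
    except (cohort_mod.DegenerateLabelsError, InsufficientDataError) as exc:
        log.warning("cohort expansion disabled (%s); using SIU-only cohort", exc)
    if scorer is not None:
        members = cohort_mod.expand_cohort(
            scorer, threshold, qlog, lexicon, features, sius
        )
    else:
        members = [
            CohortMember(r.user_id, r.condition, r.event_day, "siu")
            for r in sius
            if r.primary
        ]
    members = [m for m in members if m.condition in set(retained_conditions)]
    counts["cohort_members"] = len(members)
    counts["cohort_classified"] = sum(1 for m in members if m.source == "classified")

    # stage 2: query generalization
    alog = annotate_log(qlog, cmap)
    label_user_days = alog.label_user_days()

    # stage 3: per-condition screens
    rng = np.random.default_rng(params.seed)
    all_users = qlog.user_ids()
    report = PrecursorReport()
    diagnostics: dict[str, screening.ScreenDiagnostics] = {}
    for condition in retained_conditions:
        cohort_c = [m for m in members if m.condition == condition]
        if not cohort_c:
            continue
        cohort_users = {m.user_id for m in cohort_c}
        pool = [u for u in all_users if u not in cohort_users]
        size = min(params.background_multiple * len(cohort_c), len(pool))
        background = rng.choice(pool, size=size, replace=False) if size else []
        rows, diag = screening.run_screen(
            condition,
            cohort_c,
            alog,
            background,
            lexicon=lexicon,
            q=params.q,
            window=params.window,
            min_fraction=params.min_fraction,
            label_user_days=label_user_days,
        )
        counts[f"candidates[{condition}]"] = diag.n_candidates
        counts[f"temporal_rejected[{condition}]"] = len(diag.temporal_rejected)
        counts[f"reported[{condition}]"] = len(rows)
        report.rows.extend(rows)
        diagnostics[condition] = diag
    report.sort()
    return PipelineResult(
        report=report,
        sius=sius,
        cohort=members,
        threshold=threshold,
        cv_auc=auc,
        threshold_curve=curve,
        counts=counts,
        diagnostics=diagnostics,
    )
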
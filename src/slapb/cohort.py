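"""Cohort expansion: from self-identified users to a larger event cohort.

The question the classifier answers, per user, is: how likely is it that
the disease this user queried most often is the one they actually have?
Training labels come from the self-identified users, for whom the answer is
checkable. Each user with at least one disease query is summarized by eight
features of their disease/drug query profile (top-disease count, runner-up
count, their ratio, top-disease popularity, breadth counts at three depths,
and a drug-relatedness score from the disease-drug co-occurrence matrix).
A regularized logistic model — any linear margin scorer would do, only the
score/threshold semantics matter downstream — is trained with stratified
five-fold cross-validation, optionally after greedy forward feature
selection, and the operating threshold is tuned so that the per-condition
make-up of the expanded cohort still rank-correlates with reference
incidence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .datamodel import CohortMember, IncidenceTable, QueryLog, SIURecord
from .lexicon import Lexicon, TermCountVector, match_terms
from .siu import InsufficientDataError, incidence_rank_correlation

FEATURE_COLUMNS = ["f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8"]


class DegenerateLabelsError(ValueError):
    """Training labels contain a single class."""


def _top_two(counts: dict[str, int]) -> tuple[str, int, int]:
    """Most common disease (ties -> lexicographic), its count, runner-up count."""
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top, c1 = ordered[0]
    c2 = ordered[1][1] if len(ordered) > 1 else 0
    return top, c1, c2


def build_drug_disease_matrix(
    vectors: Sequence[TermCountVector], lexicon: Lexicon
) -> dict[tuple[str, str], int]:
    """M[(disease, drug)] = number of users who queried both."""
    m: dict[tuple[str, str], int] = defaultdict(int)
    for vec in vectors:
        diseases = [t for t in vec.counts if lexicon.terms.get(t) == "disease"]
        drugs = [t for t in vec.counts if lexicon.terms.get(t) == "drug"]
        for dis in diseases:
            for drug in drugs:
                m[(dis, drug)] += 1
    return dict(m)


def compute_features(
    vectors: Sequence[TermCountVector],
    lexicon: Lexicon,
    cooccurrence: Mapping[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Eight-feature summary per user, indexed by user_id.

    Users with no disease queries are excluded (f1 is undefined for them).
    The returned frame carries the feature columns plus ``top_disease``.
    f3 uses a max(f2, 1) denominator guard so a lone disease gives f3 = f1.
    """
    if cooccurrence is None:
        cooccurrence = build_drug_disease_matrix(vectors, lexicon)
    disease_users: dict[str, int] = defaultdict(int)
    per_user_disease: dict[str, dict[str, int]] = {}
    per_user_drugs: dict[str, list[str]] = {}
    for vec in vectors:
        d = {t: c for t, c in vec.counts.items() if lexicon.terms.get(t) == "disease"}
        if d:
            per_user_disease[vec.user_id] = d
            for t in d:
                disease_users[t] += 1
        per_user_drugs[vec.user_id] = [
            t for t in vec.counts if lexicon.terms.get(t) == "drug"
        ]
    n_users = len(vectors)
    rows = []
    index = []
    for vec in vectors:
        d = per_user_disease.get(vec.user_id)
        if not d:
            continue
        top, f1, f2 = _top_two(d)
        counts = list(d.values())
        rows.append(
            {
                "f1": f1,
                "f2": f2,
                "f3": f1 / max(f2, 1),
                "f4": disease_users[top] / n_users,
                "f5": sum(1 for c in counts if c > 1),
                "f6": sum(1 for c in counts if c > 5),
                "f7": sum(1 for c in counts if c > 10),
                "f8": sum(
                    cooccurrence.get((top, drug), 0)
                    for drug in per_user_drugs[vec.user_id]
                ),
                "top_disease": top,
            }
        )
        index.append(vec.user_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="user_id"))


def label_training(
    sius: Iterable[SIURecord], features: pd.DataFrame
) -> pd.Series:
    """1 iff the user's most frequently queried disease equals their
    (primary) self-identified condition. Indexed by user_id; only SIUs with
    feature rows appear."""
    primary = {r.user_id: r.condition for r in sius if r.primary}
    uids = [u for u in features.index if u in primary]
    return pd.Series(
        [int(features.loc[u, "top_disease"] == primary[u]) for u in uids],
        index=pd.Index(uids, name="user_id"),
        dtype=int,
    )


@dataclass
class LinearScorer:
    """A fitted linear model exposing scores in [0, 1]."""

    model: object
    columns: list[str]

    def score(self, features: pd.DataFrame) -> pd.Series:
        x = features[self.columns].to_numpy(dtype=float)
        return pd.Series(
            self.model.predict_proba(x)[:, 1], index=features.index
        )


def _make_model(seed: int):
    return make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
    )


def _check_two_classes(y: np.ndarray, k_folds: int) -> None:
    # stratified CV needs every class in every training fold
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2 or counts.min() < k_folds:
        raise DegenerateLabelsError(
            "training labels need two classes with at least one member per fold"
        )


def _cv_auc(x: np.ndarray, y: np.ndarray, k_folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(x, y):
        model = _make_model(seed)
        model.fit(x[train], y[train])
        aucs.append(roc_auc_score(y[test], model.predict_proba(x[test])[:, 1]))
    return float(np.mean(aucs))


def train_and_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    k_folds: int = 5,
    seed: int = 0,
    columns: Sequence[str] | None = None,
) -> tuple[LinearScorer, float]:
    """Stratified k-fold CV AUC plus a scorer refit on all training data."""
    cols = list(columns if columns is not None else FEATURE_COLUMNS)
    aligned = features.loc[labels.index]
    y = labels.to_numpy()
    _check_two_classes(y, k_folds)
    x = aligned[cols].to_numpy(dtype=float)
    auc = _cv_auc(x, y, k_folds, seed)
    model = _make_model(seed)
    model.fit(x, y)
    return LinearScorer(model, cols), auc


def forward_select(
    features: pd.DataFrame,
    labels: pd.Series,
    k_folds: int = 5,
    seed: int = 0,
    min_gain: float = 1e-4,
    candidates: Sequence[str] | None = None,
) -> tuple[list[str], float]:
    """Greedy sequential forward selection by CV AUC; stops when no single
    addition improves the AUC by more than ``min_gain``."""
    pool = list(candidates if candidates is not None else FEATURE_COLUMNS)
    aligned = features.loc[labels.index]
    y = labels.to_numpy()
    _check_two_classes(y, k_folds)
    selected: list[str] = []
    best_auc = 0.5
    while pool:
        scored = [
            (
                _cv_auc(
                    aligned[selected + [c]].to_numpy(dtype=float), y, k_folds, seed
                ),
                c,
            )
            for c in pool
        ]
        auc, col = max(scored)
        if auc <= best_auc + min_gain and selected:
            break
        if not selected and auc <= 0.5 + min_gain:
            # nothing informative at all: keep the single best-scoring feature
            selected, best_auc = [col], auc
            break
        selected.append(col)
        pool.remove(col)
        best_auc = auc
    return selected, best_auc


def tune_threshold(
    scorer: LinearScorer,
    features: pd.DataFrame,
    sius: Sequence[SIURecord],
    n_users: int,
    incidence: IncidenceTable,
    grid: Sequence[float],
    rho_target: float = 0.3,
) -> tuple[float, pd.DataFrame]:
    """Sweep the score threshold and pick the operating point.

    Threshold 0 means the SIU population alone. For t > 0 the cohort is the
    SIUs plus every user scoring above t, assigned their most-common
    disease. The chosen threshold is the smallest grid value (i.e. the
    largest cohort) whose per-condition fractions still rank-correlate with
    reference incidence at rho >= rho_target; if none qualifies the sweep
    falls back to 0.
    """
    grid = sorted(set(float(t) for t in grid))
    if not grid:
        raise ValueError("empty threshold grid")
    primary = {r.user_id: (r.condition, r.event_day) for r in sius if r.primary}
    scores = scorer.score(features)
    curve_rows = []
    best = None
    for t in grid:
        assigned: dict[str, str] = {u: c for u, (c, _) in primary.items()}
        if t > 0:
            for uid, s in scores.items():
                if s > t and uid not in assigned:
                    assigned[uid] = features.loc[uid, "top_disease"]
        counts: dict[str, int] = defaultdict(int)
        for cond in assigned.values():
            counts[cond] += 1
        fractions = {c: n / n_users for c, n in counts.items()}
        try:
            rho, _ = incidence_rank_correlation(fractions, incidence)
        except InsufficientDataError:
            rho = np.nan
        curve_rows.append({"threshold": t, "rho": rho, "cohort_size": len(assigned)})
        if best is None and not np.isnan(rho) and rho >= rho_target and t > 0:
            best = t
    curve = pd.DataFrame(curve_rows)
    return (best if best is not None else 0.0), curve


def expand_cohort(
    scorer: LinearScorer,
    threshold: float,
    log: QueryLog,
    lexicon: Lexicon,
    features: pd.DataFrame,
    sius: Sequence[SIURecord],
) -> list[CohortMember]:
    """Union of SIUs (with their self-identification day as event day) and
    classifier-accepted users (event day = first query mentioning their
    assigned condition, by analogy with the SIU first-query convention).
    Duplicate-free; SIU membership wins."""
    members: dict[str, CohortMember] = {}
    for r in sius:
        if r.primary:
            members[r.user_id] = CohortMember(r.user_id, r.condition, r.event_day, "siu")
    if threshold > 0:
        scores = scorer.score(features)
        accepted = {
            uid: features.loc[uid, "top_disease"]
            for uid, s in scores.items()
            if s > threshold and uid not in members
        }
        first_day: dict[str, int] = {}
        for rec in log.records:
            cond = accepted.get(rec.user_id)
            if cond is None:
                continue
            if rec.user_id in first_day and rec.day >= first_day[rec.user_id]:
                continue
            if any(c == cond for c, _ in match_terms(rec.text, lexicon)):
                first_day[rec.user_id] = rec.day
        for uid, cond in accepted.items():
            if uid in first_day:
                members[uid] = CohortMember(uid, cond, first_day[uid], "classified")
    return [members[u] for u in sorted(members)]


def multiclass_accuracy(
    vectors: Sequence[TermCountVector],
    sius: Sequence[SIURecord],
    lexicon: Lexicon,
    attribute_sets: Sequence[Sequence[str]],
    k_folds: int = 5,
    seed: int = 0,
) -> dict[tuple[str, ...], float]:
    """Five-fold CV accuracy of a multinomial linear classifier predicting
    each SIU's condition from term-count features restricted to the given
    kinds (subsets of disease/drug/symptom). Conditions with fewer SIUs
    than folds are left out of that evaluation."""
    primary = {r.user_id: r.condition for r in sius if r.primary}
    by_uid = {v.user_id: v for v in vectors}
    uids = [u for u in sorted(primary) if u in by_uid]
    out: dict[tuple[str, ...], float] = {}
    for kinds in attribute_sets:
        kinds = tuple(sorted(kinds))
        terms = sorted(
            t for t, k in lexicon.terms.items() if k in kinds
        )
        t_index = {t: j for j, t in enumerate(terms)}
        y_all = np.array([primary[u] for u in uids])
        classes, class_counts = np.unique(y_all, return_counts=True)
        valid = set(classes[class_counts >= k_folds])
        mask = np.array([primary[u] in valid for u in uids])
        kept = [u for u, m in zip(uids, mask) if m]
        if len(set(y_all[mask])) < 2:
            raise DegenerateLabelsError("fewer than two classes with enough SIUs")
        x = np.zeros((len(kept), len(terms)))
        for i, u in enumerate(kept):
            for t, c in by_uid[u].counts.items():
                j = t_index.get(t)
                if j is not None:
                    x[i, j] = c
        y = y_all[mask]
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        accs = []
        for train, test in skf.split(x, y):
            model = _make_model(seed)
            model.fit(x[train], y[train])
            accs.append(float(np.mean(model.predict(x[test]) == y[test])))
        out[kinds] = float(np.mean(accs))
    return out
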
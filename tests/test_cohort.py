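import numpy as np
import pandas as pd
import pytest

from slapb.cohort import (
    DegenerateLabelsError,
    FEATURE_COLUMNS,
    build_drug_disease_matrix,
    compute_features,
    expand_cohort,
    forward_select,
    label_training,
    multiclass_accuracy,
    train_and_cv,
    tune_threshold,
)
from slapb.datamodel import IncidenceTable, QueryLog, QueryRecord, SIURecord
from slapb.lexicon import TermCountVector, build_term_vectors
from slapb.siu import detect_sius, siu_incidence_check


def vec(uid, counts):
    return TermCountVector(uid, counts)


def test_feature_definitions_on_two_disease_profile(lexicon):
    vectors = [vec("u1", {"asthma": 10, "gout": 2})]
    feats = compute_features(vectors, lexicon)
    row = feats.loc["u1"]
    assert (row.f1, row.f2, row.f3) == (10, 2, 5)
    assert (row.f5, row.f6, row.f7, row.f8) == (2, 1, 0, 0)
    assert row.top_disease == "asthma"
    assert row.f4 == 1.0  # the only user queried it


def test_single_disease_once_uses_denominator_guard(lexicon):
    feats = compute_features([vec("u1", {"gout": 1})], lexicon)
    row = feats.loc["u1"]
    assert (row.f1, row.f2, row.f3, row.f5) == (1, 0, 1, 0)


def test_drug_relatedness_from_cooccurrence_matrix(lexicon):
    m = {("asthma", "aspirin"): 7}
    feats = compute_features(
        [vec("u1", {"asthma": 3, "aspirin": 1})], lexicon, cooccurrence=m
    )
    assert feats.loc["u1", "f8"] == 7


def test_cooccurrence_matrix_counts_users_not_queries(lexicon):
    vectors = [
        vec("u1", {"asthma": 5, "aspirin": 2}),
        vec("u2", {"asthma": 1, "aspirin": 1}),
        vec("u3", {"asthma": 1}),
    ]
    m = build_drug_disease_matrix(vectors, lexicon)
    assert m[("asthma", "aspirin")] == 2


def test_user_without_disease_queries_excluded(lexicon):
    feats = compute_features([vec("u1", {"aspirin": 3})], lexicon)
    assert feats.empty


def test_features_equal_brute_force_on_small_log(lexicon, small_scenario):
    _, log, _ = small_scenario
    users = set(log.user_ids()[:150])
    sub = QueryLog(
        [r for r in log.records if r.user_id in users], log.observation_length
    )
    vectors = build_term_vectors(sub, lexicon)
    feats = compute_features(vectors, lexicon)
    for v in vectors:
        diseases = {
            t: c for t, c in v.counts.items() if lexicon.terms[t] == "disease"
        }
        if not diseases:
            assert v.user_id not in feats.index
            continue
        ordered = sorted(diseases.items(), key=lambda kv: (-kv[1], kv[0]))
        assert feats.loc[v.user_id, "f1"] == ordered[0][1]
        assert feats.loc[v.user_id, "f5"] == sum(1 for c in diseases.values() if c > 1)


def test_label_training_rule(lexicon):
    vectors = [vec("u1", {"hiv": 6, "influenza": 1}), vec("u2", {"hiv": 2, "breast cancer": 4})]
    feats = compute_features(vectors, lexicon)
    sius = [SIURecord("u1", "hiv", 5), SIURecord("u2", "hiv", 9)]
    labels = label_training(sius, feats)
    assert labels.to_dict() == {"u1": 1, "u2": 0}


def _separable(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = pd.Series(np.tile([0, 1], n // 2))
    x = pd.DataFrame(rng.normal(size=(n, 8)), columns=FEATURE_COLUMNS)
    x["f1"] = y * 10.0 + x["f1"] * 0.01
    y.index = x.index
    return x, y


def test_separable_features_reach_perfect_auc():
    x, y = _separable()
    scorer, auc = train_and_cv(x, y)
    assert auc == pytest.approx(1.0)
    assert scorer.score(x).between(0, 1).all()


def test_single_class_labels_raise():
    x, y = _separable()
    with pytest.raises(DegenerateLabelsError):
        train_and_cv(x, pd.Series(1, index=y.index))


def test_permuted_labels_give_chance_auc():
    x, y = _separable()
    aucs = []
    for seed in range(20):
        perm = pd.Series(
            np.random.default_rng(seed).permutation(y.to_numpy()), index=y.index
        )
        aucs.append(train_and_cv(x, perm, seed=seed)[1])
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_forward_selection_finds_informative_feature_first():
    x, y = _separable()
    selected, auc = forward_select(x, y)
    assert selected[0] == "f1"
    assert auc > 0.95


def test_forward_selection_on_pure_noise_stays_small():
    # greedy CV-AUC chases small spurious gains on noise, so the subset can
    # exceed one feature, but it stays small and near-chance
    rng = np.random.default_rng(3)
    x = pd.DataFrame(rng.normal(size=(200, 8)), columns=FEATURE_COLUMNS)
    y = pd.Series(np.tile([0, 1], 100))
    selected, auc = forward_select(x, y)
    assert len(selected) <= 4
    assert abs(auc - 0.5) < 0.15


class StepScorer:
    """Score 1 for a fixed set of users, 0 otherwise."""

    def __init__(self, positives):
        self.positives = positives

    def score(self, features):
        return pd.Series(
            [1.0 if u in self.positives else 0.0 for u in features.index],
            index=features.index,
        )


def _threshold_fixture(lexicon):
    rng = np.random.default_rng(4)
    incidence = IncidenceTable([("asthma", 0.04), ("gout", 0.02), ("migraine", 0.01)])
    vectors, sius, positives = [], [], set()
    uid = 0
    for cond, inc in incidence.rows:
        for i in range(int(inc * 1000)):
            user = f"u{uid:03d}"
            uid += 1
            vectors.append(vec(user, {cond: 5}))
            if i % 2 == 0:
                sius.append(SIURecord(user, cond, 10))
            else:
                positives.add(user)
    feats = compute_features(vectors, lexicon)
    return incidence, feats, sius, positives


def test_step_scorer_thresholds_in_open_interval_identical(lexicon):
    incidence, feats, sius, positives = _threshold_fixture(lexicon)
    scorer = StepScorer(positives)
    _, curve = tune_threshold(
        scorer, feats, sius, 1000, incidence, grid=[0.0, 0.2, 0.5, 0.8]
    )
    mid = curve[curve.threshold > 0]
    assert mid.cohort_size.nunique() == 1
    assert mid.rho.nunique() == 1


def test_threshold_above_max_score_gives_siu_only_cohort(lexicon):
    incidence, feats, sius, positives = _threshold_fixture(lexicon)
    _, curve = tune_threshold(
        StepScorer(positives), feats, sius, 1000, incidence, grid=[0.0, 2.0]
    )
    n_siu = len({r.user_id for r in sius})
    assert curve[curve.threshold == 2.0].cohort_size.item() == n_siu


def test_rho_at_threshold_zero_equals_siu_incidence_check(lexicon):
    incidence, feats, sius, positives = _threshold_fixture(lexicon)
    _, curve = tune_threshold(
        StepScorer(positives), feats, sius, 1000, incidence, grid=[0.0, 0.5]
    )
    rho_zero = curve[curve.threshold == 0.0].rho.item()
    rho_check, _ = siu_incidence_check(sius, 1000, incidence)
    assert rho_zero == pytest.approx(rho_check)


def test_empty_grid_is_config_error(lexicon):
    incidence, feats, sius, positives = _threshold_fixture(lexicon)
    with pytest.raises(ValueError):
        tune_threshold(StepScorer(positives), feats, sius, 1000, incidence, grid=[])


def _expand_fixture(lexicon):
    records = [
        QueryRecord("u1", 40, "i was diagnosed with gout"),
        QueryRecord("u1", 50, "gout treatment"),
        QueryRecord("u2", 30, "gout symptoms"),
        QueryRecord("u2", 60, "gout diet"),
        QueryRecord("u3", 20, "asthma inhaler"),
    ]
    log = QueryLog(records)
    vectors = build_term_vectors(log, lexicon)
    feats = compute_features(vectors, lexicon)
    sius = detect_sius(log, lexicon)
    return log, feats, sius


def test_expand_cohort_dedups_and_sets_event_days(lexicon):
    log, feats, sius = _expand_fixture(lexicon)
    scorer = StepScorer({"u1", "u2", "u3"})
    members = expand_cohort(scorer, 0.5, log, lexicon, feats, sius)
    by_uid = {m.user_id: m for m in members}
    # u1 is both SIU and above threshold: single entry, SIU wins
    assert by_uid["u1"].source == "siu" and by_uid["u1"].event_day == 40
    # u2 classified: event day = first query mentioning the condition
    assert by_uid["u2"] .source == "classified" and by_uid["u2"].event_day == 30
    assert by_uid["u3"].condition == "asthma"


def test_expand_cohort_monotone_in_threshold(lexicon, small_scenario):
    _, log, _ = small_scenario
    vectors = build_term_vectors(log, lexicon)
    feats = compute_features(vectors, lexicon)
    sius = detect_sius(log, lexicon)
    labels = label_training(sius, feats)
    scorer, _ = train_and_cv(feats, labels, seed=1)
    lo = {m.user_id for m in expand_cohort(scorer, 0.1, log, lexicon, feats, sius)}
    hi = {m.user_id for m in expand_cohort(scorer, 0.6, log, lexicon, feats, sius)}
    assert hi <= lo
    assert {r.user_id for r in sius} <= hi


def test_below_threshold_non_siu_excluded(lexicon):
    log, feats, sius = _expand_fixture(lexicon)
    members = expand_cohort(StepScorer(set()), 0.5, log, lexicon, feats, sius)
    assert [m.user_id for m in members] == ["u1"]


def test_classifier_separates_affected_users_on_simulated_log(
    lexicon, small_scenario
):
    """Affected users query their condition ~Poisson(6.8) against a 2.15
    background; the scorer must separate correct from incorrect
    top-disease assignments well above chance."""
    _, log, _ = small_scenario
    vectors = build_term_vectors(log, lexicon)
    feats = compute_features(vectors, lexicon)
    sius = detect_sius(log, lexicon)
    labels = label_training(sius, feats)
    _, auc = train_and_cv(feats, labels, seed=0)
    assert auc > 0.75


def test_multiclass_accuracy_separable_by_disease_terms(lexicon):
    vectors, sius = [], []
    conditions = ["asthma", "gout", "migraine"]
    for i in range(60):
        cond = conditions[i % 3]
        uid = f"u{i:02d}"
        vectors.append(vec(uid, {cond: 3}))
        sius.append(SIURecord(uid, cond, 1))
    acc = multiclass_accuracy(
        vectors, sius, lexicon, [["disease"], ["symptom"]]
    )
    assert acc[("disease",)] == 1.0
    # symptom counts carry no signal for these users
    assert acc[("symptom",)] < 0.6
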
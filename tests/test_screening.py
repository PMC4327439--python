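import itertools

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from slapb.categorize import annotate_log
from slapb.datamodel import CohortMember, QueryLog, QueryRecord
from slapb.screening import (
    bh_fdr,
    build_temporal_profiles,
    gradient_check,
    run_screen,
    select_candidates,
    temporal_filter,
)
from slapb.siu import detect_sius
from slapb.synthetic import (
    null_scenario,
    reference_scenario,
    simulate,
    toy_category_map,
)


def brute_force_step_up(p, q):
    """Independent re-statement of the step-up rule: largest k with
    p_(k) <= k q / m rejects the k smallest p-values."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
            break
    flags = [False] * m
    for i in order[:k_star]:
        flags[i] = True
    return flags


def test_bh_fdr_hand_example():
    flags = bh_fdr([0.001, 0.01, 0.02, 0.2, 0.9], q=0.05)
    assert flags.tolist() == [True, True, True, False, False]


def test_bh_fdr_degenerate_inputs():
    assert not bh_fdr([1.0, 1.0, 1.0]).any()
    assert bh_fdr([0.0, 0.0]).all()
    assert bh_fdr([]).size == 0
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_fdr_matches_brute_force_on_all_short_grids():
    grid = [0.004, 0.02, 0.3, 1.0]
    for m in range(1, 5):
        for combo in itertools.product(grid, repeat=m):
            assert bh_fdr(list(combo), 0.05).tolist() == brute_force_step_up(
                list(combo), 0.05
            )
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = rng.choice(grid, size=rng.integers(5, 9)).tolist()
        assert bh_fdr(p, 0.05).tolist() == brute_force_step_up(p, 0.05)


def test_bh_fdr_agrees_with_statsmodels():
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.random(30)
        expected = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert (bh_fdr(p, 0.05) == expected).all()


def test_temporal_filter_rejects_shared_signal_keeps_cohort_only():
    rng = np.random.default_rng(2)
    days = 183
    spike = np.zeros(days)
    spike[90:93] = 60
    shared_a = rng.poisson(5, days) + spike
    shared_b = rng.poisson(25, days) + 5 * spike
    lone_a = rng.poisson(5, days) + spike  # cohort-only structure
    lone_b = rng.poisson(25.0, days).astype(float)
    profiles = {
        ("category", "news"): (shared_a, shared_b),
        ("category", "precursor"): (lone_a, lone_b),
        ("category", "flat"): (np.zeros(days), rng.poisson(5, days).astype(float)),
    }
    rejected, kept, stats = temporal_filter(profiles, q=0.05)
    assert ("category", "news") in rejected
    assert ("category", "precursor") in kept
    # constant series: correlation undefined, label kept
    assert ("category", "flat") in kept
    assert np.isnan(stats[("category", "flat")][0])


def test_identical_nonconstant_series_rejected():
    series = np.arange(20.0)
    rejected, _, stats = temporal_filter({("query", "x"): (series, series)}, q=0.05)
    assert rejected == [("query", "x")]
    assert stats[("query", "x")][0] == pytest.approx(1.0)


def _cohort_log(n_cohort=200, label_users=2):
    records = [QueryRecord(f"u{i}", 0, "filler text") for i in range(n_cohort)]
    records += [QueryRecord(f"u{i}", 5, "rare label") for i in range(label_users)]
    log = QueryLog(records)
    cohort = [CohortMember(f"u{i}", "cond", 10, "siu") for i in range(n_cohort)]
    return cohort, annotate_log(log, {})


def test_candidate_fraction_boundary_inclusive():
    cohort, alog = _cohort_log(label_users=2)  # exactly 1% of 200
    labels = {c.label for c in select_candidates(cohort, alog, 0.01)}
    assert "rare label" in labels
    cohort, alog = _cohort_log(label_users=1)
    labels = {c.label for c in select_candidates(cohort, alog, 0.01)}
    assert "rare label" not in labels


def test_candidates_naming_the_condition_are_excluded(lexicon):
    records = [
        QueryRecord(f"u{i}", 2, t)
        for i in range(20)
        for t in ("asthma treatment", "gardening")
    ]
    cohort = [CohortMember(f"u{i}", "asthma", 10, "siu") for i in range(20)]
    alog = annotate_log(QueryLog(records), {})
    labels = {
        c.label
        for c in select_candidates(cohort, alog, 0.01, "asthma", lexicon)
    }
    assert labels == {"gardening"}


def test_empty_cohort_is_an_error():
    _, alog = _cohort_log()
    with pytest.raises(ValueError):
        select_candidates([], alog)


def test_background_sample_must_be_disjoint():
    cohort, alog = _cohort_log()
    with pytest.raises(ValueError):
        build_temporal_profiles(alog, [], {"u0"}, {"u0", "zz"})


@pytest.mark.parametrize(
    "fractions, expected",
    [
        ((0.01, 0.02, 0.03, 0.05), "positive"),
        ((0.05, 0.03, 0.02, 0.01), "negative"),
    ],
)
def test_gradient_check_monotone_strata(fractions, expected):
    records, condition_users = [], set()
    uid = 0
    for stratum, frac in enumerate(fractions, start=1):
        for i in range(100):
            user = f"u{uid}"
            uid += 1
            for d in range(stratum):
                records.append(QueryRecord(user, d, "the label"))
            if i < round(frac * 100):
                condition_users.add(user)
    alog = annotate_log(QueryLog(records), {})
    verdict, rho = gradient_check(("the label", "query"), condition_users, alog)
    assert verdict == expected


def test_gradient_check_underpopulated_strata_undetermined():
    records = [QueryRecord("u1", 0, "the label"), QueryRecord("u2", 0, "the label")]
    alog = annotate_log(QueryLog(records), {})
    verdict, rho = gradient_check(("the label", "query"), {"u1"}, alog)
    assert verdict == "undetermined"


def test_screen_recovers_planted_precursor_and_rejects_spike(lexicon):
    config = reference_scenario(seed=21, n_users=3000)
    log, truth = simulate(config)
    cmap = toy_category_map(config)
    alog = annotate_log(log, cmap)
    cohort = [
        CohortMember(u, c, truth.event_day[u], "siu")
        for u, c in truth.condition.items()
        if c == "diabetes mellitus"
    ]
    cohort_users = {m.user_id for m in cohort}
    pool = [u for u in log.user_ids() if u not in cohort_users]
    bg = np.random.default_rng(0).choice(pool, size=len(cohort) * 5, replace=False)
    rows, diag = run_screen("diabetes mellitus", cohort, alog, bg, lexicon=lexicon)
    planted = [
        r for r in rows
        if r.precursor_label == "sugar free recipes" and r.label_kind == "category"
    ]
    assert len(planted) == 1
    assert 2.9 <= planted[0].relative_hazard <= 5.5
    assert ("category", "celebrity gossip") in diag.temporal_rejected
    # a label never queried by the cohort cannot be reported
    assert all(r.n_users_exposed > 0 for r in rows)


def test_null_screen_emits_almost_nothing(lexicon):
    fractions = []
    for rep in range(5):
        config = null_scenario(seed=500 + rep)
        log, truth = simulate(config)
        alog = annotate_log(log, toy_category_map(config))
        cohort = [
            CohortMember(r.user_id, r.condition, r.event_day, "siu")
            for r in detect_sius(log, lexicon)
            if r.primary
        ]
        cohort_users = {m.user_id for m in cohort}
        pool = [u for u in log.user_ids() if u not in cohort_users]
        bg = np.random.default_rng(rep).choice(pool, size=len(pool) // 2, replace=False)
        rows, diag = run_screen("asthma", cohort, alog, bg, lexicon=lexicon)
        fractions.append(len(rows) / diag.n_candidates)
    assert np.mean(fractions) <= 0.05
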
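"""Synthetic query-log generator with planted ground truth.

The generator realizes exactly the model the screen estimates: each
affected user's event day is drawn from the multinomial implied by the
non-homogeneous Poisson process — day weights exp(sum_c beta_c r_{c,d}),
where r_{c,d} marks the risk window following each day the user queried a
planted precursor category. Because the generative law matches the fitted
likelihood, parameter recovery is a sharp test rather than an approximate
one.

What is planted, per configuration:
  * condition assignment by reference incidence (at most one condition per
    user; the pipeline assigns one condition per user, so comorbidity is
    out of scope);
  * a self-identification trigger query ("i was diagnosed with <condition>")
    on the event day for a configurable fraction of affected users;
  * elevated post-event querying of the user's own condition (Poisson with
    mean 6.8 after the event vs 2.15 for background disease queriers — the
    two distributional anchors available for these rates);
  * precursor categories queried by everyone at a daily rate, which for
    affected users modulate the event-day distribution with the planted
    relative hazard;
  * background categories queried independently of everything;
  * news-spike categories: a burst on a few consecutive days across the
    whole population, emulating externally driven query spikes.

Exposure-query timing is uniform over the window (no distributional guidance
exists for it; uniform is the neutral choice). Each category is queried
through three text variants so that category labels aggregate several
query strings, as real category maps do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .categorize import CategoryMap, ClickRecord
from .datamodel import IncidenceTable, QueryLog, QueryRecord
from .lexicon import Lexicon
from .sccs import CaseSeries, user_series_from_days


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedPrecursor:
    condition: str
    category: str
    relative_hazard: float
    window: int = 15
    daily_query_prob: float = 0.01

    def __post_init__(self) -> None:
        if self.relative_hazard <= 0:
            raise ConfigError("relative hazard must be positive")
        if self.window < 1:
            raise ConfigError("risk window must be >= 1 day")


@dataclass(frozen=True)
class BackgroundCategory:
    name: str
    daily_query_prob: float


@dataclass(frozen=True)
class NewsSpike:
    category: str
    spike_day: int
    spike_height: float  # per-user query probability on each spike day
    base_daily_prob: float = 0.004
    duration: int = 3  # typical news spikes last a few days


@dataclass
class SimConfig:
    n_users: int
    incidence: IncidenceTable
    observation_length: int = 183
    siu_fraction: float = 1.0
    mean_condition_queries_affected: float = 6.8
    mean_condition_queries_background: float = 2.15
    background_disease_query_fraction: float = 0.2
    disease_pool: Optional[list[str]] = None  # defaults to toy_lexicon diseases
    precursors: list[PlantedPrecursor] = field(default_factory=list)
    background_categories: list[BackgroundCategory] = field(default_factory=list)
    news_spikes: list[NewsSpike] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(inc for _, inc in self.incidence.rows)
        if total > 1.0:
            raise ConfigError(f"incidence fractions sum to {total} > 1")
        for frac in (
            self.siu_fraction,
            self.background_disease_query_fraction,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(f"fraction {frac} outside [0, 1]")
        conditions = set(self.incidence.conditions())
        for p in self.precursors:
            if p.condition not in conditions:
                raise ConfigError(
                    f"precursor condition {p.condition!r} not in incidence table"
                )


@dataclass
class GroundTruth:
    condition: dict[str, str]  # affected user -> condition
    event_day: dict[str, int]
    siu_users: set[str]
    planted: dict[tuple[str, str], float]  # (condition, category) -> e^beta


_CATEGORY_TEMPLATES = ("{c}", "{c} guide", "{c} online")
_DISEASE_TEMPLATES = ("{d}", "{d} symptoms", "{d} treatment")
TRIGGER_TEMPLATE = "i was diagnosed with {d}"


def _user_ids(n_users: int) -> list[str]:
    width = max(5, len(str(n_users - 1)))
    return [f"u{i:0{width}d}" for i in range(n_users)]


def simulate(config: SimConfig) -> tuple[QueryLog, GroundTruth]:
    """Generate a query log and its ground truth. Same config (including
    seed) always yields a byte-identical log."""
    rng = np.random.default_rng(config.seed)
    n, length = config.n_users, config.observation_length
    uids = _user_ids(n)
    conditions = config.incidence.conditions()
    incidences = [dict(config.incidence.rows)[c] for c in conditions]
    pool = config.disease_pool
    if pool is None:
        pool = toy_lexicon().of_kind("disease")

    events: list[tuple[int, int, str]] = []  # (user index, day, text)

    def emit_category_days(cat: str, user_idx: np.ndarray, days: np.ndarray) -> None:
        variants = rng.integers(0, len(_CATEGORY_TEMPLATES), size=days.size)
        for u, d, v in zip(user_idx, days, variants):
            events.append((int(u), int(d), _CATEGORY_TEMPLATES[v].format(c=cat)))

    def draw_daily(cat: str, prob: float) -> tuple[np.ndarray, np.ndarray]:
        counts = rng.binomial(length, prob, size=n)
        total = int(counts.sum())
        days = rng.integers(0, length, size=total)
        user_idx = np.repeat(np.arange(n), counts)
        emit_category_days(cat, user_idx, days)
        return user_idx, days

    # 1. condition assignment
    probs = np.array(incidences + [1.0 - sum(incidences)])
    assignment = rng.choice(len(conditions) + 1, size=n, p=probs)

    # 2. background categories
    for bg in config.background_categories:
        draw_daily(bg.name, bg.daily_query_prob)

    # 3. precursor categories, queried by the whole population; keep the
    #    per-user day lists of each to build risk profiles
    precursor_days: dict[str, dict[int, list[int]]] = {}
    for cat in sorted({p.category for p in config.precursors}):
        prob = max(
            p.daily_query_prob for p in config.precursors if p.category == cat
        )
        user_idx, days = draw_daily(cat, prob)
        per_user: dict[int, list[int]] = {}
        for u, d in zip(user_idx, days):
            per_user.setdefault(int(u), []).append(int(d))
        precursor_days[cat] = per_user

    # 4. news spikes: a low base rate plus a burst over a few days
    for spike in config.news_spikes:
        draw_daily(spike.category, spike.base_daily_prob)
        for day in range(
            spike.spike_day, min(spike.spike_day + spike.duration, length)
        ):
            hit = np.nonzero(rng.random(n) < spike.spike_height)[0]
            emit_category_days(
                spike.category, hit, np.full(hit.size, day, dtype=int)
            )

    # 5. event days: multinomial over days with weights exp(sum beta r_d)
    by_condition: dict[str, list[PlantedPrecursor]] = {}
    for p in config.precursors:
        by_condition.setdefault(p.condition, []).append(p)
    affected = np.nonzero(assignment < len(conditions))[0]
    truth = GroundTruth(
        condition={},
        event_day={},
        siu_users=set(),
        planted={
            (p.condition, p.category): p.relative_hazard
            for p in config.precursors
        },
    )
    for u in affected:
        cond = conditions[assignment[u]]
        truth.condition[uids[u]] = cond
        planted = by_condition.get(cond)
        if not planted:
            day = int(rng.integers(0, length))
        else:
            log_w = np.zeros(length)
            for p in sorted(planted, key=lambda p: p.category):
                risk = np.zeros(length, dtype=bool)
                for e in precursor_days[p.category].get(int(u), ()):
                    risk[e + 1 : e + 1 + p.window] = True
                log_w += np.log(p.relative_hazard) * risk
            w = np.exp(log_w - log_w.max())
            day = int(rng.choice(length, p=w / w.sum()))
        truth.event_day[uids[u]] = day

    # 6. self-identification triggers on the event day
    siu_draw = rng.random(affected.size)
    for u, r in zip(affected, siu_draw):
        if r < config.siu_fraction:
            uid = uids[u]
            truth.siu_users.add(uid)
            events.append(
                (int(u), truth.event_day[uid], TRIGGER_TEMPLATE.format(d=truth.condition[uid]))
            )

    # 7. post-event querying of the own condition
    n_own = rng.poisson(config.mean_condition_queries_affected, size=affected.size)
    for u, k in zip(affected, n_own):
        uid = uids[u]
        start = truth.event_day[uid]
        days = start + (rng.random(int(k)) * (length - start)).astype(int)
        variants = rng.integers(0, len(_DISEASE_TEMPLATES), size=int(k))
        for d, v in zip(days, variants):
            events.append(
                (int(u), int(d), _DISEASE_TEMPLATES[v].format(d=truth.condition[uid]))
            )

    # 8. background disease interest, independent of any event
    noisy = np.nonzero(rng.random(n) < config.background_disease_query_fraction)[0]
    pick = rng.integers(0, len(pool), size=noisy.size)
    n_noise = rng.poisson(config.mean_condition_queries_background, size=noisy.size)
    for u, j, k in zip(noisy, pick, n_noise):
        disease = pool[int(j)]
        own = truth.condition.get(uids[u])
        if disease == own:  # background interest must be in some other disease
            disease = pool[(int(j) + 1) % len(pool)]
        days = rng.integers(0, length, size=int(k))
        variants = rng.integers(0, len(_DISEASE_TEMPLATES), size=int(k))
        for d, v in zip(days, variants):
            events.append((int(u), int(d), _DISEASE_TEMPLATES[v].format(d=disease)))

    events.sort()
    records = [
        QueryRecord(user_id=uids[u], day=d, text=text) for u, d, text in events
    ]
    return QueryLog(records, length), truth


def simulate_case_series(
    n_users: int,
    beta: float,
    window: int = 15,
    n_days: int = 183,
    exposure_rate: float = 2.0,
    rng: np.random.Generator | None = None,
) -> CaseSeries:
    """Directly simulate reduced case series under the SCCS model (no query
    text): per user, 1 + Poisson(exposure_rate) exposure days placed
    uniformly, one event day drawn with weight e^beta on risk days."""
    if rng is None:
        rng = np.random.default_rng(0)
    n_exp = 1 + rng.poisson(exposure_rate, size=n_users)
    users = []
    for i in range(n_users):
        days = rng.choice(n_days, size=min(int(n_exp[i]), n_days), replace=False)
        risk = np.zeros(n_days, dtype=bool)
        for e in days:
            risk[e + 1 : e + 1 + window] = True
        w = np.exp(beta * risk)
        event = int(rng.choice(n_days, p=w / w.sum()))
        users.append(
            user_series_from_days(f"s{i:05d}", n_days, event, days, window)
        )
    return CaseSeries(users, window)


def toy_lexicon() -> Lexicon:
    """A fixed small medical lexicon: 20 diseases, 10 drugs, 10 symptoms,
    each with at least one synonym where a common one exists."""
    diseases = {
        "myocardial infarction": ["heart attack"],
        "hiv": ["human immunodeficiency virus"],
        "diabetes mellitus": ["diabetes"],
        "herpes simplex": ["herpes"],
        "asthma": ["reactive airway disease"],
        "hypertension": ["high blood pressure"],
        "influenza": ["flu"],
        "anorexia nervosa": ["anorexia"],
        "depression": ["major depressive disorder"],
        "arthritis": ["joint inflammation"],
        "breast cancer": ["mammary carcinoma"],
        "lyme disease": ["lyme borreliosis"],
        "epilepsy": ["seizure disorder"],
        "migraine": ["migraine headache"],
        "celiac disease": ["coeliac disease"],
        "gout": ["gouty arthritis"],
        "psoriasis": ["plaque psoriasis"],
        "pregnancy": ["gestation"],
        "allergy": ["allergies"],
        "schizophrenia": ["schizoaffective disorder"],
    }
    drugs = {
        "aspirin": ["acetylsalicylic acid"],
        "ibuprofen": ["advil"],
        "metformin": ["glucophage"],
        "insulin": ["humulin"],
        "atorvastatin": ["lipitor"],
        "acyclovir": ["zovirax"],
        "fluoxetine": ["prozac"],
        "albuterol": ["salbutamol"],
        "levothyroxine": ["synthroid"],
        "amoxicillin": ["amoxil"],
    }
    symptoms = {
        "headache": ["head ache"],
        "fever": ["pyrexia"],
        "cough": ["coughing"],
        "fatigue": ["tiredness"],
        "nausea": ["queasiness"],
        "chest pain": ["chest ache"],
        "shortness of breath": ["dyspnea"],
        "rash": ["skin rash"],
        "dizziness": ["vertigo"],
        "sore throat": ["throat pain"],
    }
    terms: dict[str, str] = {}
    synonym_map: dict[str, str] = {}
    for table, kind in ((diseases, "disease"), (drugs, "drug"), (symptoms, "symptom")):
        for canon, syns in table.items():
            terms[canon] = kind
            for s in syns:
                synonym_map[s] = canon
    return Lexicon(terms, synonym_map)


def _category_names(config: SimConfig) -> list[str]:
    names = {bg.name for bg in config.background_categories}
    names |= {p.category for p in config.precursors}
    names |= {s.category for s in config.news_spikes}
    return sorted(names)


def toy_category_map(config: SimConfig) -> CategoryMap:
    """The category map matching the generator's query vocabulary: every
    text variant of a category maps to one page carrying that category."""
    cmap: CategoryMap = {}
    for cat in _category_names(config):
        page = "pg_" + cat.replace(" ", "_")
        for tmpl in _CATEGORY_TEMPLATES:
            cmap[tmpl.format(c=cat)] = (page, (cat,))
    return cmap


def toy_clicks(
    config: SimConfig, n_months: int = 6, monthly_clicks: int = 12
) -> tuple[list[ClickRecord], dict[str, list[str]]]:
    """Click records and page categories from which
    :func:`slapb.categorize.build_category_map` reconstructs
    :func:`toy_category_map` (every pair clears the monthly threshold)."""
    clicks: list[ClickRecord] = []
    page_categories: dict[str, list[str]] = {}
    for cat in _category_names(config):
        page = "pg_" + cat.replace(" ", "_")
        page_categories[page] = [cat]
        for tmpl in _CATEGORY_TEMPLATES:
            for month in range(n_months):
                clicks.append(
                    ClickRecord(tmpl.format(c=cat), page, month, monthly_clicks)
                )
    return clicks, page_categories


def null_scenario(seed: int, n_users: int = 500, n_categories: int = 30) -> SimConfig:
    """Global-null study conditions: one condition, no planted precursors,
    no spikes — every candidate label the screen sees is null."""
    categories = [
        BackgroundCategory(f"pastime {i:02d}", 0.008) for i in range(n_categories)
    ]
    return SimConfig(
        n_users=n_users,
        incidence=IncidenceTable([("asthma", 0.4)]),
        siu_fraction=1.0,
        background_disease_query_fraction=0.1,
        background_categories=categories,
        seed=seed,
    )


def reference_scenario(seed: int, n_users: int = 10_000) -> SimConfig:
    """The package's reference end-to-end scenario: five conditions, one
    planted precursor (relative hazard 4 within a 15-day window) for the
    most common condition, one news-spike confounder, and a dozen
    background categories."""
    background = [
        BackgroundCategory(name, 0.004)
        for name in (
            "gardening",
            "used cars",
            "travel deals",
            "home workouts",
            "online banking",
            "knitting patterns",
            "board games",
            "hiking trails",
            "car insurance",
            "photography tips",
            "guitar lessons",
            "coffee brewing",
        )
    ]
    return SimConfig(
        n_users=n_users,
        incidence=IncidenceTable(
            [
                ("diabetes mellitus", 0.15),
                ("asthma", 0.08),
                ("migraine", 0.05),
                ("gout", 0.03),
                ("psoriasis", 0.02),
            ]
        ),
        siu_fraction=1.0,
        precursors=[
            PlantedPrecursor("diabetes mellitus", "sugar free recipes", 4.0)
        ],
        background_categories=background,
        news_spikes=[NewsSpike("celebrity gossip", spike_day=90, spike_height=0.25)],
        seed=seed,
    )
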
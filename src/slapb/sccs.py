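"""Self-controlled case series (SCCS) estimation of relative hazards.

Model. Each case i is observed for D_i days and experiences exactly one
event, on day d_i. Events arise from a non-homogeneous Poisson process with
per-person baseline rate e^{theta_i}, multiplied by e^{beta} on "risk" days
— the W days following each exposure (here: each day the person queried the
candidate label). The log-likelihood is

    L(beta, theta) = sum_i sum_d [ y_{i,d} (theta_i + beta r_{i,d})
                                   - exp(theta_i + beta r_{i,d}) ],

with y_{i,d} the event indicator and r_{i,d} the risk-day indicator.

Because each person has exactly one event, every theta_i is profiled out in
closed form: theta_i(beta) = -log(n0_i + n1_i e^beta), where n1_i / n0_i
count risk / baseline days. Substituting gives the one-dimensional concave
profile log-likelihood

    Lp(beta) = sum_i [ beta e_i - log(n0_i + n1_i e^beta) - 1 ],

with e_i the event-in-risk indicator — the same maximizer as the joint
problem, which is kept around as a small-N simplex oracle. Lp is maximized
with the Nelder-Mead simplex by default. The person-level sufficient
statistics are (n1_i, n0_i, e_i): persons with no risk days or no baseline
days carry no information about beta and are flagged.

Significance is a likelihood-ratio test of beta = 0 against a chi-square
with one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .datamodel import CohortMember, label_key
from .categorize import AnnotatedLog

BETA_CAP = 10.0  # |beta| beyond this is reported as a non-converged boundary fit


class DegenerateSeriesError(ValueError):
    """No person in the series carries information about beta."""


@dataclass(frozen=True)
class UserSeries:
    """One person's case series reduced to its sufficient statistics."""

    user_id: str
    n_days: int
    event_day: int
    n_risk: int
    event_in_risk: bool
    n_exposure_days: int

    @property
    def n_baseline(self) -> int:
        return self.n_days - self.n_risk

    @property
    def informative(self) -> bool:
        return self.n_risk > 0 and self.n_baseline > 0


@dataclass
class CaseSeries:
    users: list[UserSeries]
    window: int
    label: tuple[str, str] | None = None

    def informative(self) -> list[UserSeries]:
        return [u for u in self.users if u.informative]

    @property
    def n_exposed_users(self) -> int:
        return sum(1 for u in self.users if u.n_exposure_days > 0)


def risk_days_from_exposures(
    exposure_days: Iterable[int],
    n_days: int,
    window: int,
    include_exposure_day: bool = False,
) -> np.ndarray:
    """Boolean risk indicator over the observation window: the union of
    (e, e+W] after each exposure day e (or [e, e+W] when the exposure day
    itself is included), clipped to the window."""
    risk = np.zeros(n_days, dtype=bool)
    start_off = 0 if include_exposure_day else 1
    for e in exposure_days:
        lo = max(e + start_off, 0)
        hi = min(e + window + 1, n_days)
        if lo < hi:
            risk[lo:hi] = True
    return risk


def user_series_from_days(
    user_id: str,
    n_days: int,
    event_day: int,
    exposure_days: Iterable[int],
    window: int,
    include_exposure_day: bool = False,
    post_event_exposures: bool = True,
) -> UserSeries:
    """Reduce day-level data to a UserSeries.

    With ``post_event_exposures=False`` exposures on or after the event day
    are discarded (event-censored variant); the default keeps them, the
    standard SCCS choice that avoids selection bias from event-dependent
    exposure truncation.
    """
    days = sorted(set(int(e) for e in exposure_days))
    if not post_event_exposures:
        days = [e for e in days if e < event_day]
    risk = risk_days_from_exposures(days, n_days, window, include_exposure_day)
    return UserSeries(
        user_id=user_id,
        n_days=n_days,
        event_day=event_day,
        n_risk=int(risk.sum()),
        event_in_risk=bool(risk[event_day]),
        n_exposure_days=len(days),
    )


def build_case_series(
    cohort: Sequence[CohortMember],
    alog: AnnotatedLog,
    label: tuple[str, str],
    window: int = 15,
    include_exposure_day: bool = False,
    post_event_exposures: bool = True,
    label_user_days: Mapping[tuple[str, str], Mapping[str, set[int]]] | None = None,
) -> CaseSeries:
    """Case series for one (cohort, label) pair.

    Exposure days are the days each cohort member issued any query carrying
    the label. ``label_user_days`` may pass a precomputed exposure index
    (as returned by :meth:`AnnotatedLog.label_user_days`) to avoid
    re-scanning the log per label.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if label_user_days is None:
        label_user_days = alog.label_user_days()
    exposures = label_user_days.get(label_key(*label), {})
    n_days = alog.log.observation_length
    users = [
        user_series_from_days(
            m.user_id,
            n_days,
            m.event_day,
            exposures.get(m.user_id, ()),
            window,
            include_exposure_day,
            post_event_exposures,
        )
        for m in sorted(cohort, key=lambda m: m.user_id)
    ]
    return CaseSeries(users, window, label=label_key(*label))


def log_likelihood(
    series: CaseSeries, beta: float, thetas: Mapping[str, float]
) -> float:
    """Full Poisson log-likelihood at (beta, theta), up to the additive
    constant from the y! terms (zero here: y is 0/1)."""
    total = 0.0
    for u in series.users:
        theta = thetas[u.user_id]
        total += theta + beta * u.event_in_risk
        total -= math.exp(theta) * (u.n_baseline + u.n_risk * math.exp(beta))
    return total


def profile_thetas(series: CaseSeries, beta: float) -> dict[str, float]:
    """Closed-form per-person baseline maximizers given beta."""
    eb = math.exp(beta)
    return {
        u.user_id: -math.log(u.n_baseline + u.n_risk * eb) for u in series.users
    }


def _profile_arrays(series: CaseSeries):
    info = series.informative()
    n1 = np.array([u.n_risk for u in info], dtype=float)
    n0 = np.array([u.n_baseline for u in info], dtype=float)
    e = np.array([u.event_in_risk for u in info], dtype=float)
    return info, n1, n0, e


def profile_loglik(series: CaseSeries, beta: float) -> float:
    """Profile log-likelihood Lp(beta) == log_likelihood at profiled thetas.

    Uninformative persons contribute a beta-free constant, included so that
    Lp matches :func:`log_likelihood` exactly.
    """
    thetas = profile_thetas(series, beta)
    return log_likelihood(series, beta, thetas)


@dataclass
class SCCSFit:
    beta_hat: float
    se_beta: float
    log_lik: float
    log_lik_null: float
    lrt_p: float
    n_exposed_users: int
    n_informative_users: int
    converged: bool

    @property
    def relative_hazard(self) -> float:
        return math.exp(self.beta_hat)

    def wald_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta_hat - z * self.se_beta, self.beta_hat + z * self.se_beta

    def thetas(self, series: CaseSeries) -> dict[str, float]:
        """Recover the per-person baseline estimates at beta_hat."""
        return profile_thetas(series, self.beta_hat)


def _fit_from_stats(
    n1: np.ndarray, n0: np.ndarray, e: np.ndarray, n_exposed: int, n_info: int
) -> SCCSFit:
    ln1, ln0 = np.log(n1), np.log(n0)
    k = float(e.sum())

    def lp(beta: float) -> float:
        return float(
            beta * k - np.logaddexp(ln0, ln1 + beta).sum() - e.size
        )

    # boundary cases: all events in one stratum -> MLE at +-infinity
    if k == 0.0 or k == float(e.size):
        beta_hat = -BETA_CAP if k == 0.0 else BETA_CAP
        converged = False
    else:
        res = optimize.minimize(
            lambda b: -lp(b[0]),
            x0=[0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 500},
        )
        beta_hat = float(res.x[0])
        converged = bool(res.success)
        if abs(beta_hat) > BETA_CAP:
            beta_hat = math.copysign(BETA_CAP, beta_hat)
            converged = False
    ll_hat, ll_null = lp(beta_hat), lp(0.0)
    h = 1e-4
    d2 = (lp(beta_hat + h) - 2 * ll_hat + lp(beta_hat - h)) / h**2
    se = float(1.0 / math.sqrt(-d2)) if d2 < 0 else math.inf
    lrt = max(2.0 * (ll_hat - ll_null), 0.0)
    return SCCSFit(
        beta_hat=beta_hat,
        se_beta=se,
        log_lik=ll_hat,
        log_lik_null=ll_null,
        lrt_p=float(stats.chi2.sf(lrt, df=1)),
        n_exposed_users=n_exposed,
        n_informative_users=n_info,
        converged=converged,
    )


def fit(series: CaseSeries) -> SCCSFit:
    """Maximize the profile log-likelihood over beta (Nelder-Mead, start 0).

    The reported log-likelihoods include each informative person's "-1"
    profiling constant but exclude uninformative persons, whose
    contribution is beta-free; LRT and standard errors are unaffected.
    """
    info, n1, n0, e = _profile_arrays(series)
    if not info:
        raise DegenerateSeriesError(
            "no person has both risk and baseline days; beta is not identified"
        )
    return _fit_from_stats(n1, n0, e, series.n_exposed_users, len(info))


def fit_joint_oracle(series: CaseSeries, max_restarts: int = 8) -> SCCSFit:
    """Direct simplex maximization over (theta_1..theta_N, beta), without
    profiling. A test oracle for small N: slow but assumption-free about
    the profiling step. Restarts the simplex until the optimum stops
    moving."""
    users = series.users
    n = len(users)
    if n > 50:
        raise ValueError("joint oracle is intended for N <= 50")
    if not any(u.informative for u in users):
        raise DegenerateSeriesError("beta is not identified")
    n1 = np.array([u.n_risk for u in users], dtype=float)
    n0 = np.array([u.n_baseline for u in users], dtype=float)
    e = np.array([u.event_in_risk for u in users], dtype=float)

    def neg(params: np.ndarray) -> float:
        thetas, beta = params[:-1], params[-1]
        ll = np.sum(thetas + beta * e) - np.sum(
            np.exp(thetas) * (n0 + n1 * np.exp(beta))
        )
        return -ll

    x = np.concatenate([-np.log(n0 + n1), [0.0]])
    fun = neg(x)
    for _ in range(max_restarts):
        res = optimize.minimize(
            neg,
            x,
            method="Nelder-Mead",
            options={
                "xatol": 1e-9,
                "fatol": 1e-12,
                "maxiter": 4000 * (n + 1),
                "maxfev": 4000 * (n + 1),
                "adaptive": True,
            },
        )
        x = res.x
        if abs(res.fun - fun) < 1e-10:
            fun = res.fun
            break
        fun = res.fun
    beta_hat = float(x[-1])
    info_mask = (n1 > 0) & (n0 > 0)
    fit_stats = _fit_from_stats(
        n1[info_mask],
        n0[info_mask],
        e[info_mask],
        series.n_exposed_users,
        int(info_mask.sum()),
    )
    return SCCSFit(
        beta_hat=beta_hat,
        se_beta=fit_stats.se_beta,
        log_lik=float(-fun),
        log_lik_null=fit_stats.log_lik_null,
        lrt_p=fit_stats.lrt_p,
        n_exposed_users=series.n_exposed_users,
        n_informative_users=int(info_mask.sum()),
        converged=True,
    )
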
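# Methods

This note documents the statistical model, the design choices made where
the design was genuinely open, the synthetic-data generator's assumptions,
and the package's known limitations.

## The self-controlled case series model

For a cohort of N cases, each observed over a common window of D days
(default 183, about six months) with exactly one event on day d_i, we model
event occurrence as a non-homogeneous Poisson process: a per-person
baseline rate e^{theta_i}, multiplied by e^{beta} on risk days. The risk
indicator r_{i,d} is 1 on the union of windows (e, e+W] after each exposure
day e — the days the person issued any query carrying the candidate label —
clipped to the observation window. W defaults to 15 days.

Because every person contributes exactly one event, the per-person
baselines maximize in closed form at theta_i(beta) = -log(n0_i + n1_i
e^beta), where n1_i and n0_i count risk and baseline days. The resulting
profile log-likelihood

    Lp(beta) = sum_i [ beta e_i - log(n0_i + n1_i e^beta) ] + const,

with e_i the event-in-risk indicator, is concave in beta and identical in
its maximizer to the joint (N+1)-dimensional problem; we maximize it with
the Nelder–Mead simplex (start 0, tolerance 1e-8, max 500 iterations). The
joint simplex maximization is retained as `fit_joint_oracle`, a test-scale
(N ≤ 50) cross-check that the profiling step is exact. The profile
depends on the data only through (n1_i, n0_i, e_i); persons with no risk
days or no baseline days carry no information about beta and are flagged.

Significance is a likelihood-ratio test of beta = 0 against chi-square(1);
standard errors come from the numerical curvature of Lp at the maximum.
When every informative event falls in one stratum the MLE diverges; the
estimate is capped at |beta| = 10 and flagged non-converged, and such
candidates are excluded from reports rather than shown with an absurd
hazard.

Numerical notes: the per-person terms use `logaddexp`, so large e^beta
never overflows; optimizer output is invariant to person order up to
summation rounding (~1e-7 on beta).

### Risk-window conventions

* The exposure day itself is excluded — "the W days *following*" the
  query — via windows (e, e+W]. `include_exposure_day=True` switches to
  [e, e+W].
* Exposures after the event are retained by default, the standard SCCS
  choice: censoring exposure at the event makes exposure depend on outcome
  and biases the estimate. `post_event_exposures=False` provides the
  event-censored variant for sensitivity analysis.
* Candidate labels that name the target condition (or contain it, or one
  of its synonyms, as a token match) are excluded before fitting. Cases
  query their own condition heavily *after* the event, so such labels are
  tautologically associated with it — mostly as spurious "protective"
  effects, since all their risk days are post-event.

## Cohort identification

Trigger-phrase detection is token-boundary based on normalized text
(lower-cased, punctuation as token breaks), so "i have" does not match
inside "i haven't" and "hives" never matches "hiv". No negation handling
is attempted ("i don't have cancer" still matches); this is a known
limitation of the heuristic, acceptable because the incidence
rank-correlation check guards cohort make-up in aggregate rather than
per user.

For classifier-expanded members the event day is not observable. We use
the day of the user's first query mentioning their assigned condition, by
analogy with the first-self-identification convention for SIUs. **This is
a modeling choice, not an observed quantity**: if assigned users' first
condition query systematically lags or leads onset, their case series are
misaligned. The simulator plants self-identification on the true event
day, so this choice is exercised only for classifier-added members.

The scorer is a standardized logistic regression; any linear margin model
mapped to [0, 1] satisfies the downstream contract, which only uses
score-vs-threshold comparisons. Cross-validation is stratified five-fold,
seeded; training requires both label classes to have at least one member
per fold, otherwise cohort expansion is disabled and the pipeline falls
back to the SIU-only cohort (logged). Threshold tuning picks the smallest
grid threshold — the largest cohort — whose per-condition cohort fractions
still rank-correlate with reference incidence at rho >= 0.3; the sweep
reports the full (threshold, rho, cohort size) curve so the trade-off is
inspectable.

Greedy forward feature selection stops when no single addition improves
CV-AUC by more than 1e-4. On pure-noise features this rule still admits
two or three features through spurious ~0.01 CV gains; it bounds model
size, it does not certify feature relevance.

## Query generalization

A (query, page) pair enters the category map only if clicked at least
`min_monthly_clicks` (default 10) times in **every** month of the observed
span; this is the strict reading of a per-month threshold, and
`mode="mean"` offers the laxer per-month-average reading. Among surviving
pages per query the highest total click count wins, ties broken to the
lexicographically smaller page id for determinism. Every query always
carries its own literal text as an additional label of kind "query", so
the final report can distinguish broad categories from specific query
strings.

## Screening

Candidates are labels queried by at least 1% of the cohort (boundary
inclusive). The temporal filter computes, per label, the Pearson
correlation (Spearman by flag) between its daily counts in the cohort and
in a disjoint background sample (default 10x the cohort, seeded uniform
draw), and rejects labels significant under Benjamini–Hochberg at q = 0.05
across labels: a shared temporal profile indicates an external driver such
as a news event, not individual risk. Labels with constant series are kept
— an undefined correlation is no evidence of confounding. The surviving
candidates are fitted, and their LRT p-values are BH-corrected at q within
the condition; how per-candidate significance should be computed was an
open design point, and LRT-plus-BH is the standard choice for SCCS
screens.

The dose-response (gradient) check stratifies label users by days-queried
(1, 2, 3, 4+) and calls the label "positive" when Spearman rho between
stratum index and fraction-with-condition is >= .5, "negative" when
<= -.5, and "undetermined" otherwise or with fewer than three populated
strata. A literal "negative when rho < .5" rule would label weak positives
negative; the symmetric rule is a deliberate divergence, documented here.

## The synthetic generator

The generator draws each affected user's event day from the multinomial
implied by the Poisson model — day weights exp(sum_c beta_c r_{c,d}) over
the planted precursors — rather than by thinning, so the generative law
equals the fitted likelihood exactly and parameter recovery is a sharp
test. Other planted structure: condition assignment by reference incidence
(one condition per user); a trigger query on the event day for a
configurable fraction of affected users (default 1.0); own-condition query
counts Poisson(6.8) after the event versus Poisson(2.15) for background
disease queriers — the two distributional anchors adopted for these rates;
background and news-spike categories queried independently of events, the
spikes as 3-day population-wide bursts. Exposure-query timing is uniform
over the window; no guidance exists for it and uniform is neutral.

What the generator does **not** emulate: natural-language variety (each
category has three fixed text variants), comorbidity, per-user activity
windows, seasonal or weekday structure, and exposure bursts correlated
with user-level states. Passing tests therefore show the estimator and the
pipeline plumbing are correct under the stated model; they do not show the
trigger-phrase heuristic or the category map would behave as well on real
logs.

## Problem sizes used in validation

The bundled reference table (29 conditions) drives the rank-correlation
check; its Spearman rho evaluates to 0.50 under average-rank tie handling.
Estimator checks use a 100-person homogeneous design with closed-form MLE
3.5, twenty random series (N <= 50) for profile-vs-joint agreement, and
100 replicates of 2,000-person series with planted hazard 3 for recovery
and coverage. Screen calibration uses 50 replicates of a 500-user global
null (~120 null labels each); the end-to-end scenario uses 10,000 users,
five conditions, ~1,500 cases for the precursor condition with planted
hazard 4, and one news-spike confounder. These sizes keep the full
validation run to a few minutes on one CPU while leaving Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

* One event per person, fixed common observation window; Farrington-style
  age effects, multiple events, and exposure-duration dose modeling are
  out of scope.
* The SIU assumptions (self-identifiers have the condition; onset is near
  the first self-identifying query) are strong and unverifiable from logs
  alone; the incidence correlation is a population-level, not user-level,
  check.
* Temporal filtering removes shared-profile labels wholesale; a genuine
  precursor that also spikes with news coverage would be lost.
* Associations are correlational; the package orders exposure before
  event but cannot establish causation.
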
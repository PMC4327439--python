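# slapb — search-log analysis for precursor behaviors

`slapb` discovers **precursor behaviors**: query categories whose occurrence
precedes a health event with an elevated within-person event rate. It is
aimed at infodemiology / digital-epidemiology researchers who have (or can
simulate) a per-user search-query log and want case-only risk-marker
screening with proper multiple-testing control.

The pipeline has three stages:

1. **Cohort identification.** Users who self-identify a condition — a query
   combining a trigger phrase ("i have", "i suffer from", "living with",
   "i was diagnosed with") with a disease name from a medical lexicon — form
   the seed cohort (SIUs); the day of the first such query is taken as the
   event day. A linear classifier over eight features of each user's
   disease-query profile then expands the cohort with users whose most
   frequently queried disease is likely the one they have, with the
   operating threshold tuned so the cohort's per-condition make-up still
   rank-correlates with reference incidence.
2. **Query generalization.** Queries are mapped, via most-clicked
   encyclopedia page and that page's subject categories, to broad category
   labels; unmapped queries keep their literal text as a label.
3. **Screening.** For each candidate label (queried by ≥1% of the cohort),
   the relative hazard of the event in the 15 days following each label
   query is estimated with the **self-controlled case series (SCCS)**
   model; labels whose daily counts track the general population (news-type
   spikes) are rejected first, and the survivors are reported under
   Benjamini–Hochberg FDR control.

## The model

Each case *i* is observed for *D<sub>i</sub>* days and has exactly one
event. Events follow a non-homogeneous Poisson process with rate
e<sup>θ<sub>i</sub></sup> on baseline days and
e<sup>θ<sub>i</sub>+β</sup> on *risk* days — the *W* days after each
exposure (label) query, so the log-likelihood is

    L(β, θ) = Σᵢ Σ_d [ y_id (θᵢ + β r_id) − exp(θᵢ + β r_id) ]

with y the event indicator and r the risk-day indicator. Each θ<sub>i</sub>
profiles out in closed form (one event per person), leaving a concave 1-D
profile likelihood maximized by Nelder–Mead; e^β̂ is the reported
**relative hazard**, with a χ²₁ likelihood-ratio p-value against β = 0.
Because each person serves as their own control, time-invariant
confounders cancel.

A synthetic query-log generator plants ground truth (conditions, trigger
queries, precursor exposures with known e^β, news spikes) by drawing event
days from exactly this model, so every stage is testable end to end.

## Worked example

```python
from slapb import run_all, PipelineParams
from slapb.synthetic import (reference_scenario, simulate,
                             toy_lexicon, toy_category_map)

config = reference_scenario(seed=1, n_users=10_000)   # planted hazard 4
log, truth = simulate(config)
result = run_all(log, toy_lexicon(), toy_category_map(config),
                 config.incidence, PipelineParams(seed=1))
print(f"cohort: {len(result.cohort)} users "
      f"({result.counts['cohort_classified']} classifier-added), "
      f"CV AUC {result.cv_auc:.3f}, threshold {result.threshold}")
for row in result.report.rows[:4]:
    print(f"{row.condition}\t{row.precursor_label}\t{row.label_kind}"
          f"\t{row.relative_hazard:.2f}\t{row.p_value:.2g}")
```

prints

```
cohort: 3591 users (301 classifier-added), CV AUC 0.999, threshold 0.01
diabetes mellitus	sugar free recipes	category	4.29	4.6e-120
diabetes mellitus	sugar free recipes	query	3.84	3.7e-46
diabetes mellitus	sugar free recipes online	query	3.63	4.3e-42
diabetes mellitus	sugar free recipes guide	query	2.97	3.6e-28
```

The planted precursor category ("sugar free recipes", true relative hazard
4 within a 15-day window) is recovered at 4.29 from ~1,500 cases, its
individual query strings show attenuated but elevated hazards, and the
planted news-spike category ("celebrity gossip") is rejected by the
temporal filter before any hazard is estimated.

The same flow is available from the shell:

```bash
slapb simulate --config sim.yaml --out log.tsv --truth truth.tsv \
      --lexicon lex.tsv --category-map map.tsv --incidence inc.tsv
slapb run-all --config run.yaml
```

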
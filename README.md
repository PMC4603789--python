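# pcstates

A dynamic clinical-states progression model of prostate cancer in the
United States: a deterministic, tenure-structured multi-state cohort
simulator that converts published landmark survival fractions into
competing-risk hazards, flows annual diagnosed cohorts through eight
clinical states from 1990 to a projection horizon, and quantifies
per-state incidence, prevalence and all-cause mortality under baseline
and hypothetical-intervention scenarios.

## Who this is for

Epidemiologists and clinical researchers who need population-level
estimates of how many men occupy each milestone of the prostate cancer
disease continuum — from newly diagnosed localized disease through
biochemical failure, castration resistance, and metastatic
castration-resistant disease (mCRPC) — and how those numbers shift if a
novel therapy improves progression-free survival (PFS) or overall
survival (OS) in a specific state. The central question the model
answers: where in the continuum does an effective therapy buy the most?

## The model

**States.** Eight living clinical states plus absorbing death:
localized, locally advanced, rising PSA (non-castrate biochemical
failure), nmCRPC (non-metastatic castration-resistant), metastatic
non-castrate, and three mCRPC states (asymptomatic, symptomatic,
post-chemotherapy). Disease only progresses: the transition graph is
acyclic, every state can die, and progression outflow splits among
destinations by configurable routing fractions.

**Hazards.** Each state carries published 5- and 10-year OS and PFS
fractions per treatment arm (from pivotal trials and meta-analyses).
Under a piecewise-constant hazard with breakpoints at 5 and 10 years of
state tenure,

    h[0,5) = −ln S(5) / 5,   h[5,10) = −ln( S(10)/S(5) ) / 5,

and the 5–10-year rate extrapolates beyond 10 years. PFS events are a
superset of deaths, so the cause-specific split is h_death = h_OS and
h_prog = max(h_PFS − h_OS, 0). Arms blend by weight.

**Dynamics.** Annual cycles. Each (state, tenure) cell exits with
probability 1 − exp(−(h_p + h_d)), split between progression and death
in proportion to the rates; stayers age one year of tenure; progressors
land in their destination at tenure 0 and are not re-exposed until the
next year. Incident diagnoses enter localized / locally advanced /
metastatic non-castrate states with full-year exposure.

**Scenarios.** An intervention divides the progression hazard of its
target states by (1 + PFS improvement) and the death hazard by
(1 + OS improvement) from its introduction year (default semantics;
hazard × (1 − improvement) is available as an option).

An individual-level Monte-Carlo microsimulation with the identical
conventions ships alongside the engine as an independent oracle; the
engine is its exact expectation, which the test suite exploits.

## Worked example

```
python examples/02_baseline_run.py
```

prints (abridged):

```
state                      prevalence    published  mortality  published
LOCALIZED                   1,271,769    1,383,920     60,767     73,485
...
MCRPC_POSTCHEMO                19,273       23,220     10,292     16,905

total prevalence 2009: 2,281,914 (published 2,219,280); all-cause deaths: 166,084 (published 168,290)
mCRPC entry incidence 2009: 23,096, of which 85% from nmCRPC (published: 86%)
```

Each row is one clinical state in 2009: end-of-year prevalence and
deaths during the year, next to the published base-case values. The
simulated totals land close to the published ones but are not expected
to match digit-for-digit — the original model's 1990–2008 incidence
series, treatment-mix weights and nmCRPC routing split were never
published, so the default run uses documented placeholder inputs
(see `docs/methods.md`). The structural finding is reproduced: the
nmCRPC state, not the metastatic non-castrate state, dominates the
inflow into mCRPC.

The other examples recover the hazard table from the survival landmarks
(`01`), compare the three intervention scenarios and show the
dip-and-rebound of mCRPC deaths under an OS-only intervention (`03`),
and run the engine-vs-microsimulation cross-check (`04`).

A thin CLI wraps the same library calls:

```
pcstates run --start 1990 --horizon 2020 --out report.csv
pcstates scenario --scenario nmcrpc --year 2020
pcstates validate --report report.csv --tol 0.15
pcstates synth-incidence --anchors anchors.yaml --out incidence.csv
```

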
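# Methods

## Model structure

The package implements a discrete-time, tenure-structured multi-state
cohort model of diagnosed prostate cancer. The population is
partitioned into eight living clinical states plus absorbing death;
state membership is defined by primary-tumour status, detectable
metastases, prior/current treatment and testosterone level. The
transition graph is progression-only (acyclic among living states):

    LOCALIZED ──────────────► RISING_PSA_NONCASTRATE ─► NMCRPC
    LOCALLY_ADVANCED ─► {RISING_PSA_NONCASTRATE, NMCRPC}
    NMCRPC ─► {MCRPC_ASYMPTOMATIC, MCRPC_SYMPTOMATIC}
    METASTATIC_NONCASTRATE ─► {MCRPC_ASYMPTOMATIC, MCRPC_SYMPTOMATIC}
    MCRPC_ASYMPTOMATIC ─► MCRPC_SYMPTOMATIC ─► MCRPC_POSTCHEMO
    every living state ─► DEAD

An optional LOCALIZED → LOCALLY_ADVANCED edge is available through
configuration for the reading in which an active-surveillance patient's
worsening local disease re-stages him; the default omits it, keeping
localized failures on the rising-PSA route.

## Hazard recovery from landmark survival

Inputs are 5- and 10-year OS and PFS fractions per state and treatment
arm, measured from entry into the state. The survival model is
piecewise exponential with breakpoints at 5 and 10 years of tenure;
the two landmarks pin the two segment rates exactly
(h1 = −ln S(5)/5, h2 = −ln(S(10)/S(5))/5), and the 5–10-year rate is
extrapolated indefinitely — the minimal assumption given no third
landmark. Inversion is exact: the reconstructed curve reproduces both
landmarks to machine precision, which the tests assert at 1e-12 for all
32 (5-yr, 10-yr) pairs in the shipped table.

Cause-specific decomposition treats OS as the death-rate authority and
PFS as the union of progression and death: h_death = h_OS,
h_prog = max(h_PFS − h_OS, 0). The clamp matters in practice: several
states source OS and PFS from different cohorts, and the published
curves cross (e.g. the nmCRPC 10-yr PFS of 0.081 exceeds its 10-yr OS
of 0.002). A crossing yields a zero progression hazard for that segment
and a logged warning, never an error: the table is taken as printed.

Printed fractions of 0.000 (all three mCRPC PFS rows, the post-chemo
10-yr OS) cannot enter a log. They are read as "below the printed
resolution" and floored at 5e-4 — half of one unit in the third decimal
— before inversion. The floor is configurable (`survival_floor`), as is
an optional hazard cap (`max_hazard`, off by default: the nmCRPC
second-segment death rate of ~1.03/yr is kept faithful to the table
rather than smoothed).

Decomposition is applied per arm and the cause-specific rates then
blended by arm weight (decompose-then-blend). The order is visible only
through the clamp; per-arm decomposition keeps each arm a coherent
clinical pathway. Default arm weights are uniform within each state and
are explicit placeholders — the original model's registry-derived
treatment mix was not published.

Terminal living states (post-chemotherapy mCRPC) have no living
successor; their recovered progression rate would route mass nowhere,
so it is forced to zero at profile build. Their PFS events are
absorbed into within-state residence and death.

## Discrete-time dynamics

One cycle is one calendar year. A (state, tenure) cell with rates
(h_p, h_d) exits with probability 1 − exp(−(h_p + h_d)), split between
progression and death proportionally to the rates (competing
exponential clocks); stayers advance one year of tenure. Conventions,
all explicit because they are irreproducible otherwise:

- **Entry exposure.** Incident diagnoses enter at tenure 0 on January 1
  and face the full year's risk. A half-cycle option
  (`entry_exposure="half"`) exposes entrants for half a year.
- **No same-year cascades.** Progressors land in their destination at
  tenure 0 and are not re-exposed there until the next year; annual
  accounting cannot represent multi-hop transitions within a year.
- **Tenure cap.** Tenure is capped at 30 years; capped cells keep the
  10+ segment hazard (which is constant anyway). With a 1990 start and
  a 2020 horizon nothing reaches the cap before the final year.
- **Real-valued occupancy.** The ledger holds fractional persons;
  reports can be rounded to the nearest 5 for display, matching the
  published tables' printing convention.

Deaths inside PFS are handled once, in the decomposition; the engine
never subtracts them again. Conservation — occupancy plus cumulative
deaths equals cumulative injected incidence — is asserted after every
step at 1e-6 relative; observed residuals are ~1e-16.

## Incidence inputs

The simulation is driven by diagnosed counts per year in three stages
(localized / locally advanced / metastatic), from 1990. The original
model's registry-based 1990–2008 series is not published, so the
shipped default is explicitly non-authoritative: it interpolates
linearly from a chosen 1990 level to the published 2009 stage counts
(194,765 / 27,555 / 9,790), then grows each stage geometrically so the
2020 projection hits the published values (259,715 / 37,310 / 13,575)
exactly. The 1990 level is 170,000 total with the 2009 stage split
(~84/12/4 → 142,800 / 20,400 / 6,800), a realistic early-PSA-era order
of magnitude; it is a one-time modelling choice, stated here and in the
config, not a fitted quantity. Pre-1990 prevalent cases are excluded,
matching the original model's design.

Users can substitute any series via CSV; a synthetic generator
interpolates (linearly or geometrically) between arbitrary anchors with
optional seeded lognormal noise, and is seed-deterministic and
scale-equivariant.

The geometric-growth projection hits its endpoint anchors exactly but
will not reproduce intermediate years of a rate-times-population
projection; it is a surrogate for, not a reconstruction of, the
original forward model.

## Routing

Progression outflow splits by per-source fractions. Two splits are
unpublished and shipped as documented placeholders:

- nmCRPC (and metastatic non-castrate) progressors split 0.50/0.50
  between asymptomatic and symptomatic mCRPC. The original split was
  derived from an external chemotherapy-sequencing cohort whose number
  was not printed; no value here is presented as the published one.
- Locally advanced progressors route to nmCRPC in proportion to the
  weight share of treatment arms containing hormonal therapy (castrate
  relapse) and to rising PSA otherwise — 0.5 under uniform weights,
  recomputed automatically if weights change.

## Scenarios

An intervention is (target states, PFS improvement, OS improvement,
introduction year). The default semantics read "25% improvement" as a
25% extension of expected event-free time: hazard ÷ 1.25. The
alternative reading, hazard × 0.75, is selectable
(`semantics="hazard_scale"`). The intervention applies to everyone in a
target state from the introduction year (drug availability); a
restricted mode (`scenario_scope="new_entrants"`) covers only patients
who entered the state after introduction, identified by tenure. The
combined scenario composes the nmCRPC-PFS and mCRPC-OS interventions.

## Verification strategy

- **Closed forms.** Single-risk runs reproduce exponential decay to
  1e-9 over 20 years; two-state chains reproduce 1 − exp(−ht) transfer.
- **Microsimulation oracle.** An individual-level Monte-Carlo
  simulation with identical conventions is implemented independently of
  the ledger arithmetic. The engine is its exact expectation, so each
  (state, year) occupancy count is Binomial(n, p) around the engine's
  prediction. The full-scale check uses n = 100,000 over all ~248
  cells; because ~250 simultaneous 3-SE comparisons produce occasional
  benign excursions by chance alone, the assertion allows at most two
  cells beyond 3 SE and requires any such cell to pass an exact
  binomial test at the Bonferroni-corrected 3-sigma family level. A
  genuine implementation divergence at this n still fails.
- **Fixture arithmetic.** The published per-state and scenario tables
  are shipped as source-tagged fixtures; the reporting layer reproduces
  every printed aggregate and delta from them exactly (total prevalence
  2,219,280 in 2009 and 3,072,480 in 2020; the 2,121,650 / 97,630
  non-metastatic/metastatic split; 168,290 deaths with a 20.5% mCRPC
  share; scenario deltas 5,061 / 2,032 / 13,922 / 13,448).
- **Structural echo.** Under default routing the nmCRPC state feeds the
  majority of mCRPC entry inflow in every settled year (85% in 2009 in
  the default run, vs the published 86%); the exact percentage depends
  on the unpublished routing/weights and is deliberately not asserted.

What passing these tests shows: the hazard recovery, bookkeeping and
scenario machinery are internally exact and mutually consistent. What
they do not show: agreement with the original model's headline totals,
which depend on its unpublished inputs. The shipped
`validate` operation compares a simulated run against the published
table at a default 15% tolerance as a diagnostic, not a test.

## Problem sizes

The default run is 31 years × 8 states × 31 tenure cells; the full
oracle comparison uses 100,000 individuals; the Monte-Carlo check of
the annual discretization uses 10^6 exponential-clock draws. The entire
suite and the acceptance script each complete in well under a minute.

## Known limitations

- All-cause mortality only; prostate-cancer-specific deaths are not
  attributed (the published discussion's attribution argument is out of
  scope).
- No age structure, patient-level covariates, parametric survival fits,
  cost/utility outcomes, or probabilistic sensitivity analysis.
- The within-year event order of the original implementation is
  unknown; the conventions above are this package's own, stated rather
  than calibrated, and plausibly shift outputs by a few percent.
- The published 2020 localized-state mortality cell (10,915) is
  inconsistent with the quoted 2020 total of 219,360 (the printed
  column sums to 122,360). The fixture transcribes the cell as printed
  and flags the discrepancy; no correction is guessed. Likewise the
  published 2009 mCRPC incidence (36,100) counts first entry into the
  mCRPC group, not the sum of the three per-state inflow rows (which
  include inter-mCRPC moves); this package exposes both quantities
  (`mcrpc_entry_incidence` vs per-state `incidence`).
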
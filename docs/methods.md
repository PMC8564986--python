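# Methods

This document describes the model implemented by `screencea`, the
assumptions it makes where the underlying study design admits more than
one reading, and the numerical choices behind the sensitivity analyses
and the validation oracle.

## Model structure

### Cohort and cycles

A closed cohort of `cohort_size` women (default 100,000) in one age band
(40–49 or 50–59) is followed for `horizon_cycles` annual cycles (default
10). The cohort engine is an expected-value (deterministic) simulation:
women are fractional, and every quantity is an expectation over the
implied individual-level stochastic process. The matching individual-level
microsimulation (below) samples that same process.

### Decision tree (per cycle)

In the screened arm, each cycle the at-risk pool is screened once.
With annual incidence *p*, sensitivity *Se* and specificity *Sp*:

- true positives = at_risk × p × Se (screen-detected cancers),
- false negatives = at_risk × p × (1 − Se), assumed to surface
  clinically within the same cycle (clinically detected),
- false positives = at_risk × (1 − p) × (1 − Sp),
- true negatives are the remainder.

In the non-screened arm all incident cancers (at_risk × p) are
clinically detected. Screen-detected cancers draw their stage at
diagnosis (I–IV) from the screened-arm distribution, clinically detected
ones from the less favourable clinical distribution — the *stage shift*
is the only mechanism by which screening changes health outcomes.

By default the at-risk pool is depleted by cumulative diagnoses
(`deplete_at_risk_pool: true`); diagnosed women are not re-screened.

### Markov chain

Each diagnosed cohort (by stage and entry cycle) advances through five
states: remission, local recurrence, distant recurrence, cancer death,
other-cause death. Transition matrices are stage-group specific (I,
II/III, IV) and age-band specific; stages II and III share rates but are
tracked separately because their treatment costs differ. Stage IV enters
the chain directly in distant recurrence; all other stages enter in
remission. The chain is progression-only (no return to remission), the
death states are absorbing, and every matrix is validated to be
row-stochastic with non-negative entries. Other-cause mortality is a
scenario input applied additively to all alive states; the packaged
baseline sets it to 0 (the source study tracks cause-specific deaths
only).

### Costs

Per cycle, the screened arm accrues:

- screening: number screened × mammography unit price (4.5 USD at the
  government tariff, 42 USD private),
- doctor visits: 6 USD, attached per screen by default
  (`doctor_visit_attachment: per_screen`; `per_positive` is available),
- diagnostic confirmation (FNAC, 22 USD): every true positive, plus
  every false positive when `include_false_positive_workup: true`
  (default) — whether the source totals charged FNAC for false positives
  is not recoverable from the published text, hence the flag,
- treatment: one-off stage-specific cost at diagnosis (I: 160, II:
  458.48, III: 850.45, IV: 668.70 USD).

The non-screened arm accrues a doctor visit plus FNAC per clinically
detected cancer, and the same treatment costs. Costs are discounted at
5%/year and effects at 3%/year, with payments at the beginning of each
cycle (`discount_timing: begin_of_cycle`; first cycle undiscounted). No
half-cycle correction is applied.

### Outcomes

Deaths averted = cumulative cancer deaths (non-screened) − cumulative
cancer deaths (screened) over the horizon. Life-years gained supports
two modes:

- `calibrated_multiplier` (default): LYG = deaths averted × a fixed
  discounted life-expectancy multiplier per death averted (31.3958 years
  at 40–49, 23.9051 at 50–59). The multipliers reproduce the source
  study's LYG-to-deaths-averted ratios exactly and already embody its
  effect discounting, so the effect discount rate has no further impact
  in this mode.
- `life_table`: LYG = deaths averted × the discounted annuity
  Σ_t min(1, L−t)/(1+r)^t over the mean remaining life expectancy L of
  the band, discounted at the effect rate. The packaged baseline carries
  remaining-life-years values only for the 40–49 band (36.10 years at
  40–44, 31.72 at 45–49); requesting life-table mode for 50–59 raises an
  error rather than inventing a value.

Metrics: ICER = ΔC/ΔE with dominance flags for the non-ratio quadrants
("dominant", "dominated", "undefined"); INMB = λ·ΔE − ΔC; cost per death
averted; number screened per death averted = cohort size / deaths
averted. The verdict uses strict inequality (ICER < λ ⇒ cost-effective);
λ defaults to 2808.5 USD/LYG (three times GDP per capita).

### Provider-mix policies

A policy is the share of screens delivered at the private price. The
mammography price enters costs only — never detection, transitions or
outcomes — so an intermediate share is evaluated by blending the
incremental costs of the two pure-price runs linearly; this is
algebraically identical to re-running the pipeline with a blended unit
price, and the blend's LYG and deaths averted are those of either pure
run (asserted to agree). ICER and INMB are therefore affine in the
private share, a property the test suite checks.

## One-way sensitivity analysis (tornado)

Each registered scalar parameter is moved one at a time to ±20% of its
base value (probabilities capped at 1; discount rates swept over the
fixed range 0–6%) with everything else held at base, and the ICER is
recomputed; entries are sorted by span = |ICER_high − ICER_low|.

Stage-at-diagnosis distributions are excluded from the registry:
perturbing one simplex coordinate forces a renormalisation of the other
three, which is no longer a one-way move. They are varied jointly in the
PSA instead.

Structural zero spans are expected and meaningful: at a pure government
policy the private price has no causal path to the ICER, and in
calibrated-multiplier mode neither does the effect discount rate.

## Probabilistic sensitivity analysis

Second-order Monte Carlo. Families, parameterised by method of moments
around the base value with a common coefficient of variation (default
0.1):

- **Beta** for probabilities (incidence, sensitivity, specificity,
  transition rates): mean = base, variance = (cv·mean)²; when the moment
  match is infeasible for an extreme mean the variance is clamped to
  0.99·m(1−m).
- **Gamma** for treatment costs and the life-expectancy multiplier:
  shape = 1/cv², scale = mean·cv².
- **Dirichlet** jointly for each stage distribution, over its positive
  entries, with total concentration derived from the CV as 1/cv² − 1
  (≈99 at the default cv; this matches the component-wise dispersion of
  the Beta draws and degenerates correctly as cv → 0, so a vanishing CV
  collapses the PSA onto the deterministic result). An explicit
  concentration can override the derivation.
- **Fixed** for unit prices (mammography, doctor visit, FNAC) and
  discount rates, which the analysis treats as administered quantities
  rather than sampling uncertainty.

Draws are reproducible and order-independent: draw *i*, attempt *a*
seeds its generator with `[seed, i, a]`. A draw that produces an invalid
scenario (e.g. a transition row summing past 1) is rejected and redrawn,
up to `max_redraws` attempts; redraws are counted in the summary. The
summary reports mean, SEM, SD and 2.5/50/97.5 percentiles for
incremental cost, LYG, ICER and INMB, plus P(cost-effective) = P(INMB >
0), evaluable at any willingness-to-pay from the stored draws.

## Synthetic scenarios and the microsimulation oracle

`ScenarioSampler` produces random valid scenarios by scaling every
baseline quantity with independent uniform factors (default range
0.5–1.5), clipping probabilities to [0, 1], renormalising stage
distributions, and rejecting/redrawing the rare draw that still violates
a joint constraint. Collapsing the range to (1, 1) recovers the baseline
exactly. The generator's defaults emulate the magnitude and correlation
structure of plausible low-income screening settings; it does not vary
structural flags (timing conventions, attachment rules) or the horizon.

`microsim_cohort` simulates *n* individual women through the identical
decision tree and Markov chain with vectorised numpy sampling; cycle *t*
uses a generator seeded with `[seed, t]`, so results are independent of
evaluation order. It serves as a statistical oracle: `oracle_z_scores`
compares microsimulation counts (diagnoses, final-cycle state
occupancies, cancer deaths) with the cohort engine's expectations using
binomial standard errors computed **under the null** — i.e. from the
cohort engine's expected proportion, not the empirical one. Empirical
standard errors systematically understate the dispersion of rare-event
counts and produce spurious rejections precisely in the cells where
expected counts are small; the null SE makes z = (observed −
expected)/SE(expected) correctly sized there. Costs, which are sums of
heterogeneous per-woman amounts rather than counts, use the empirical
standard error. Structurally empty cells (expectation 0) must be empty
in the microsimulation; a nonzero count there maps to an infinite z.

Validation scale: 20 random scenarios at 20,000 individuals each, with
agreement required within 3 Monte Carlo standard errors — sizes chosen
to keep the check under a few seconds while leaving the 3-SE test
sensitive to percent-level disagreements in the main aggregates.

## Toy fixture

`toy_fixture()` is a hand-enumerable two-cycle scenario (cohort 100,
incidence 0.1, Se 0.5, Sp 1, all cancers stage I, remission→distant 0.5,
distant→death 1, zero costs, zero discounts, unit LYG multiplier) whose
expected detections, deaths and metrics have exact closed forms; the
test suite asserts the cohort engine reproduces them to machine
precision.

## Validation and known deviations

The package's own headline numbers are recomputed by
`scripts/acceptance.py` and asserted by the test suite. Two points merit
attention when comparing against the source study's printed totals:

- The source under-specifies several accounting rules (other-cause
  mortality, discount timing, false-positive work-up costing, the
  life-table LYG computation). Under this package's explicit defaults
  the government-policy incremental cost at 40–49 computes to ≈10.78M
  USD versus the printed 8.66M (within ±25%); the printed value is
  closer to a screening-only cost reading.
- Under the same defaults the tornado ranks specificity, incidence and
  sensitivity above the mammography unit price at the government policy:
  charging FNAC for false positives makes specificity a first-order cost
  driver, and at the 4.5 USD government tariff the price lever is small.
  The corresponding acceptance test asserts the source's stated ranking
  (mammography cost and sensitivity both top-3) and is expected to fail
  on the mammography clause; it is deliberately left intact rather than
  weakened.
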
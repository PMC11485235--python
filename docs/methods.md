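# Methods

## Model and estimation

The package implements a discrete-time, age-inhomogeneous illness-death
(semi-competing-risks) Markov model over the ordered state space
S = (healthy, ill, dead).  "Ill" means a chosen condition pair is
jointly present, irrespective of other conditions; death is absorbing
and remission is disallowed.  Assumptions worth stating explicitly:

* **Markov in age:** transition probabilities depend only on the current
  state and integer age (completed years), not on duration of illness.
* **Discrete months, yearly model:** rates are observed monthly and the
  cohort model runs yearly; conversion is exact under the model via the
  matrix power T_y = T_m^12, computed by 12 successive multiplications
  (exact and cheap at 3×3; no eigendecomposition).
* **Age attribution:** a transition between consecutive months is
  attributed to the age attained at the *first* month of the pair.  Data
  observed over a 12-month window with ages incrementing every 12 months
  make this unambiguous for most persons; for longer windows it is a
  documented convention.
* **Missing data fallback:** an origin state with no observations at an
  age keeps its occupants ("remain in the same state", an identity row),
  flagged per (age, state) in `data_present`.  At high ages this implies
  an immortal ill state if ill data run out; the age cap at 100 bounds
  the resulting bias and the condition is visible in the flags.  It is
  documented, not corrected.
* **Eligibility:** each of the three transition types must have ≥ 1,000
  observations summed over ages; otherwise the pair is refused (the
  report lists the failing types) unless explicitly overridden.
* **Remission observations** are excluded from the counts and surfaced
  as a per-age report; fitting refuses such panels by default because
  the model form cannot represent them.

## Metrics

With yearly matrices in hand, a birth cohort starting (1, 0, 0) at age 0
is advanced one age at a time; the inflow into illness at age a is
P_healthy(a)·P[healthy→ill at a], recorded before each advance.  Note
the yearly inflow is the probability of being *ill at age a+1* given
healthy at a — someone who acquires the pair and dies within the same
year contributes to healthy→dead instead.  That is a property of the
yearly model itself, shared by the estimator, the analytic ground truth
and the microsimulation, so all routes estimate the same quantity.

* **Remaining-years convention.**  Expected remaining years at age a
  count the year of age a as lived (survival 1 at entry, multiplied by
  (1 − q(x)) per subsequent year, truncated at 100; no half-cycle
  correction).  A yearly death probability of 1 everywhere therefore
  gives exactly 1.0.  The identical convention is applied to the
  ill-state and comparator curves, so their difference Y_LL(a) is
  insensitive to the convention to first order.
* **Comparator.**  The two-state alive–dead model pools death
  transitions from both alive states of the same count tensor (monthly
  q(a) = pooled deaths / pooled at-risk person-months, annualized as
  1 − (1 − q)^12), rather than using an external life table: the
  comparator then represents the same observed population, with and
  without the conditions.
* **Median onset.**  The integer argmin of |tail share − ½| with ties
  broken to the lower age, with candidate ages restricted to the
  support range of the inflow (first to last age with positive inflow).
  The restriction matters only in degenerate cases: a point-mass inflow
  ties every age at deviation ½ and would otherwise resolve to age 0;
  within the support it resolves to the mass point, which is the only
  epidemiologically sensible answer.  For smooth everywhere-positive
  inflow the restriction is inert.
* **Age at death** is reported as a_median + Y_LW — the composition of
  the two displayed metrics; no separate estimator is introduced.
* **Zero lifetime risk** makes every onset-conditional metric undefined;
  the functions raise a dedicated `NotComputableError` and the assembled
  metrics carry NaN (never silently 0).

## Synthetic cohort generator

The generator emulates a registry-style panel: monthly snapshots over an
observation window for a cohort with configurable entry-age mix.  Three
monthly hazards (illness onset, mortality while healthy, mortality while
ill), each a function of age on [0, 100] with values validated into
[0, 1], drive a per-person chain.  Within a month, death is sampled
first with the state-appropriate hazard; a surviving healthy person may
then acquire the illness — a person never becomes ill and dies in the
same month, a convention forced by the fact that monthly snapshots could
not observe both.  All draws come from one root-seeded stream with
person *i* consuming row *i* of each block of uniforms, so panels are
byte-identical across runs and independent of iteration order.

Defaults used as the study conditions for recovery experiments (chosen
once, on realism grounds): Gompertz-type hazards min(1, b·e^{θa}) with
illness b = 5·10⁻⁵, θ = 0.06 per year; healthy mortality b = 5·10⁻⁶,
θ = 0.095; ill mortality 2.5× the healthy baseline; all hazards zero
below age 20 to mimic an adult-only registry (the estimation pipeline's
missing-age fallback then covers childhood ages).  These give a
lifetime risk ≈ 0.51, median onset 60, Y_LW ≈ 14.0 y and Y_LL ≈ 3.4 y —
magnitudes typical of a common condition pair.  Cohorts enter uniformly
over ages 20–100 with 12 monthly snapshots; n = 500,000 for recovery
runs, sized so that every adult age has tens of thousands of at-risk
person-months while the full pipeline runs in seconds.

Entry states are healthy by default; an optional per-age initial-illness
probability admits prevalent cases.  For recovery experiments this is
set to the birth-cohort equilibrium prevalence P(ill | alive, a), so the
panel's age-specific healthy/ill mix — and hence the pooled comparator —
converges to the analytic ground truth's.  What the generator does *not*
emulate: mid-window registration and deregistration (every person has
complete follow-up; the registry treatment of censoring is unknown),
birth-cohort effects, duration dependence, seasonality, or measurement
error in condition coding.  Passing recovery tests therefore shows the
estimator is consistent under the model's own assumptions, not that
those assumptions hold in any real registry.

## Ground truth and oracles

`analytic_metrics` propagates the exact monthly matrices implied by the
hazards (no sampling, no estimation) through the same metric
definitions, with the comparator taken as the person-month-weighted
pooled mortality of the birth cohort.  The microsimulation oracle
path-samples onset along the full three-state yearly chain and then
re-simulates ill-state survival from the onset age under the ill row —
the exact convention of the deterministic per-age expectation — so both
routes share an estimand and differ only by Monte-Carlo noise.  The
reported SE for the integer median-onset estimate converts the tail-share
binomial SE via the local onset density; agreement is asserted within
3 SE floored at 1 year, the resolution of an integer estimator.

## Numerical choices

* Row normalisation uses exact count ratios, so estimated rows sum to 1
  to machine precision; annualization preserves stochasticity to ~1e-15
  and tests assert 1e-10.
* The dead row and the ill→healthy entry are structural (exact 0/1
  floats), and remain exact under matrix powers.
* Annualization rejects non-stochastic monthly rows (tolerance 1e-9 on
  the row sum), naming the age and row.
* Eligibility threshold default 1,000 per transition type; age cap 100
  (101 integer bins).  Both are parameters of the estimator.
* Per-cell convergence checks in the tests compare ~500 binomial cells
  at 3 SE; since the maximum of that many z-scores exceeds 3 by chance,
  the suite asserts ≥ 99% coverage at 3 SE and a hard 5-SE cap instead
  of a per-cell maximum.

## Prevalence analytics

Point prevalence is a plain proportion over an optional age/sex stratum
(empty strata raise, never return 0).  Observed-minus-expected excess
for a pair is joint prevalence minus the product of the marginals,
computed crude by default (stratified variants are available by passing
a stratum filter); the expected-by-chance reference assumes no
association, so the excess is descriptive, not a test statistic.
Condition-count distributions report, per age band (default 5-year bands
20–24 … 85+), sex and index-condition status, the proportion with ≥ k
conditions (k = 1..6, the last meaning six or more); the index group's
count includes the index condition itself, while the comparator group is
restricted to persons without it who have at least one of the other
conditions.  Presentation rounding of percentages is one decimal, half
away from zero.

## Known limitations

* No interval-censoring correction: a monthly snapshot design cannot see
  within-month sequences, and the within-month event order (death before
  onset) is a convention.
* No smoothing across ages; sparse ages fall back to identity rows
  rather than borrowing strength.
* No confidence intervals on the burden metrics (no bootstrap); the
  microsimulation SEs quantify Monte-Carlo error of the oracle, not
  sampling error of the estimates.
* Y_LW/Y_LL are expectation-weighted means; median-based variants of the
  per-age survival summaries are a possible extension.
* The comparator pools all alive person-months; a comparator restricted
  to, say, persons with other conditions only is not implemented.
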
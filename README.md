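# mltcburden

Quantifying the burden of multiple long-term conditions (MLTCs) with a
three-state illness-death Markov model estimated from person-month panel
data, plus the cross-sectional prevalence analytics that accompany such
analyses, and a synthetic cohort generator with exact analytic ground
truth for validating the whole pipeline.

## Who this is for

Epidemiologists and health-service analysts who observe monthly health
snapshots for a population (per-person condition flags and vital status)
and want time-based burden metrics for a condition pair — e.g. diabetes
together with one comorbid condition — rather than prevalence counts
alone: how likely is a person to ever acquire the pair, at what age,
how many years do they live with it, and how many years of life does it
cost them, individually and per 1,000 population.

## The model

States are healthy (the pair is not jointly present), ill (both
conditions present, irrespective of others) and dead; death is absorbing
and remission (ill → healthy) is not permitted.  From monthly
observations, moves from state *i* to *j* at age *a* are tallied as
*n*<sub>i,j,a</sub> and normalised into monthly transition matrices

> P<sub>i,j,a</sub> = n<sub>i,j,a</sub> / Σ<sub>k∈S</sub> n<sub>i,k,a</sub>,

with an identity-row fallback where an origin state has no data at an
age (individuals are assumed to remain in that state).  Monthly matrices
are annualized by matrix power, T<sub>y</sub> = T<sub>m</sub><sup>12</sup>,
and a birth cohort is propagated through ages 0–100.  The per-age inflow
into illness, P<sub>healthy→ill</sub>(a) = P<sub>healthy</sub>(a) ·
P<sub>healthy,ill,a</sub>, yields

* **lifetime risk** L<sub>r</sub> = Σ<sub>a=0</sub><sup>100</sup> P<sub>healthy→ill</sub>(a),
* **years lived with** the pair, Y<sub>LW</sub>: the inflow-weighted mean over
  onset ages of the expected remaining years in the ill state,
* **years of life lost**, Y<sub>LL</sub>: the same weighting applied to the gap
  between a two-state alive–dead comparator (deaths pooled over both
  alive states of the same data) and the ill-state survival,
* **median onset age** a<sub>median</sub>: the integer α minimising
  |Σ<sub>a=α</sub><sup>100</sup> P<sub>healthy→ill</sub>(a)/L<sub>r</sub> − ½|,
* **age at death** = a<sub>median</sub> + Y<sub>LW</sub>, and
* **community burden** per 1,000 population,
  C<sub>YLW</sub> = 1000 · Y<sub>LW</sub> · L<sub>r</sub> and
  C<sub>YLL</sub> = 1000 · Y<sub>LL</sub> · L<sub>r</sub>.

A condition pair is eligible only when each transition type
(healthy→ill, healthy→dead, ill→dead) has at least 1,000 observations.

The prevalence side computes point prevalence, joint prevalence of a
condition pair with its observed-minus-expected excess over the
independence expectation (expected = product of the marginals), and the
distribution of condition counts by age band, sex and index-condition
status.

## Worked example

```python
from mltcburden import (HazardSpec, CohortConfig, IllnessDeathModel,
                        analytic_metrics, equilibrium_ill_prevalence,
                        generate_panel)

# Gompertz-type monthly hazards, zero below age 20, 2.5x mortality when ill
hz = HazardSpec.from_gompertz(5e-5, 0.06, 5e-6, 0.095,
                              excess_mortality=2.5, adult_min_age=20)
cfg = CohortConfig.uniform_ages(500_000, 20, 100, random_seed=123,
                                initial_ill_prob=equilibrium_ill_prevalence(hz))
panel = generate_panel(cfg, hz)          # 6M person-month rows
model = IllnessDeathModel().fit(panel)
print(model.summary().round(3))
truth = analytic_metrics(hz)             # exact ground truth
print({k: round(v, 3) for k, v in truth.as_dict().items()})
```

This prints (estimates first, then the analytic truth):

```
L_r                0.517
a_median          60.000
Y_LW              14.117
Y_LL               3.269
age_at_death      74.117
C_YLW           7294.791
C_YLL           1689.508
dtype: float64
{'L_r': 0.511, 'a_median': 60.0, 'Y_LW': 13.96, 'Y_LL': 3.385,
 'age_at_death': 73.96, 'C_YLW': 7135.031, 'C_YLL': 1730.065}
```

Read: a person in this synthetic population has a 51% lifetime risk of
acquiring the condition pair, typically at age 60; once acquired they
live about 14 years with it and lose about 3.4 years relative to the
pooled general population, amounting to roughly 7,100 years lived with
and 1,700 years lost per 1,000 population.  The estimates recover the
truth to within sampling noise at n = 500,000.

A command-line layer wraps the same pipeline:

```sh
mltc-burden simulate --seed 1 --n-persons 100000 --out runs/sim
mltc-burden burden --panel runs/sim/panel.csv --out runs/burden
mltc-burden prevalence --snapshot runs/sim/snapshot.csv --out runs/prev
```

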
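"""Synthetic cohort generation with analytic ground truth.

Emulates a registry-style person-month panel: monthly snapshots of
health state (healthy / ill / dead) for a cohort observed over a fixed
window, with age-dependent illness incidence, age-dependent mortality
that is elevated in the illness state, absorbing death and no remission.
Because the generating hazards are known, the burden metrics can also be
computed exactly by deterministic propagation (:func:`analytic_metrics`),
giving an independent ground truth for parameter-recovery tests of the
estimation pipeline.

Discrete-time convention: within a month, death is sampled first using
the mortality hazard of the current state; a survivor who is healthy may
then acquire the illness.  A person therefore never becomes ill and dies
in the same month — monthly snapshots could not distinguish that path
anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .states import HEALTHY, ILL, DEAD, STATE_LABELS

MAX_AGE = 100

HazardFn = Callable[[np.ndarray], np.ndarray]


def constant_hazard(p: float) -> HazardFn:
    """Age-constant monthly hazard."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"constant hazard {p} outside [0, 1]")
    return lambda age: np.full_like(np.asarray(age, dtype=float), p)


def gompertz_hazard(baseline: float, slope: float) -> HazardFn:
    """Gompertz-type monthly hazard min(1, b * exp(theta * age)).

    Parameters
    ----------
    baseline : float
        Hazard at age 0 (per month), b >= 0.
    slope : float
        Log-linear age slope theta (per year of age).
    """
    if baseline < 0:
        raise ValueError(f"Gompertz baseline must be >= 0, got {baseline}")
    return lambda age: np.minimum(1.0, baseline * np.exp(slope * np.asarray(age, dtype=float)))


def adult_onset(fn: HazardFn, min_age: int = 20) -> HazardFn:
    """Zero the hazard below ``min_age``, mimicking an adult-only registry."""
    def wrapped(age):
        age = np.asarray(age, dtype=float)
        return np.where(age >= min_age, _eval(fn, age), 0.0)
    return wrapped


def _eval(fn: HazardFn, ages) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    try:
        out = np.asarray(fn(ages), dtype=float)
        if out.shape != ages.shape:
            raise TypeError
    except (TypeError, ValueError):
        out = np.array([float(fn(float(a))) for a in np.atleast_1d(ages)])
        out = out.reshape(ages.shape)
    return out


@dataclass(frozen=True)
class HazardSpec:
    """Monthly hazards of the generating process, as functions of age in years.

    All three hazards are probabilities per month and must lie in [0, 1]
    for every age in [0, 100]; this is checked at construction.
    """

    monthly_illness_hazard: HazardFn
    monthly_mortality_healthy: HazardFn
    monthly_mortality_ill: HazardFn
    parameterization: str = "custom"

    def __post_init__(self):
        ages = np.arange(MAX_AGE + 1, dtype=float)
        for name in ("monthly_illness_hazard", "monthly_mortality_healthy",
                     "monthly_mortality_ill"):
            vals = _eval(getattr(self, name), ages)
            if not np.all((vals >= 0.0) & (vals <= 1.0)):
                bad = int(ages[np.argmax((vals < 0) | (vals > 1))])
                raise ValueError(
                    f"{name} outside [0, 1] at age {bad} "
                    f"(value {vals[bad]:.6g})"
                )

    @classmethod
    def from_gompertz(cls, illness_baseline: float, illness_slope: float,
                      mortality_baseline: float, mortality_slope: float,
                      excess_mortality: float = 1.0,
                      adult_min_age: int | None = None) -> "HazardSpec":
        """Gompertz-type hazards with a proportional excess mortality in illness.

        ``excess_mortality`` multiplies the healthy mortality baseline for
        the ill state (>= 1 guarantees mortality_ill >= mortality_healthy
        at every age).  ``adult_min_age`` zeroes all hazards below that
        age, mimicking a registry restricted to adults.
        """
        if excess_mortality < 0:
            raise ValueError("excess_mortality must be >= 0")
        ill = gompertz_hazard(illness_baseline, illness_slope)
        mort_h = gompertz_hazard(mortality_baseline, mortality_slope)
        mort_i = gompertz_hazard(mortality_baseline * excess_mortality,
                                 mortality_slope)
        if adult_min_age is not None:
            ill = adult_onset(ill, adult_min_age)
            mort_h = adult_onset(mort_h, adult_min_age)
            mort_i = adult_onset(mort_i, adult_min_age)
        return cls(ill, mort_h, mort_i, parameterization="gompertz")

    def tables(self, age_cap: int = MAX_AGE):
        """Hazards tabulated at integer ages 0..age_cap.

        Returns (illness, mortality_healthy, mortality_ill) arrays.
        """
        ages = np.arange(age_cap + 1, dtype=float)
        return (_eval(self.monthly_illness_hazard, ages),
                _eval(self.monthly_mortality_healthy, ages),
                _eval(self.monthly_mortality_ill, ages))

    def monthly_matrices(self, age_cap: int = MAX_AGE) -> np.ndarray:
        """Exact per-age monthly transition matrices implied by the hazards.

        Death is applied first, then illness onset among healthy
        survivors, matching the generator's within-month ordering.
        """
        pi, qh, qi = self.tables(age_cap)
        m = np.zeros((age_cap + 1, 3, 3))
        m[:, HEALTHY, DEAD] = qh
        m[:, HEALTHY, ILL] = (1 - qh) * pi
        m[:, HEALTHY, HEALTHY] = (1 - qh) * (1 - pi)
        m[:, ILL, DEAD] = qi
        m[:, ILL, ILL] = 1 - qi
        m[:, DEAD, DEAD] = 1.0
        return m


@dataclass(frozen=True)
class CohortConfig:
    """Size, entry-age mix and observation window of a synthetic cohort.

    ``start_age_distribution`` maps integer age (0..100) to the
    probability of a person entering observation at that age; it must
    sum to 1.  ``initial_ill_prob`` optionally gives, per entry age, the
    probability of entering already in the illness state (prevalent
    cases); by default everyone enters healthy.
    """

    n_persons: int
    start_age_distribution: Mapping[int, float]
    observation_months: int = 12
    random_seed: int = 0
    initial_ill_prob: Mapping[int, float] | None = None
    with_sex: bool = True

    def __post_init__(self):
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        if self.observation_months < 1:
            raise ValueError("observation_months must be >= 1")
        ages = np.array(sorted(self.start_age_distribution), dtype=int)
        probs = np.array([self.start_age_distribution[int(a)] for a in ages])
        if len(ages) == 0:
            raise ValueError("start_age_distribution is empty")
        if ages.min() < 0 or ages.max() > MAX_AGE:
            raise ValueError("start ages must lie in [0, 100]")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("start_age_distribution must be a probability "
                             f"distribution summing to 1 (sum {probs.sum():.6g})")

    @classmethod
    def uniform_ages(cls, n_persons: int, age_min: int = 20, age_max: int = 100,
                     **kwargs) -> "CohortConfig":
        ages = range(age_min, age_max + 1)
        p = 1.0 / len(ages)
        return cls(n_persons, {a: p for a in ages}, **kwargs)


def generate_panel(config: CohortConfig, hazards: HazardSpec) -> pd.DataFrame:
    """Simulate a person-month panel under the given hazards.

    Returns a DataFrame with columns ``person_id``, ``month_index``,
    ``age_years`` (completed years at month start), ``state`` (literal
    healthy|ill|dead) and, when ``config.with_sex``, ``sex``.  The panel
    is deterministic for a fixed ``config.random_seed``: all random
    draws come from one root-seeded stream, with person *i* always
    consuming row *i* of each draw, so the output does not depend on
    iteration order.
    """
    n = config.n_persons
    months = config.observation_months
    rng = np.random.default_rng(np.random.SeedSequence(config.random_seed))

    ages_support = np.array(sorted(config.start_age_distribution), dtype=np.int64)
    probs = np.array([config.start_age_distribution[int(a)] for a in ages_support])
    probs = probs / probs.sum()

    pi, qh, qi = hazards.tables(MAX_AGE)

    # One block of uniforms per purpose, row-indexed by person.
    u_age = rng.random(n)
    u_init = rng.random(n)
    u_sex = rng.random(n)
    u_event = rng.random((n, max(months - 1, 0), 2))

    start_age = ages_support[np.searchsorted(np.cumsum(probs), u_age, side="right").clip(max=len(ages_support) - 1)]

    states = np.zeros((n, months), dtype=np.int8)
    if config.initial_ill_prob is not None:
        p0 = np.array([float(config.initial_ill_prob.get(int(a), 0.0))
                       for a in start_age])
        if np.any((p0 < 0) | (p0 > 1)):
            raise ValueError("initial_ill_prob values must lie in [0, 1]")
        states[u_init < p0, 0] = ILL

    for m in range(months - 1):
        age = np.minimum(start_age + m // 12, MAX_AGE)
        cur = states[:, m]
        nxt = cur.copy()
        alive = cur != DEAD
        q = np.where(cur == ILL, qi[age], qh[age])
        dies = alive & (u_event[:, m, 0] < q)
        nxt[dies] = DEAD
        onset = (cur == HEALTHY) & ~dies & (u_event[:, m, 1] < pi[age])
        nxt[onset] = ILL
        states[:, m + 1] = nxt

    month_idx = np.tile(np.arange(months, dtype=np.int64), n)
    pid = np.repeat(np.arange(n, dtype=np.int64), months)
    age_years = np.minimum(start_age[:, None] + np.arange(months) // 12,
                           MAX_AGE).astype(np.int64).ravel()
    panel = pd.DataFrame({
        "person_id": pid,
        "month_index": month_idx,
        "age_years": age_years,
        "state": pd.Categorical.from_codes(states.ravel(),
                                           categories=list(STATE_LABELS)),
    })
    if config.with_sex:
        sex = np.where(u_sex < 0.5, "female", "male")
        panel["sex"] = pd.Categorical(np.repeat(sex, months),
                                      categories=["female", "male"])
    return panel


def _monthly_cohort_propagation(hazards: HazardSpec, age_cap: int = MAX_AGE):
    """Propagate a birth cohort month by month under the exact hazards.

    Returns per-age arrays (p_healthy, p_ill) at the start of each age
    year and the pooled monthly alive->dead probability per age
    (person-month weighted over the 12 months of that age), which is the
    large-sample limit of the two-state comparator estimated by pooling
    deaths from both alive states.
    """
    pi, qh, qi = hazards.tables(age_cap)
    p_h, p_i = 1.0, 0.0
    ph_year = np.zeros(age_cap + 1)
    pi_year = np.zeros(age_cap + 1)
    pooled_q = np.zeros(age_cap + 1)
    for a in range(age_cap + 1):
        ph_year[a], pi_year[a] = p_h, p_i
        deaths = 0.0
        at_risk = 0.0
        for _ in range(12):
            deaths += p_h * qh[a] + p_i * qi[a]
            at_risk += p_h + p_i
            p_h, p_i = (p_h * (1 - qh[a]) * (1 - pi[a]),
                        p_i * (1 - qi[a]) + p_h * (1 - qh[a]) * pi[a])
        pooled_q[a] = deaths / at_risk if at_risk > 0 else 0.0
    return ph_year, pi_year, pooled_q


def equilibrium_ill_prevalence(hazards: HazardSpec,
                               age_cap: int = MAX_AGE) -> dict[int, float]:
    """Birth-cohort probability of being ill given alive, by integer age.

    Useful as ``CohortConfig.initial_ill_prob`` so that a panel of
    late-entering persons carries the same age-specific healthy/ill mix
    as a cohort followed from birth — the mix that the pooled two-state
    comparator implicitly assumes.
    """
    ph, pi_, _ = _monthly_cohort_propagation(hazards, age_cap)
    alive = ph + pi_
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(alive > 0, pi_ / alive, 0.0)
    return {a: float(frac[a]) for a in range(age_cap + 1)}


def analytic_metrics(hazards: HazardSpec, age_cap: int = MAX_AGE):
    """Ground-truth burden metrics by exact propagation of the hazards.

    Builds the exact per-age monthly transition matrices implied by the
    generating hazards, annualizes them (12th matrix power), derives the
    pooled two-state comparator from the birth-cohort state mix, and
    evaluates the same metric definitions used by the estimation
    pipeline — bypassing panel simulation and estimation entirely.

    Returns
    -------
    BurdenMetrics
    """
    from .transitions import AgeTransitionMatrices, annualize
    from .metrics import ComparatorModel, burden_from_matrices

    monthly = hazards.monthly_matrices(age_cap)
    mats = annualize(AgeTransitionMatrices(
        monthly=monthly, yearly=None,
        data_present=np.ones((age_cap + 1, 3), dtype=bool), age_cap=age_cap))
    _, _, pooled_q = _monthly_cohort_propagation(hazards, age_cap)
    comparator = ComparatorModel(monthly_death=pooled_q,
                                 yearly_death=1.0 - (1.0 - pooled_q) ** 12,
                                 age_cap=age_cap)
    return burden_from_matrices(mats, comparator)


def generate_prevalence_snapshot(n_persons: int,
                                 condition_marginals: Mapping[str, object],
                                 joint_excess: Mapping[tuple, float] | None = None,
                                 random_seed: int = 0,
                                 age_range: tuple[int, int] = (20, 90)) -> pd.DataFrame:
    """Cross-sectional snapshot: one row per person with 0/1 condition flags.

    Parameters
    ----------
    condition_marginals : mapping
        Condition label -> marginal prevalence, either a float or a
        callable ``f(age_array, sex_array) -> prob_array``.
    joint_excess : mapping, optional
        ``(cond_a, cond_b) -> excess`` over the independence expectation;
        the implied joint prevalence ``p_a * p_b + excess`` must respect
        the Frechet bounds ``[max(0, p_a + p_b - 1), min(p_a, p_b)]`` for
        every person, else the request is rejected.  Pairs must be
        disjoint.  Conditions not in any pair are sampled independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence(random_seed))
    lo, hi = age_range
    age = rng.integers(lo, hi + 1, size=n_persons)
    sex = np.where(rng.random(n_persons) < 0.5, "female", "male")

    def marg(cond):
        p = condition_marginals[cond]
        if callable(p):
            vals = np.asarray(p(age, sex), dtype=float)
            if vals.shape != age.shape:
                vals = np.full(n_persons, float(vals))
        else:
            vals = np.full(n_persons, float(p))
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"marginal prevalence of {cond!r} outside [0, 1]")
        return vals

    joint_excess = dict(joint_excess or {})
    paired = [c for pair in joint_excess for c in pair]
    if len(paired) != len(set(paired)):
        raise ValueError("joint_excess pairs must be disjoint")
    for c in paired:
        if c not in condition_marginals:
            raise ValueError(f"pair condition {c!r} has no marginal")

    flags = {}
    for (ca, cb), excess in joint_excess.items():
        pa, pb = marg(ca), marg(cb)
        joint = pa * pb + excess
        lo_b = np.maximum(0.0, pa + pb - 1.0)
        hi_b = np.minimum(pa, pb)
        if np.any(joint < lo_b - 1e-12) or np.any(joint > hi_b + 1e-12):
            raise ValueError(
                f"excess {excess} for pair ({ca}, {cb}) implies a joint "
                "prevalence outside the Frechet bounds [max(0, p+q-1), min(p, q)]"
            )
        u = rng.random(n_persons)
        # cells: 11, 10, 01, 00 in cumulative order
        p11 = joint
        p10 = pa - joint
        p01 = pb - joint
        both = u < p11
        a_only = (~both) & (u < p11 + p10)
        b_only = (~both) & (~a_only) & (u < p11 + p10 + p01)
        flags[ca] = (both | a_only).astype(np.int8)
        flags[cb] = (both | b_only).astype(np.int8)
    for cond in condition_marginals:
        if cond in flags:
            continue
        flags[cond] = (rng.random(n_persons) < marg(cond)).astype(np.int8)

    out = pd.DataFrame({"person_id": np.arange(n_persons, dtype=np.int64),
                        "age_years": age.astype(np.int64), "sex": sex})
    for cond in condition_marginals:  # preserve caller's column order
        out[cond] = flags[cond]
    return out
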
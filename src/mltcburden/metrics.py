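"""Burden metrics from an illness-death model.

A birth cohort is propagated through the yearly transition matrices to
obtain state occupancy and the per-age inflow into illness
P_healthy→ill(a) = P_healthy(a) · P[healthy, ill, a].  From these:

* lifetime risk  L_r = Σ_a P_healthy→ill(a),
* Y_LW(a): expected remaining years for a person ill at age a,
* Y_LL(a): comparator (two-state alive–dead) remaining years minus
  Y_LW(a), where the comparator pools deaths from both alive states of
  the same count tensor,
* inflow-weighted averages Y_LW and Y_LL,
* a_median: the integer age α minimising |upper-tail inflow share − ½|,
* community scalings C = 1000 · metric · L_r.

Remaining-years convention: the year of the starting age is counted as
lived (survival 1 at entry), no half-cycle correction; with a yearly
death probability of 1 everywhere the expectation is exactly 1.0.  The
same convention applies to the ill and comparator curves, so Y_LL is
insensitive to it to first order.  All sums truncate at the age cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .states import HEALTHY, ILL, DEAD
from .transitions import (AgeTransitionMatrices, TransitionCountTensor,
                          EligibilityReport, check_eligibility,
                          DEFAULT_ELIGIBILITY_THRESHOLD)


class NotComputableError(ValueError):
    """A metric is undefined for this input (e.g. lifetime risk is zero)."""


class IneligibleError(RuntimeError):
    """The count tensor fails the minimum-observations filter."""

    def __init__(self, report: EligibilityReport):
        self.report = report
        super().__init__(
            "insufficient transition observations "
            f"(threshold {report.threshold}): failing types {report.failing}"
        )


@dataclass(frozen=True)
class CohortOccupancy:
    """State occupancy of a birth cohort by integer age, plus illness inflow."""

    p_healthy: np.ndarray
    p_ill: np.ndarray
    p_dead: np.ndarray
    inflow: np.ndarray      # P_healthy→ill(a)
    age_cap: int


@dataclass(frozen=True)
class ComparatorModel:
    """Two-state alive–dead model pooled over both alive states."""

    monthly_death: np.ndarray
    yearly_death: np.ndarray
    age_cap: int


@dataclass(frozen=True)
class BurdenMetrics:
    """The burden metrics for one condition combination.

    ``age_at_death`` is the median onset age plus the years lived with
    the condition combination.  Community metrics are per 1,000
    population: C = 1000 · metric · L_r.  When lifetime risk is zero the
    onset-conditional metrics are undefined and reported as NaN.
    """

    lifetime_risk: float
    median_onset_age: float
    years_lived_with: float
    years_of_life_lost: float
    age_at_death: float
    community_years_lived: float
    community_years_lost: float

    def as_dict(self) -> dict:
        return {
            "L_r": self.lifetime_risk,
            "a_median": self.median_onset_age,
            "Y_LW": self.years_lived_with,
            "Y_LL": self.years_of_life_lost,
            "age_at_death": self.age_at_death,
            "C_YLW": self.community_years_lived,
            "C_YLL": self.community_years_lost,
        }


def _require_yearly(matrices: AgeTransitionMatrices) -> np.ndarray:
    if matrices.yearly is None:
        raise ValueError("matrices have no yearly part; call annualize() first")
    return matrices.yearly


def propagate_cohort(matrices: AgeTransitionMatrices) -> CohortOccupancy:
    """Advance a birth cohort (all healthy at age 0) through the yearly matrices.

    Occupancy is recorded at the start of each age; the inflow into
    illness at age a is recorded before the advance as
    P_healthy(a) · P[healthy→ill at a].
    """
    yearly = _require_yearly(matrices)
    A = matrices.age_cap + 1
    occ = np.zeros((A, 3))
    inflow = np.zeros(A)
    v = np.array([1.0, 0.0, 0.0])
    for a in range(A):
        occ[a] = v
        inflow[a] = v[HEALTHY] * yearly[a, HEALTHY, ILL]
        v = v @ yearly[a]
    return CohortOccupancy(p_healthy=occ[:, HEALTHY], p_ill=occ[:, ILL],
                           p_dead=occ[:, DEAD], inflow=inflow,
                           age_cap=matrices.age_cap)


def lifetime_risk(occupancy: CohortOccupancy) -> float:
    """Probability of ever entering the illness state: Σ_a inflow(a)."""
    return float(occupancy.inflow.sum())


def _remaining_years(yearly_death: np.ndarray, a: int, age_cap: int) -> float:
    if not 0 <= a <= age_cap:
        raise ValueError(f"age {a} outside [0, {age_cap}]")
    s = 1.0
    total = 0.0
    for x in range(a, age_cap + 1):
        total += s
        s *= 1.0 - yearly_death[x]
    return total


def expected_remaining_years_ill(matrices: AgeTransitionMatrices, a: int) -> float:
    """Expected whole years lived from age a by a person in the ill state.

    Sum over x in [a, age_cap] of the probability of still being alive
    (ill) at x given ill at a; the entry year counts as lived.
    """
    yearly = _require_yearly(matrices)
    return _remaining_years(yearly[:, ILL, DEAD], a, matrices.age_cap)


def build_comparator(counts: TransitionCountTensor) -> ComparatorModel:
    """Two-state comparator: pool deaths from both alive states per age.

    Monthly alive→dead probability at age a is
    (n[h,d,a] + n[i,d,a]) / (all transitions out of healthy and ill at a);
    ages without data fall back to staying alive.  Annualized as
    1 − (1 − q)^12.
    """
    c = counts.counts.astype(float)
    num = c[HEALTHY, DEAD] + c[ILL, DEAD]
    den = c[HEALTHY].sum(axis=0) + c[ILL].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(den > 0, num / den, 0.0)
    return ComparatorModel(monthly_death=q,
                           yearly_death=1.0 - (1.0 - q) ** 12,
                           age_cap=counts.age_cap)


def comparator_remaining_years(comparator: ComparatorModel, a: int) -> float:
    """Expected remaining years at age a in the pooled alive–dead model."""
    return _remaining_years(comparator.yearly_death, a, comparator.age_cap)


def years_of_life_lost_at(matrices: AgeTransitionMatrices,
                          comparator: ComparatorModel, a: int) -> float:
    """Difference between comparator and ill-state remaining years at age a."""
    return (comparator_remaining_years(comparator, a)
            - expected_remaining_years_ill(matrices, a))


def average_metric(per_age_values: np.ndarray, occupancy: CohortOccupancy,
                   L_r: float) -> float:
    """Inflow-weighted mean of a per-age metric over onset ages.

    Weights are P_healthy→ill(a) / L_r and sum to 1.  Undefined when
    L_r = 0 (no one ever enters the illness state).
    """
    if L_r <= 0:
        raise NotComputableError("lifetime risk is zero; onset-conditional "
                                 "metrics are undefined")
    w = occupancy.inflow / L_r
    return float(np.dot(w, np.asarray(per_age_values, dtype=float)))


def median_onset(occupancy: CohortOccupancy, L_r: float) -> int:
    """Integer age α minimising |Σ_{a=α}^{cap} inflow(a)/L_r − 0.5|.

    Ties break toward the lower age.  Candidate ages are restricted to
    the support range of the inflow (first to last age with positive
    inflow): the onset median must lie among observed onset ages, and
    without the restriction a degenerate point-mass inflow would tie
    every age at deviation 0.5 and resolve to age 0.
    """
    if L_r <= 0:
        raise NotComputableError("lifetime risk is zero; median onset "
                                 "is undefined")
    tail = np.cumsum(occupancy.inflow[::-1])[::-1] / L_r
    support = np.nonzero(occupancy.inflow > 0)[0]
    lo, hi = support[0], support[-1]
    dev = np.abs(tail[lo:hi + 1] - 0.5)
    return int(lo + np.argmin(dev))


def burden_from_matrices(matrices: AgeTransitionMatrices,
                         comparator: ComparatorModel) -> BurdenMetrics:
    """Assemble all burden metrics from annualized matrices and a comparator."""
    occ = propagate_cohort(matrices)
    L_r = lifetime_risk(occ)
    if L_r <= 0:
        nan = math.nan
        return BurdenMetrics(lifetime_risk=0.0, median_onset_age=nan,
                             years_lived_with=nan, years_of_life_lost=nan,
                             age_at_death=nan, community_years_lived=nan,
                             community_years_lost=nan)
    ages = range(matrices.age_cap + 1)
    ylw_by_age = np.array([expected_remaining_years_ill(matrices, a) for a in ages])
    yll_by_age = np.array([comparator_remaining_years(comparator, a) for a in ages]) - ylw_by_age
    y_lw = average_metric(ylw_by_age, occ, L_r)
    y_ll = average_metric(yll_by_age, occ, L_r)
    a_med = median_onset(occ, L_r)
    return BurdenMetrics(
        lifetime_risk=L_r,
        median_onset_age=float(a_med),
        years_lived_with=y_lw,
        years_of_life_lost=y_ll,
        age_at_death=a_med + y_lw,
        community_years_lived=1000.0 * y_lw * L_r,
        community_years_lost=1000.0 * y_ll * L_r,
    )


def compute_burden(matrices: AgeTransitionMatrices,
                   counts: TransitionCountTensor,
                   threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD,
                   allow_ineligible: bool = False) -> BurdenMetrics:
    """Full burden computation with the eligibility gate.

    Raises :class:`IneligibleError` (carrying the report) when the
    counts fail the minimum-observations filter, unless
    ``allow_ineligible`` is set.
    """
    report = check_eligibility(counts, threshold)
    if not report.eligible and not allow_ineligible:
        raise IneligibleError(report)
    return burden_from_matrices(matrices, build_comparator(counts))
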
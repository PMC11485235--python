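"""Transition tallying and per-age transition-matrix estimation.

Monthly state observations are turned into counts n[i][j][a] of moves
from state i to state j at age a (age in completed years at the first
month of each consecutive pair).  Counts become row-normalised monthly
matrices; ages/states without data fall back to "remain in the same
state" (an identity row).  Yearly matrices are the 12th matrix power of
the monthly ones.  Condition pairs qualify for the illness-death model
only when each of the three transition types (healthy→ill,
healthy→dead, ill→dead) has at least 1,000 observations in total.

Observed ill→healthy moves (remission) are incompatible with the model
form; they are excluded from the counts and surfaced per age so the
caller can reject the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import HEALTHY, ILL, DEAD, N_STATES, STATE_LABELS, StateSpace

DEFAULT_AGE_CAP = 100
DEFAULT_ELIGIBILITY_THRESHOLD = 1000

#: the three estimable transition types, as (origin, destination) codes
TRANSITION_TYPES = ((HEALTHY, ILL), (HEALTHY, DEAD), (ILL, DEAD))


@dataclass(frozen=True)
class TransitionCountTensor:
    """Counts ``counts[i, j, a]`` of observed monthly i→j moves at age a."""

    counts: np.ndarray            # (3, 3, age_cap + 1) int64
    remission_by_age: np.ndarray  # excluded ill→healthy observations per age
    age_cap: int = DEFAULT_AGE_CAP

    def __post_init__(self):
        c = self.counts
        if c.shape != (N_STATES, N_STATES, self.age_cap + 1):
            raise ValueError(f"counts has shape {c.shape}, expected "
                             f"(3, 3, {self.age_cap + 1})")
        if np.any(c < 0):
            raise ValueError("negative transition counts")
        if c[DEAD, HEALTHY].any() or c[DEAD, ILL].any():
            raise ValueError("counts out of the dead state are impossible")
        if c[ILL, HEALTHY].any():
            raise ValueError("ill→healthy counts must be zero "
                             "(remission is excluded from the tensor)")

    @property
    def remission_total(self) -> int:
        return int(self.remission_by_age.sum())

    def total(self, origin: int, destination: int) -> int:
        """Total observations of one transition type over all ages."""
        return int(self.counts[origin, destination].sum())


@dataclass(frozen=True)
class AgeTransitionMatrices:
    """Per-age monthly (and, once annualized, yearly) 3x3 stochastic matrices."""

    monthly: np.ndarray             # (age_cap + 1, 3, 3)
    yearly: np.ndarray | None       # same shape, filled by annualize()
    data_present: np.ndarray        # (age_cap + 1, 3) bool, per origin state
    age_cap: int = DEFAULT_AGE_CAP


@dataclass(frozen=True)
class EligibilityReport:
    """Pass/fail of the minimum-observations filter per transition type."""

    totals: dict          # (origin_label, dest_label) -> total count
    threshold: int
    eligible: bool

    @property
    def failing(self) -> list:
        return [k for k, v in self.totals.items() if v < self.threshold]


def tally_transitions(panel: pd.DataFrame,
                      states: StateSpace | None = None,
                      age_cap: int = DEFAULT_AGE_CAP) -> TransitionCountTensor:
    """Tally monthly transitions from a person-month panel.

    Each consecutive month pair of each person contributes one count at
    the age attained at the first month of the pair.  Moves out of the
    dead state are never counted; ill→healthy moves are excluded from
    the tensor and reported in ``remission_by_age``.
    """
    states = states or StateSpace()
    required = {"person_id", "month_index", "age_years"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel lacks required columns: {sorted(missing)}")
    codes = states.encode(panel)
    pid = pd.factorize(panel["person_id"])[0]
    month = panel["month_index"].to_numpy(dtype=np.int64)
    age = panel["age_years"].to_numpy(dtype=np.int64)
    if len(panel) and (age.min() < 0 or age.max() > age_cap):
        raise ValueError(f"panel ages outside [0, {age_cap}]")

    order = np.lexsort((month, pid))
    pid, month, age, codes = pid[order], month[order], age[order], codes[order]

    consec = (pid[1:] == pid[:-1]) & (month[1:] == month[:-1] + 1)
    i = codes[:-1][consec]
    j = codes[1:][consec]
    a = age[:-1][consec]

    live = i != DEAD
    i, j, a = i[live], j[live], a[live]

    remission = (i == ILL) & (j == HEALTHY)
    remission_by_age = np.bincount(a[remission], minlength=age_cap + 1)
    keep = ~remission
    flat = (i[keep].astype(np.int64) * N_STATES + j[keep]) * (age_cap + 1) + a[keep]
    counts = np.bincount(flat, minlength=N_STATES * N_STATES * (age_cap + 1))
    counts = counts.reshape(N_STATES, N_STATES, age_cap + 1).astype(np.int64)
    return TransitionCountTensor(counts=counts,
                                 remission_by_age=remission_by_age.astype(np.int64),
                                 age_cap=age_cap)


def estimate_monthly_matrices(counts: TransitionCountTensor) -> AgeTransitionMatrices:
    """Row-normalise counts into per-age monthly transition matrices.

    P[i, j, a] = n[i, j, a] / sum_k n[i, k, a] where the denominator is
    positive; origin rows with no observations at an age are set to the
    identity (individuals are assumed to remain in the same state) and
    flagged ``data_present = False``.  The dead row is structurally
    (0, 0, 1) and the ill→healthy entry exactly 0.
    """
    A = counts.age_cap + 1
    c = counts.counts.astype(float)              # (3, 3, A)
    denom = c.sum(axis=1)                        # (3, A)
    monthly = np.zeros((A, 3, 3))
    data_present = (denom > 0).T.copy()          # (A, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(denom[:, None, :] > 0, c / denom[:, None, :], 0.0)
    monthly[:] = np.transpose(ratios, (2, 0, 1))
    for s in range(N_STATES):
        fallback = ~data_present[:, s]
        monthly[fallback, s, :] = 0.0
        monthly[fallback, s, s] = 1.0
    monthly[:, DEAD, :] = 0.0
    monthly[:, DEAD, DEAD] = 1.0
    monthly[:, ILL, HEALTHY] = 0.0
    return AgeTransitionMatrices(monthly=monthly, yearly=None,
                                 data_present=data_present,
                                 age_cap=counts.age_cap)


def annualize(matrices: AgeTransitionMatrices,
              rtol: float = 1e-9) -> AgeTransitionMatrices:
    """Fill the yearly matrices: T_y = T_m^12 by 12 successive products.

    Rejects any monthly row that is not stochastic (non-negative,
    summing to 1 within ``rtol``), naming the offending age and row.
    """
    monthly = matrices.monthly
    sums = monthly.sum(axis=2)
    bad = (np.abs(sums - 1.0) > rtol) | (monthly < -1e-15).any(axis=2)
    if bad.any():
        a, s = np.argwhere(bad)[0]
        raise ValueError(
            f"monthly matrix at age {a} has a non-stochastic "
            f"{STATE_LABELS[s]} row (sum {sums[a, s]:.12g})"
        )
    yearly = np.broadcast_to(np.eye(3), monthly.shape).copy()
    for _ in range(12):
        yearly = yearly @ monthly
    return AgeTransitionMatrices(monthly=monthly, yearly=yearly,
                                 data_present=matrices.data_present,
                                 age_cap=matrices.age_cap)


def check_eligibility(counts: TransitionCountTensor,
                      threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD) -> EligibilityReport:
    """Apply the minimum-observations filter to the three transition types."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    totals = {
        (STATE_LABELS[i], STATE_LABELS[j]): counts.total(i, j)
        for i, j in TRANSITION_TYPES
    }
    eligible = all(v >= threshold for v in totals.values())
    return EligibilityReport(totals=totals, threshold=threshold,
                             eligible=eligible)
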
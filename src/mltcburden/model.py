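"""Scikit-learn-style estimator for the illness-death burden pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .states import StateSpace
from .transitions import (tally_transitions, estimate_monthly_matrices,
                          annualize, check_eligibility,
                          DEFAULT_AGE_CAP, DEFAULT_ELIGIBILITY_THRESHOLD)
from .metrics import (build_comparator, burden_from_matrices,
                      propagate_cohort, lifetime_risk,
                      expected_remaining_years_ill,
                      comparator_remaining_years, IneligibleError)


class IllnessDeathModel(BaseEstimator):
    """Three-state illness-death Markov model fitted to a person-month panel.

    ``fit`` tallies monthly transitions, applies the eligibility filter,
    estimates per-age monthly transition matrices, annualizes them
    (T_y = T_m^12), builds the pooled two-state alive–dead comparator
    and derives the burden metrics from a birth-cohort propagation.

    Parameters
    ----------
    eligibility_threshold : int, default 1000
        Minimum total observations required of each transition type
        (healthy→ill, healthy→dead, ill→dead).
    age_cap : int, default 100
        Ages are modelled on [0, age_cap]; all sums truncate there.
    allow_ineligible : bool, default False
        Proceed despite a failing eligibility filter.
    allow_remission : bool, default False
        Proceed despite observed ill→healthy moves (they are excluded
        from the counts either way); by default such a panel is refused
        because it is incompatible with the model form.
    condition_pair : tuple of str, optional
        Derive the ill state from two condition-flag columns (both
        present = ill) instead of a literal ``state`` column.

    Attributes
    ----------
    counts_ : TransitionCountTensor
    eligibility_ : EligibilityReport
    matrices_ : AgeTransitionMatrices
        With both monthly and yearly parts filled.
    comparator_ : ComparatorModel
    occupancy_ : CohortOccupancy
    metrics_ : BurdenMetrics

    Examples
    --------
    >>> from mltcburden import HazardSpec, CohortConfig, generate_panel
    >>> hz = HazardSpec.from_gompertz(5e-5, 0.06, 5e-6, 0.095,
    ...                               excess_mortality=2.5, adult_min_age=20)
    >>> panel = generate_panel(CohortConfig.uniform_ages(50_000), hz)
    >>> model = IllnessDeathModel().fit(panel)
    >>> 0 < model.metrics_.lifetime_risk < 1
    True
    """

    def __init__(self, eligibility_threshold: int = DEFAULT_ELIGIBILITY_THRESHOLD,
                 age_cap: int = DEFAULT_AGE_CAP,
                 allow_ineligible: bool = False,
                 allow_remission: bool = False,
                 condition_pair: tuple | None = None):
        self.eligibility_threshold = eligibility_threshold
        self.age_cap = age_cap
        self.allow_ineligible = allow_ineligible
        self.allow_remission = allow_remission
        self.condition_pair = condition_pair

    def fit(self, X: pd.DataFrame, y=None) -> "IllnessDeathModel":
        """Fit the model to a person-month panel.

        Parameters
        ----------
        X : DataFrame
            Columns ``person_id``, ``month_index``, ``age_years`` and
            either ``state`` (healthy|ill|dead) or, with
            ``condition_pair`` set, ``dead`` plus per-condition flags.
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a person-month panel DataFrame")
        if not 1 <= self.age_cap <= 100:
            raise ValueError("age_cap must lie in [1, 100]")
        states = StateSpace(condition_pair=self.condition_pair)
        self.counts_ = tally_transitions(X, states, age_cap=self.age_cap)
        if self.counts_.remission_total and not self.allow_remission:
            raise ValueError(
                f"{self.counts_.remission_total} ill→healthy (remission) "
                "observations are present; this condition pair is "
                "incompatible with the no-remission model form "
                "(set allow_remission=True to exclude them and proceed)"
            )
        self.eligibility_ = check_eligibility(self.counts_,
                                              self.eligibility_threshold)
        if not self.eligibility_.eligible and not self.allow_ineligible:
            raise IneligibleError(self.eligibility_)
        self.matrices_ = annualize(estimate_monthly_matrices(self.counts_))
        self.comparator_ = build_comparator(self.counts_)
        self.occupancy_ = propagate_cohort(self.matrices_)
        self.metrics_ = burden_from_matrices(self.matrices_, self.comparator_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "metrics_"):
            raise AttributeError("model is not fitted; call fit(panel) first")

    def expected_remaining_years(self, age: int, state: str = "ill") -> float:
        """Expected remaining years at ``age`` in the ill state or the
        pooled comparator (``state='comparator'``)."""
        self._check_fitted()
        if state == "ill":
            return expected_remaining_years_ill(self.matrices_, age)
        if state == "comparator":
            return comparator_remaining_years(self.comparator_, age)
        raise ValueError("state must be 'ill' or 'comparator'")

    @property
    def lifetime_risk_(self) -> float:
        self._check_fitted()
        return lifetime_risk(self.occupancy_)

    def summary(self) -> pd.Series:
        """Burden metrics as a pandas Series (L_r, a_median, Y_LW, ...)."""
        self._check_fitted()
        return pd.Series(self.metrics_.as_dict())
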
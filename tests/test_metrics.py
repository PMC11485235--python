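"""Cohort propagation, burden metrics and their invariants."""

import numpy as np
import pytest

from mltcburden import (CohortConfig, HazardSpec, NotComputableError,
                        average_metric, build_comparator, compute_burden,
                        comparator_remaining_years, constant_hazard,
                        expected_remaining_years_ill, generate_panel,
                        lifetime_risk, median_onset, microsimulate_metrics,
                        propagate_cohort, tally_transitions,
                        years_of_life_lost_at)
from mltcburden.metrics import (CohortOccupancy, ComparatorModel,
                                IneligibleError, burden_from_matrices)
from mltcburden.states import HEALTHY, ILL, DEAD
from mltcburden.transitions import (AgeTransitionMatrices, annualize,
                                    estimate_monthly_matrices)

from conftest import matrices_from_probs
from test_transitions import empty_counts


def occupancy_from_inflow(inflow):
    inflow = np.asarray(inflow, dtype=float)
    A = len(inflow)
    return CohortOccupancy(p_healthy=np.ones(A), p_ill=np.zeros(A),
                           p_dead=np.zeros(A), inflow=inflow, age_cap=A - 1)


class TestPropagation:
    def test_identity_matrices_nothing_moves(self):
        mats = matrices_from_probs(0.0, 0.0, 0.0)
        occ = propagate_cohort(mats)
        assert (occ.p_healthy == 1.0).all()
        assert (occ.inflow == 0.0).all()
        assert lifetime_risk(occ) == 0.0

    def test_certain_transition_at_age_zero(self):
        p_ill = np.zeros(101)
        p_ill[0] = 1.0
        mats = matrices_from_probs(p_ill, 0.0, 0.0)
        occ = propagate_cohort(mats)
        assert occ.inflow[0] == 1.0
        assert occ.p_ill[1] == 1.0
        assert lifetime_risk(occ) == 1.0

    def test_occupancy_conserved_and_inflow_product(self, small_panel):
        mats = annualize(estimate_monthly_matrices(tally_transitions(small_panel)))
        occ = propagate_cohort(mats)
        total = occ.p_healthy + occ.p_ill + occ.p_dead
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        np.testing.assert_allclose(
            occ.inflow, occ.p_healthy * mats.yearly[:, HEALTHY, ILL],
            atol=1e-14)
        assert occ.inflow.sum() <= 1.0 + 1e-12

    def test_matches_monthly_bruteforce_occupancy(self):
        """Yearly propagation of T_m^12 equals 1,212 monthly steps
        collapsed to year boundaries."""
        mats = matrices_from_probs(0.0017, 0.00083, 0.00083, monthly=True)
        occ = propagate_cohort(mats)
        v = np.array([1.0, 0.0, 0.0])
        m = mats.monthly[0]
        for a in range(101):
            np.testing.assert_allclose(
                [occ.p_healthy[a], occ.p_ill[a], occ.p_dead[a]], v, atol=1e-8)
            for _ in range(12):
                v = v @ m
    def test_lifetime_risk_independent_accumulation(self, small_panel):
        """L_r = sum of inflow also equals 1 - P_healthy(end) - mass
        dying while healthy, accumulated independently."""
        mats = annualize(estimate_monthly_matrices(tally_transitions(small_panel)))
        occ = propagate_cohort(mats)
        died_healthy = 0.0
        v = np.array([1.0, 0.0, 0.0])
        for a in range(101):
            died_healthy += v[HEALTHY] * mats.yearly[a, HEALTHY, DEAD]
            v = v @ mats.yearly[a]
        assert lifetime_risk(occ) == pytest.approx(
            1.0 - v[HEALTHY] - died_healthy, abs=1e-10)


class TestRemainingYears:
    def test_certain_yearly_death_gives_one_year(self):
        mats = matrices_from_probs(0.0, 0.0, 1.0)
        for a in (0, 50, 100):
            assert expected_remaining_years_ill(mats, a) == 1.0

    def test_immortal_ill_state_truncates_at_cap(self):
        mats = matrices_from_probs(0.0, 0.0, 0.0)
        assert expected_remaining_years_ill(mats, 90) == 11.0

    def test_matches_geometric_series(self):
        q = 0.2
        mats = matrices_from_probs(0.0, 0.0, q)
        a = 10
        expected = sum((1 - q) ** k for k in range(101 - a))
        assert expected_remaining_years_ill(mats, a) == pytest.approx(
            expected, rel=1e-12)


class TestComparator:
    def test_pooled_ratio(self):
        counts = empty_counts()
        counts.counts[HEALTHY, HEALTHY, 60] = 900
        counts.counts[HEALTHY, DEAD, 60] = 100
        counts.counts[ILL, ILL, 60] = 50
        counts.counts[ILL, DEAD, 60] = 50
        comp = build_comparator(counts)
        assert comp.monthly_death[60] == pytest.approx(150 / 1100)
        assert comp.yearly_death[60] == pytest.approx(
            1 - (1 - 150 / 1100) ** 12)

    def test_no_ill_months_equals_healthy_mortality(self):
        counts = empty_counts()
        counts.counts[HEALTHY, HEALTHY, 40] = 990
        counts.counts[HEALTHY, DEAD, 40] = 10
        comp = build_comparator(counts)
        assert comp.monthly_death[40] == pytest.approx(0.01)

    def test_zero_data_age_stays_alive(self):
        comp = build_comparator(empty_counts())
        assert (comp.monthly_death == 0.0).all()
        assert comparator_remaining_years(comp, 90) == 11.0


class TestYearsOfLifeLost:
    def test_null_excess_is_exactly_zero(self):
        q = np.linspace(0.01, 0.4, 101)
        mats = matrices_from_probs(0.02, q, q)
        comp = ComparatorModel(monthly_death=np.zeros(101), yearly_death=q,
                               age_cap=100)
        for a in range(101):
            assert years_of_life_lost_at(mats, comp, a) == 0.0

    def test_certain_ill_death(self):
        mats = matrices_from_probs(0.0, 0.0, 1.0)
        comp = ComparatorModel(monthly_death=np.zeros(101),
                               yearly_death=np.full(101, 0.1), age_cap=100)
        a = 30
        assert years_of_life_lost_at(mats, comp, a) == pytest.approx(
            comparator_remaining_years(comp, a) - 1.0)

    def test_strictly_positive_under_excess_mortality(self):
        mats = matrices_from_probs(0.02, 0.05, 0.15)
        comp = ComparatorModel(monthly_death=np.zeros(101),
                               yearly_death=np.full(101, 0.05), age_cap=100)
        assert all(years_of_life_lost_at(mats, comp, a) > 0
                   for a in range(100))

    def test_monotone_in_ill_mortality(self):
        """Raising every ill->dead probability never lowers Y_LL and
        never raises Y_LW (fixed comparator and inflow)."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            q_ill = rng.uniform(0.02, 0.3, 101)
            comp_q = rng.uniform(0.01, 0.2, 101)
            p_ill = rng.uniform(0.0, 0.05, 101)
            comp = ComparatorModel(monthly_death=np.zeros(101),
                                   yearly_death=comp_q, age_cap=100)
            lo = matrices_from_probs(p_ill, comp_q, q_ill)
            hi = matrices_from_probs(p_ill, comp_q,
                                     np.minimum(q_ill + 0.05, 1.0))
            m_lo = burden_from_matrices(lo, comp)
            m_hi = burden_from_matrices(hi, comp)
            assert m_hi.years_of_life_lost >= m_lo.years_of_life_lost
            assert m_hi.years_lived_with <= m_lo.years_lived_with


class TestAverages:
    def test_point_mass_returns_that_value(self):
        inflow = np.zeros(101)
        inflow[63] = 0.4
        occ = occupancy_from_inflow(inflow)
        values = np.arange(101, dtype=float)
        assert average_metric(values, occ, 0.4) == 63.0

    def test_constant_value_independent_of_shape(self):
        rng = np.random.default_rng(1)
        inflow = rng.dirichlet(np.ones(101)) * 0.7
        occ = occupancy_from_inflow(inflow)
        assert average_metric(np.full(101, 5.5), occ, 0.7) == pytest.approx(5.5)

    def test_two_age_hand_computation(self):
        inflow = np.zeros(101)
        inflow[50], inflow[70] = 0.3, 0.1
        values = np.zeros(101)
        values[50], values[70] = 10.0, 2.0
        occ = occupancy_from_inflow(inflow)
        # weighted mean (0.3*10 + 0.1*2) / 0.4
        assert average_metric(values, occ, 0.4) == pytest.approx(8.0)

    def test_zero_lifetime_risk_not_computable(self):
        occ = occupancy_from_inflow(np.zeros(101))
        with pytest.raises(NotComputableError):
            average_metric(np.zeros(101), occ, 0.0)
        with pytest.raises(NotComputableError):
            median_onset(occ, 0.0)


class TestMedianOnset:
    def test_point_mass(self):
        inflow = np.zeros(101)
        inflow[63] = 0.2
        assert median_onset(occupancy_from_inflow(inflow), 0.2) == 63

    def test_uniform_inflow_over_band(self):
        inflow = np.zeros(101)
        inflow[40:60] = 0.01          # uniform over ages 40..59
        assert median_onset(occupancy_from_inflow(inflow), 0.2) == 50

    def test_tie_breaks_to_lower_age(self):
        inflow = np.zeros(101)
        inflow[40], inflow[80] = 0.2, 0.2
        # tail share is exactly 0.5 for every alpha in 41..80
        assert median_onset(occupancy_from_inflow(inflow), 0.4) == 41


class TestComputeBurden:
    def test_community_identities(self, small_panel):
        counts = tally_transitions(small_panel)
        mats = annualize(estimate_monthly_matrices(counts))
        m = compute_burden(mats, counts, threshold=10)
        assert m.community_years_lived == 1000.0 * m.years_lived_with * m.lifetime_risk
        assert m.community_years_lost == 1000.0 * m.years_of_life_lost * m.lifetime_risk
        assert m.age_at_death == m.median_onset_age + m.years_lived_with

    def test_ineligible_refused_with_report(self):
        counts = empty_counts()
        mats = annualize(estimate_monthly_matrices(counts))
        with pytest.raises(IneligibleError) as exc:
            compute_burden(mats, counts)
        assert len(exc.value.report.failing) == 3
        # override computes anyway (degenerate: zero inflow)
        m = compute_burden(mats, counts, allow_ineligible=True)
        assert m.lifetime_risk == 0.0


class TestMicrosimOracle:
    def test_agrees_with_deterministic_propagation(self):
        """200k path-sampled walkers reproduce L_r, Y_LW and a_median
        from the deterministic propagation within 3 Monte-Carlo SE."""
        from conftest import study_hazards
        hz = study_hazards()
        from mltcburden import analytic_metrics
        from mltcburden.transitions import AgeTransitionMatrices
        monthly = hz.monthly_matrices(100)
        mats = annualize(AgeTransitionMatrices(
            monthly=monthly, yearly=None,
            data_present=np.ones((101, 3), bool), age_cap=100))
        truth = analytic_metrics(hz)
        sim = microsimulate_metrics(mats, n_walkers=200_000, seed=77)
        assert abs(sim["lifetime_risk"] - truth.lifetime_risk) <= \
            3 * sim["lifetime_risk_se"]
        assert abs(sim["years_lived_with"] - truth.years_lived_with) <= \
            3 * sim["years_lived_with_se"]
        assert abs(sim["median_onset_age"] - truth.median_onset_age) <= \
            max(3 * sim["median_onset_age_se"], 1.0)
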
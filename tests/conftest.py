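import numpy as np
import pytest

from mltcburden import (CohortConfig, HazardSpec, constant_hazard,
                        equilibrium_ill_prevalence, generate_panel)
from mltcburden.states import HEALTHY, ILL, DEAD
from mltcburden.transitions import AgeTransitionMatrices, annualize


def study_hazards() -> HazardSpec:
    """The Gompertz-type study conditions used for recovery experiments."""
    return HazardSpec.from_gompertz(5e-5, 0.06, 5e-6, 0.095,
                                    excess_mortality=2.5, adult_min_age=20)


@pytest.fixture(scope="session")
def gompertz_hazards() -> HazardSpec:
    return study_hazards()


@pytest.fixture(scope="session")
def constant_hazards() -> HazardSpec:
    return HazardSpec(constant_hazard(0.002), constant_hazard(0.001),
                      constant_hazard(0.001))


@pytest.fixture(scope="session")
def small_panel(gompertz_hazards):
    """A modest panel with prevalent cases, for structural tests."""
    cfg = CohortConfig.uniform_ages(
        10_000, 20, 100, random_seed=11,
        initial_ill_prob=equilibrium_ill_prevalence(gompertz_hazards))
    return generate_panel(cfg, gompertz_hazards)


def matrices_from_probs(p_ill, q_healthy, q_ill, age_cap=100,
                        monthly=False) -> AgeTransitionMatrices:
    """Build annualized matrices from per-age (or scalar) probabilities.

    With ``monthly=True`` the inputs are monthly probabilities and the
    yearly part is their 12th power; otherwise the inputs are taken as
    the *yearly* probabilities directly (yearly = given, monthly unused
    for the metric functions, which only read the yearly part).
    """
    A = age_cap + 1
    p_ill = np.broadcast_to(np.asarray(p_ill, dtype=float), (A,))
    q_h = np.broadcast_to(np.asarray(q_healthy, dtype=float), (A,))
    q_i = np.broadcast_to(np.asarray(q_ill, dtype=float), (A,))
    m = np.zeros((A, 3, 3))
    m[:, HEALTHY, ILL] = p_ill
    m[:, HEALTHY, DEAD] = q_h
    m[:, HEALTHY, HEALTHY] = 1.0 - p_ill - q_h
    m[:, ILL, DEAD] = q_i
    m[:, ILL, ILL] = 1.0 - q_i
    m[:, DEAD, DEAD] = 1.0
    mats = AgeTransitionMatrices(monthly=m, yearly=None,
                                 data_present=np.ones((A, 3), dtype=bool),
                                 age_cap=age_cap)
    if monthly:
        return annualize(mats)
    return AgeTransitionMatrices(monthly=m, yearly=m.copy(),
                                 data_present=mats.data_present,
                                 age_cap=age_cap)
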
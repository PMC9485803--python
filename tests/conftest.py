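"""Shared fixtures: a physiological control-subject parameter set at its
fasting equilibrium and a matching infusion schedule."""

import numpy as np
import pytest

from iigidyn.infusion import InfusionSchedule
from iigidyn.model_core import ModelParameters, solve_equilibrium
from iigidyn.simulator import equilibrium_state
from iigidyn.synthetic_data import gen_infusion_profile


@pytest.fixture(scope="session")
def cs_params():
    """Control-subject parameters with a2 closed by the fasting equilibrium."""
    p = ModelParameters(a1=5e-4, a2=0.25, gamma1=9.0, gamma2=3.0, k1=0.26,
                        k2=0.5, h=1.9, tau=3.0, tau1=12.0)
    _, _, a2_eq = solve_equilibrium(p, 5.5)
    return p.with_updates(a2=a2_eq)


@pytest.fixture(scope="session")
def cs_initial(cs_params):
    return equilibrium_state(cs_params, 5.5)


@pytest.fixture(scope="session")
def cs_schedule():
    rng = np.random.default_rng(1)
    return gen_infusion_profile("CS", 35.0, rng, weight_kg=85.0)


@pytest.fixture(scope="session")
def zero_schedule():
    return InfusionSchedule(grams_per_block=np.zeros(16), weight_kg=85.0)
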
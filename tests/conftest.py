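import math

import numpy as np
import pytest

from homeoburst.channels import MembraneParams, MembraneState
from homeoburst.regulation import RegulationConfig
from homeoburst.sensors import SensorConfig, SensorState
from homeoburst import engine as eng


#: A fixed-conductance regular burster (µS; period ≈ 470 ms, 4 spikes/cycle)
#: used wherever tests need genuine bursting activity without running the
#: regulation mechanism.
REFERENCE_GBAR = np.array([84.14, 0.85, 1.25, 0.13, 42.93, 15.87, 9.39])

#: Full 40-component state of a burster self-assembled by the regulation
#: mechanism (seed 1 of the scaled-down profile, after alpha latched).
#: Regenerable with engine.assemble(1, 300, reg_cfg=RegulationConfig(
#: tau_g_s=60, gamma=1e-6), sim_cfg=SimulationConfig(sustain_min=10)).
ASSEMBLED_STATE = np.array([
    -0.0577470317, 0.9965148569, 0.6604241613, 0.6480901558, 0.0044264685,
    0.401408049, 0.149612177, 0.5412974043, 0.0342490895, 0.8034418086,
    0.1041355265, 0.0709059329, 137.2015347661, 1.0, 0.382683096,
    0.2310704774, 0.3927761314, 0.2080397082, -0.0261965858, -0.0025874969,
    0.0001239329, 0.0012268702, 52.3771552318, 2.1443032396, 0.0003556379,
    3.509e-07, 50.444653463, 1.4895778453, 3.495e-07, -1.3493421031,
    -0.4215130012, 0.8181249023, 0.4215130012, -1.3493421031, -0.9912442936,
    -0.6218215481, -0.1283040376, 0.4215130012, -0.8181249023, 0.6218215481,
])


@pytest.fixture(scope="session")
def assembled_state():
    return ASSEMBLED_STATE.copy()


@pytest.fixture(scope="session")
def reference_params():
    return MembraneParams(
        gbar=REFERENCE_GBAR.copy(), shift_m=np.zeros(7), shift_h=np.zeros(4)
    )


@pytest.fixture(scope="session")
def reference_trajectory(reference_params):
    """120 s of frozen-regulation activity from the reference burster."""
    mem = MembraneState(v=-50.0, m=np.full(7, 0.05), h=np.full(4, 0.9), ca=0.4)
    y0 = eng.pack_state(mem, SensorState(), reference_params)
    return eng.run_simulation(
        y0, reference_params, SensorConfig(),
        RegulationConfig(math.inf, math.inf), 120_000.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
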
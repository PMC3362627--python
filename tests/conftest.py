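import numpy as np
import pytest

import coopna


@pytest.fixture(scope="session")
def gate_q1():
    """First-order Boltzmann gate (v_half=-30, k=6), coupling mu = 48 mV."""
    return coopna.CoopGateParams(v_half=-30.0, k=6.0, q=1, tau_m=0.1, K=1, J=48.0)


@pytest.fixture(scope="session")
def wb_params():
    """Plain Wang-Buzsaki model (no cooperative channels)."""
    return coopna.CWBParams(p=0.0)


@pytest.fixture(scope="session")
def cwb_params():
    """Default cooperative WB model: p = 0.1, strong coupling."""
    return coopna.CWBParams()


@pytest.fixture(scope="session")
def wb_spike_traj(wb_params):
    """500 ms of periodic WB spiking at a supra-rheobase step current."""
    return coopna.integrate(wb_params, 0.5, 500.0, dt=0.01)


@pytest.fixture(scope="session")
def cwb_spike_traj(cwb_params):
    """400 ms of the default cWB model just above rheobase."""
    rheo = coopna.rheobase(cwb_params)
    traj = coopna.integrate(cwb_params, 1.2 * rheo, 400.0, dt=0.01)
    traj.meta["i_step"] = 1.2 * rheo
    return traj
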
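import numpy as np
import pandas as pd
import pytest

import cardioinverse as ci
from cardioinverse.circulation_model import SimulationOutput


@pytest.fixture(scope="session")
def base_params():
    return ci.default_parameters()


@pytest.fixture(scope="session")
def ranges():
    return ci.default_ranges()


@pytest.fixture(scope="session")
def baseline_sim(base_params):
    """One default (normal-function) simulation shared across tests."""
    return ci.simulate(base_params)


@pytest.fixture(scope="session")
def small_dataset(base_params, ranges):
    """A 40-sample dataset for fast pipeline/network tests."""
    spec = ci.DatasetSpec(n_samples=40, seed=7)
    return ci.generate_dataset(spec, base_params, ranges)


@pytest.fixture(scope="session")
def small_net(small_dataset, ranges):
    cfg = ci.TrainingConfig(max_epochs=150, patience=150, seed=7)
    return ci.train_on_dataset(small_dataset, ranges, cfg)


def make_synthetic_output(v_lv, sap=None, pap=None, p_la=None, dt=0.01,
                          beat_period_steps=100):
    """Hand-built SimulationOutput for extraction tests (no simulation)."""
    n = len(v_lv)
    time = np.arange(n) * dt
    zeros = np.zeros(n)
    sap = zeros + 90.0 if sap is None else np.asarray(sap, float)
    pap = zeros + 15.0 if pap is None else np.asarray(pap, float)
    p_la = zeros + 8.0 if p_la is None else np.asarray(p_la, float)
    beat_starts = np.arange(0, n, beat_period_steps)
    flows = pd.DataFrame({c: zeros for c in (
        "q_mitral_ml_s", "q_aortic_ml_s", "q_tricuspid_ml_s", "q_pulmonic_ml_s")})
    return SimulationOutput(
        time=time, sap=sap, pap=pap, p_lv=zeros, v_lv=np.asarray(v_lv, float),
        p_la=p_la, t_heart=zeros + dt * beat_period_steps,
        valve_flows=flows, volumes=pd.DataFrame({"left_ventricle": v_lv}),
        total_volume=zeros + 5300.0, beat_starts=beat_starts, dt=dt,
        transient=0.0, steady_state_reached=True)
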
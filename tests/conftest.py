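import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest

import patchleak as pl


@pytest.fixture(scope="session")
def staircase():
    """Default staircase emulation: 1 s steps, 5 kHz, holding 0 mV."""
    return pl.staircase_protocol()


@pytest.fixture(scope="session")
def square3():
    """3-step square wave 0 / +40 / -80 mV, 1 s each, 1 kHz, no ramps."""
    rate = 1000.0
    v = np.concatenate(
        [np.full(1000, 0.0), np.full(1000, 40.0), np.full(1000, -80.0)]
    )
    t = np.arange(len(v)) / rate
    return pl.VoltageProtocol.from_samples(t, v)


@pytest.fixture(scope="session")
def linear_trace(staircase):
    """One noiseless, capacitance-free Ohmic trace (g=0.5 nS, E=0 mV)."""
    params = pl.scenario_params("linear", sigma=0.0, a_cap=0.0, seed=11)
    return pl.generate_trace(staircase, params)


@pytest.fixture(scope="session")
def scenario1_trace(staircase):
    params = pl.scenario_params("I", seed=5)
    return pl.generate_trace(staircase, params)
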
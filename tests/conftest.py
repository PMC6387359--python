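import dataclasses

import numpy as np
import pytest

from actipred import SimConfig, build_design, simulate_recording
from actipred.simulate import DEFAULT_PROTOCOL, DEFAULT_STATES


def scaled_protocol(factor):
    """The standard 8-segment day protocol with durations scaled down."""
    return tuple((s, d * factor) for s, d in DEFAULT_PROTOCOL)


def decoy_states():
    """State table with EDA decoupled from activity (EDA becomes a decoy)."""
    return {k: dataclasses.replace(v, eda_gain_uS=0.0)
            for k, v in DEFAULT_STATES.items()}


@pytest.fixture(scope="session")
def short_recording():
    """Three short days of the standard protocol (~10 min each)."""
    cfg = SimConfig(n_days=3, protocol=scaled_protocol(0.1))
    return simulate_recording(cfg, seed=7)


@pytest.fixture(scope="session")
def short_design(short_recording):
    return build_design(short_recording, delta_h=30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
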
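import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cavprime import CavParams, PrepulseSpec, build_prepulse_protocol, simulate_current


@pytest.fixture(scope="session")
def params():
    return CavParams()


def make_step(params, step_V=0.0, dur_ms=20.0, hold_V=-70.0, tail_ms=10.0):
    """Hold -> step -> hold command at params.dt."""
    spec = PrepulseSpec(hold_V=hold_V, pre_V=hold_V, pre_dur_ms=0.0, gap_ms=0.0,
                        test_V=step_V, test_dur_ms=dur_ms, pre_hold_ms=10.0,
                        tail_ms=tail_ms)
    return build_prepulse_protocol(spec, params)


@pytest.fixture(scope="session")
def step_response(params):
    """Canonical -70 -> 0 mV, 20 ms step and its simulated current."""
    stim = make_step(params)
    current, occ = simulate_current(stim, params)
    return stim, current, occ
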
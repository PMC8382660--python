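import numpy as np
import pytest

from diffbal import GoldbeterConfig, run_goldbeter_pipeline
from diffbal.systems import SteadyStateSamples


@pytest.fixture(scope="session")
def goldbeter_report():
    """Full Goldbeter pipeline under the default protocol, shared across
    the suite (simulation + LMIs + balancing + frequency diagnostics)."""
    return run_goldbeter_pipeline(GoldbeterConfig())


@pytest.fixture(scope="session")
def goldbeter_samples(goldbeter_report):
    return goldbeter_report["samples"]


def samples_at_states(system, states, rate):
    """SteadyStateSamples evaluated at an explicit list of states (for
    synthetic fixtures whose sampling region is chosen directly)."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    return SteadyStateSamples(
        sample_times=np.arange(float(len(states))),
        sample_states=states,
        jacobians=np.array([system.jacobian(x) for x in states]),
        rate_values=np.array([rate(x) for x in states]),
    )
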
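import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def warm_kernel():
    """Trigger the integrator's JIT compilation once, on a tiny run."""
    from photofenton import get_experiment, simulate
    from dataclasses import replace

    spec = replace(get_experiment("EXP4_PCT"), id="WARMUP", duration_min=0.1)
    simulate(spec, dt=0.05)
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
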
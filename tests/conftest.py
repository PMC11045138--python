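import numpy as np
import pytest

from bpwp.basis import build_frequency_mapping
from bpwp.sampling import DenseSeries, random_sample
from bpwp.synthetic import SimulationSpec, simulate_ied_series


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_sine_dense():
    """365 days at 4 samples/day: one 30-day oscillation plus mild noise."""
    spec = SimulationSpec(
        update_minutes=360.0,
        periods_days=(30.0,),
        amplitudes=(10.0,),
        phases=(0.0,),
        trend=(0.0, 5.0),
        noise_sd=1.0,
        seed=11,
    )
    return simulate_ied_series(spec)


@pytest.fixture(scope="session")
def small_grid(small_sine_dense):
    """Remapped grid matching the small dense series (N=1460, dt=0.25 d)."""
    d = small_sine_dense
    return build_frequency_mapping(d.N, d.dt, seed=0)


@pytest.fixture(scope="session")
def small_sampled(small_sine_dense):
    """Two samples per day drawn from the small series (m=730)."""
    return random_sample(small_sine_dense, 2.0, seed=5)
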
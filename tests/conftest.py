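import pytest

from mwicp.core import FrequencyGrid
from mwicp.io_sync import align_reference
from mwicp.preprocess import process_trial
from mwicp.synth import CouplingModel, SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def default_grid():
    return FrequencyGrid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse 2-6 GHz grid for cheap unit tests (20 MHz spacing)."""
    return FrequencyGrid(2.0, 6.0, 201)


@pytest.fixture(scope="session")
def fast_config(small_grid):
    """A short, cheap trial configuration with deterministic jitter."""
    return SimulationConfig(
        sensor_id="A",
        grid=small_grid,
        duration_s=30.0,
        ref_rate_hz=500.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def fast_trial(fast_config):
    return simulate_trial(fast_config)


@pytest.fixture(scope="session")
def processed_fast_trial(fast_trial):
    return process_trial(align_reference(fast_trial))


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, jitter-free trial on the full grid: analytic baseline."""
    return SimulationConfig(
        sensor_id="A",
        duration_s=10.0,
        lead_s=2.0,
        ref_rate_hz=500.0,
        trace_noise_db=0.0,
        trace_noise_phase_rad=0.0,
        ramp_curvature=0.0,
        lead_jitter_s=0.0,
        coupling=CouplingModel(
            alpha_mag_db_per_mmhg=0.0,
            beta_freq_mhz_per_mmhg=0.0,
            gamma_phase_rad_per_mmhg=0.0,
        ),
        seed=0,
    )
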
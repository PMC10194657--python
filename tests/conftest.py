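import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stridekit.pipeline import process_recording
from stridekit.simulator import NoiseModel, SimulationConfig, simulate_recording

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# noise matching the deployed fleet's reject ceilings plus a realistic
# constant gyro bias (0.05 dps) and mild insole/marker noise
PAPER_NOISE = NoiseModel(
    acc_std=3.31e-3 * 9.81,
    gyr_std=np.deg2rad(0.13),
    gyr_bias=(np.deg2rad(0.05),) * 3,
    pi_noise_std=1.0,
    marker_noise_std=0.001,
)


@pytest.fixture(scope="session")
def clean_cfg() -> SimulationConfig:
    return SimulationConfig(noise=NoiseModel.none(), seed=1)


@pytest.fixture(scope="session")
def clean_sim(clean_cfg):
    return simulate_recording(clean_cfg)


@pytest.fixture(scope="session")
def clean_result(clean_sim):
    rec, _ = clean_sim
    return process_recording(rec)


@pytest.fixture(scope="session")
def noisy_sim():
    return simulate_recording(SimulationConfig(noise=PAPER_NOISE, seed=7))


@pytest.fixture(scope="session")
def noisy_result(noisy_sim):
    rec, _ = noisy_sim
    return process_recording(rec)
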
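import warnings

import pytest
from hypothesis import HealthCheck, settings

from simfa.sifa import SIFARanks, em_fit
from simfa.synthetic import SimulationConfig, simulate_sifa_dataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-block simulated dataset with known truth (n=120)."""
    cfg = SimulationConfig(n=120, p=(15, 12), r0=1, r=(1, 1), seed=11, snr=3.0)
    ds, truth = simulate_sifa_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    _, ds, _ = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return em_fit(ds, SIFARanks(1, (1, 1)), seed=0)


@pytest.fixture(scope="session")
def study_shape_sim():
    """Four blocks mirroring the study's modality structure, reduced dims."""
    cfg = SimulationConfig(
        n=150, p=(40, 20, 20, 60), r0=2, r=(1, 1, 1, 1), seed=5, snr=2.0
    )
    ds, truth = simulate_sifa_dataset(cfg)
    return cfg, ds, truth
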
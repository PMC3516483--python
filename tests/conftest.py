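import pytest
from hypothesis import HealthCheck, settings

from nadphnet import ExperimentalDesign, calibrated_default_config, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """One full 1,344-row dataset from the calibrated default configuration."""
    return generate_dataset(calibrated_default_config(seed=1))


@pytest.fixture(scope="session")
def quiet_config():
    """Default config with all stochastic components switched off."""
    cfg = calibrated_default_config(seed=1)
    cfg.sd_background = 0.0
    cfg.sd_bottle = 0.0
    cfg.sd_residual = {k: 0.0 for k in cfg.sd_residual}
    return cfg


@pytest.fixture
def small_design():
    return ExperimentalDesign(
        genes=("Men",),
        backgrounds=("CT21", "HFL53", "JFL12"),
        samples_per_bottle_per_condition=2,
    )
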
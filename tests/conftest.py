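import numpy as np
import pytest
from hypothesis import settings

from algalink.feedback import ExperimentConfig, ScheduleConfig, run_experiment
from algalink.geometry import build_layout

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_config(**overrides) -> ExperimentConfig:
    """A fast, reduced-scale closed-loop configuration for unit tests."""
    defaults = dict(
        n_euglena=60,
        n_chlamy=180,
        schedule=ScheduleConfig(total_steps=80, warmup_steps=15, cooldown_steps=15),
        seed=7,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@pytest.fixture(scope="session")
def small_oscillation_log():
    """One reduced-scale oscillation run shared by structural tests."""
    cfg = small_config(n_euglena=100, n_chlamy=325,
                       schedule=ScheduleConfig(total_steps=400, warmup_steps=50,
                                               cooldown_steps=50),
                       threshold=0.10, seed=11)
    return run_experiment(cfg)
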
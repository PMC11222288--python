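import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pursuitlock import (PipelineConfig, SimulationParams, align_dataset,
                         build_epoch_set, make_trials)

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fast_cfg() -> PipelineConfig:
    # identity artifact stage: ICA adds minutes and is tested separately
    return PipelineConfig(artifact_strategy="identity")


@pytest.fixture(scope="session")
def target_trials():
    """16 simulated target trials at default conditions (shared, read-only)."""
    return make_trials(SimulationParams(n_trials=16, p_target=1.0, seed=5))


@pytest.fixture(scope="session")
def gaze_epochs(target_trials, fast_cfg):
    al = align_dataset(target_trials, "gaze", fast_cfg)
    return build_epoch_set(target_trials, al, fast_cfg)


@pytest.fixture(scope="session")
def trigger_epochs(target_trials, fast_cfg):
    al = align_dataset(target_trials, "trigger", fast_cfg)
    return build_epoch_set(target_trials, al, fast_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
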
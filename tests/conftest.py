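import numpy as np
import pytest

from revinfer.inference import ModelParams, simulate_responses
from revinfer.task import TaskConfig, generate_block_pair, realize_orientations

#: group-mean observer parameters fitted per condition (hazard, inference noise)
CB_PARAMS = ModelParams(h=0.191, sigma_inf=0.512)
OB_PARAMS = ModelParams(h=0.115, sigma_inf=0.550)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def task_config():
    return TaskConfig()


@pytest.fixture
def block_pair(task_config, rng):
    """One matched stable (Cb, Ob) block pair."""
    return generate_block_pair(task_config, "stable", rng)


@pytest.fixture
def simulated_block(task_config, rng):
    """A Cb block with noisy-observer responses and realized orientations."""
    cb, _ = generate_block_pair(task_config, "stable", rng)
    responses, beliefs = simulate_responses(CB_PARAMS, cb, rng)
    realize_orientations(cb, responses)
    return cb, responses, beliefs
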
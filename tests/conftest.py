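import numpy as np
import pytest

from rlwm import ModelParams, TaskConfig, build_test_pairs, generate_task, simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """One block per set size: quick to simulate, still exercises all set sizes."""
    return TaskConfig(blocks_per_set_size={2: 1, 3: 1, 4: 1, 5: 1})


@pytest.fixture
def default_params():
    return ModelParams(alpha_rl=0.02, gamma=0.5, phi=0.1, rho=0.9, wm_cap=3, nu=0.05)


@pytest.fixture
def small_session(small_config, default_params, rng):
    """(training, test, design) for one simulated subject on the small design."""
    design = generate_task(small_config, rng)
    design.test_pairs = build_test_pairs(design, 2, rng)
    train, test = simulate_subject(design, default_params, rng)
    return train, test, design
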
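import numpy as np
import pytest

import revlearn as rl
from revlearn.task import TaskConfig, generate_design


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def full_design(default_config):
    """One full 3-run x 4-block x 45-trial experiment, fixed seed."""
    return generate_design(default_config, seed=0)


@pytest.fixture(scope="session")
def small_design():
    """A single-run design for cheap closed-loop tests."""
    cfg = TaskConfig(n_runs=1, blocks_per_run=2)
    return generate_design(cfg, seed=11)


@pytest.fixture(scope="session")
def hgf_trials(full_design):
    """One HGF-simulated subject on the full design (moderate determinism)."""
    return rl.simulate("hgf", full_design, seed=42, omega=-2.5, zeta=2.0)


@pytest.fixture(scope="session")
def design_sequences(full_design):
    from revlearn.task import design_input_sequence

    return [design_input_sequence(b) for b in full_design]
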
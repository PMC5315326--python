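import numpy as np
import pytest

from cuematch import (
    RewardModel,
    TrainingConfig,
    generate_training_set,
    run_simulation1,
    run_simulation2,
)

FAST = TrainingConfig(epochs=250)


@pytest.fixture(scope="session")
def sim1_ts():
    """One independent-cue training set (0.2/0.4/0.6/0.8, 1600 trials)."""
    return generate_training_set(RewardModel.independent_preset(), replicates=100, seed=5)


@pytest.fixture(scope="session")
def sim1_run():
    """Independent-cue study at reduced scale: 2 sets x 10 nets, 250 epochs."""
    return run_simulation1(sets=2, nets_per_set=10, config=FAST, master_seed=101)


@pytest.fixture(scope="session")
def sim2_run():
    """Gated-cue factorial at reduced scale: 5 sets x 5 nets per cell."""
    return run_simulation2(sets_per_condition=5, nets_per_set=5, config=FAST, master_seed=202)
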
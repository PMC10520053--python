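"""Shared fixtures.

The expensive fixture here is the scaled-down end-to-end learning run
(saccadic sSNU, N=16, vertical symmetry, 768 training / 192 test
riddles). It is session-scoped so the learning acceptance check and the
introspection analysis share the same trained model. The suite trains one
seed end to end (the run is deterministic given the seed);
``scripts/acceptance.py`` repeats the same protocol under the caller's
seed.
"""

import numpy as np
import pytest

from oddity.harness import TrainConfig, train_model
from oddity.riddlegen import DatasetConfig, build_dataset

LEARNING_SEEDS = (1,)
LEARNING_THRESHOLD = 0.80
LEARNING_MAX_EPOCHS = 20


@pytest.fixture(scope="session")
def vertical_symmetry_data():
    """Separate-mode vertical-symmetry dataset: 768/192/192 split."""
    cfg = DatasetConfig(mode="separate", concepts=("vertical_symmetry",),
                        size=1152, seed=101)
    return build_dataset(cfg)


@pytest.fixture(scope="session")
def learning_runs(vertical_symmetry_data):
    """Train sSNU (N=16) saccadic models on vertical symmetry.

    Returns a list of (seed, model, history); each run stops early once
    the accuracy threshold is reached.
    """
    results = []
    for seed in LEARNING_SEEDS:
        cfg = TrainConfig(arch="saccadic", unit="ssnu", n=16,
                          epochs=LEARNING_MAX_EPOCHS, seed=seed,
                          stop_at_test_accuracy=LEARNING_THRESHOLD,
                          stop_after_seconds=1200, eval_val=False)
        model, hist = train_model(cfg, vertical_symmetry_data)
        results.append((seed, model, hist))
    return results
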
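"""Shared fixtures.

The expensive fixtures (the 400-sample dataset and the three trained
graders) are session-scoped because several acceptance criteria and
module tests reuse them; everything derived from them is deterministic,
so sharing does not couple the tests.
"""

import numpy as np
import pytest

from fundusgan.grader import train_grader
from fundusgan.synthetic import SynthConfig, generate_sample

GRADER_SEEDS = (7, 8, 9)


def make_dataset(n, seed, side=64):
    cfg = SynthConfig(side=side, n_samples=n, seed=seed)
    return [generate_sample(cfg, i) for i in range(n)]


@pytest.fixture(scope="session")
def dataset400():
    """400 synthetic samples at side 64, dataset seed 7."""
    return make_dataset(400, seed=7)


@pytest.fixture(scope="session")
def dataset40():
    """Small dataset for fast structural tests."""
    return make_dataset(40, seed=3)


@pytest.fixture(scope="session")
def graders(dataset400):
    """Graders trained on the 400-sample dataset, 30 epochs, 25% holdout,
    one per training seed; values are (model, holdout_report)."""
    return {seed: train_grader(dataset400, epochs=30, seed=seed,
                               holdout_fraction=0.25)
            for seed in GRADER_SEEDS}


@pytest.fixture(scope="session")
def quick_grader(dataset40):
    """Cheaply trained grader for tests that only need a non-degenerate
    trained model (not accuracy)."""
    model, _ = train_grader(dataset40, epochs=2, seed=3)
    return model


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 0.0
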
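import numpy as np
import pytest

from qsarval import ActivityPairs, ModelDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_pairs(rng):
    """Factory for seeded random activity pairs of a given length."""

    def make(n=12, corr_noise=0.3):
        x = rng.uniform(4.0, 9.0, n)
        y = x + rng.normal(0.0, corr_noise, n)
        return ActivityPairs(x, y)

    return make


@pytest.fixture
def tiny_dataset():
    """Small hand-built dataset: near-perfect train, noisier test."""
    train = ActivityPairs(
        [5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5],
        [5.12, 5.38, 6.08, 6.45, 7.05, 7.42, 8.15, 8.55],
        ids=tuple(f"T{i}" for i in range(8)),
    )
    test = ActivityPairs(
        [5.2, 6.2, 7.2, 8.2],
        [5.5, 6.0, 7.6, 8.0],
        ids=tuple(f"E{i}" for i in range(4)),
    )
    return ModelDataset(model_id="tiny", train=train, test=test)


@pytest.fixture
def dataset_csv(tmp_path, tiny_dataset):
    from qsarval import write_dataset

    path = tmp_path / "tiny.csv"
    write_dataset(tiny_dataset, path)
    return path
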
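"""Seeded synthetic model datasets with controlled error structure.

The generator emulates the (experimental, calculated) pair structure the
validation criteria consume — nothing upstream of it (no descriptors, no
refitting). Experimental activities are drawn uniformly over a stated
log-activity range; calculated activities are the truth plus a constant
bias plus noise, with an optional contaminated subset shifted by a fixed
amount to mimic outlier compounds. Every draw is fully determined by the
integer seed.

Defaults mirror a typical published model in the 44-model collection:
a 50-compound training set, 15 test compounds, a 4-log-unit activity
range, and residual noise of 0.3 log units with no bias or outliers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np

from .datasets import ModelDataset
from .exceptions import UsageError
from .pairs import ActivityPairs

__all__ = ["SyntheticSpec", "generate_dataset", "grid_scenarios"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic model dataset.

    noise_sd is the SD of the additive prediction noise (log-activity
    units); bias shifts every calculated value; outlier_fraction of each
    split (floored) is additionally shifted by outlier_shift. With
    ``heavy_tailed`` the noise is scaled Student-t with 3 degrees of
    freedom instead of Gaussian, emulating outlier-inflated error SDs.
    """

    n_train: int = 50
    n_test: int = 15
    activity_low: float = 4.0
    activity_high: float = 8.0
    noise_sd: float = 0.3
    bias: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 2.0
    heavy_tailed: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_train < 3 or self.n_test < 3:
            raise UsageError("n_train and n_test must each be at least 3")
        if not self.activity_high > self.activity_low:
            raise UsageError("activity_high must exceed activity_low")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be non-negative")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise UsageError("outlier_fraction must lie in [0, 1)")


def _noise(rng: np.random.Generator, spec: SyntheticSpec, n: int) -> np.ndarray:
    if spec.noise_sd == 0.0:
        return np.zeros(n)
    if spec.heavy_tailed:
        df = 3.0
        # scale t(3) to the requested SD (t df variance = df/(df-2))
        return rng.standard_t(df, n) * spec.noise_sd / math.sqrt(df / (df - 2.0))
    return rng.normal(0.0, spec.noise_sd, n)


def _split(rng, spec: SyntheticSpec, n: int, prefix: str) -> ActivityPairs:
    truth = rng.uniform(spec.activity_low, spec.activity_high, n)
    pred = truth + spec.bias + _noise(rng, spec, n)
    n_out = math.floor(spec.outlier_fraction * n)
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        pred[idx] += spec.outlier_shift
    return ActivityPairs(
        truth, pred, ids=tuple(f"{prefix}{i + 1}" for i in range(n))
    )


def generate_dataset(spec: SyntheticSpec) -> ModelDataset:
    """Generate one reproducible synthetic model dataset.

    The same spec (including seed) always yields a bitwise-identical
    dataset; train and test splits come from one seeded stream.
    """
    rng = np.random.default_rng(spec.seed)
    train = _split(rng, spec, spec.n_train, "T")
    test = _split(rng, spec, spec.n_test, "E")
    return ModelDataset(
        model_id=f"synthetic-seed{spec.seed}",
        train=train,
        test=test,
        source=f"synthetic: {spec}",
    )


def grid_scenarios(base: SyntheticSpec, varying: dict) -> list[ModelDataset]:
    """One dataset per point of a parameter grid.

    ``varying`` maps spec field names to value sequences; the grid is the
    Cartesian product in the given key order, and the dataset at linear
    index i uses seed ``base.seed + i``.
    """
    if not varying or any(len(v) == 0 for v in varying.values()):
        raise UsageError("parameter grid must be non-empty")
    unknown = set(varying) - set(base.__dataclass_fields__)
    if unknown:
        raise UsageError(f"unknown spec field(s) in grid: {sorted(unknown)}")
    datasets = []
    keys = list(varying)
    for i, combo in enumerate(itertools.product(*(varying[k] for k in keys))):
        spec = replace(base, **dict(zip(keys, combo)), seed=base.seed + i)
        datasets.append(generate_dataset(spec))
    return datasets
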
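import numpy as np
import pytest

from omicsmkl import (
    BlockConfig,
    FeatureBlock,
    MultiOmicsDataset,
    SyntheticConfig,
    generate_multiomics,
)


def make_dataset(blocks: dict, labels, value_kinds: dict | None = None):
    """Small in-memory dataset from {name: (array, feature_ids)} parts."""
    value_kinds = value_kinds or {}
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    return MultiOmicsDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
        blocks=[
            FeatureBlock(name, np.asarray(vals, dtype=float), list(fids),
                         value_kinds.get(name, "continuous"))
            for name, (vals, fids) in blocks.items()
        ],
    )


@pytest.fixture
def tiny_dataset():
    """3 samples, 2 blocks, both classes present."""
    rng = np.random.default_rng(0)
    labels = [1, -1, -1]
    return make_dataset(
        {
            "A": (rng.normal(size=(3, 4)), [f"a{j}" for j in range(4)]),
            "B": (rng.normal(size=(3, 2)), ["b0", "b1"]),
        },
        labels,
    )


def small_two_block_config(seed: int, n_samples: int = 80) -> SyntheticConfig:
    """Signal in one continuous block, pure noise in the other."""
    return SyntheticConfig(
        n_samples=n_samples,
        prevalence_positive=0.4,
        blocks=[
            BlockConfig("signal", "continuous", 30, n_informative=8, effect_size=1.5),
            BlockConfig("noise", "continuous", 30),
        ],
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_two_block():
    ds, truth = generate_multiomics(small_two_block_config(seed=11))
    return ds, truth
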
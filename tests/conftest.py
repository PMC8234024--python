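import numpy as np
import pytest

from ensemble_mfp.dataset_io import (
    DescriptorTable,
    InteractionMatrix,
    PairFeatureBlock,
    enumerate_pairs,
)
from ensemble_mfp.synthetic_data import SyntheticSpec, generate_benchmark, tiny_spec


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Fast 12x8 benchmark with 8/4-dimensional descriptors."""
    return generate_benchmark(tiny_spec(seed=7))


@pytest.fixture(scope="session")
def default_benchmark():
    """Default-profile benchmark (54 drugs x 26 targets, full descriptor dims)."""
    return generate_benchmark(SyntheticSpec(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    values = np.array([[1, 0, 0], [0, 1, 1], [0, 0, 0], [1, 1, 0]], dtype=np.int8)
    return InteractionMatrix([f"d{i}" for i in range(4)], [f"t{j}" for j in range(3)], values)


def random_block(rng, n, d, fp_id="fp1"):
    pairs = [(f"d{i:03d}", f"t{i:03d}") for i in range(n)]
    return PairFeatureBlock(pairs, rng.normal(size=(n, d)), fp_id)
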
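import pytest

from pairddg.synthetic import SyntheticConfig, generate_dataset, shift_benchmark_config


@pytest.fixture(scope="session")
def small_world():
    """Small synthetic dataset + ground truth for fast unit tests.

    64-d embeddings keep featurization cheap; structure (groups, mutations,
    ligand pool, offsets, noise) matches the full benchmark generator.
    """
    cfg = SyntheticConfig(
        n_groups=6, records_per_group=10, seq_len=50, embed_dim=64, seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def benchmark_world():
    """The full-scale shift benchmark: 20 groups x 30 records, tau=3,
    sigma=0.5, 1280-d embeddings.  Generated once per session; features are
    cached on the ground-truth object."""
    return generate_dataset(shift_benchmark_config(seed=0))


@pytest.fixture(scope="session")
def small_dataset(small_world):
    return small_world[0]


@pytest.fixture(scope="session")
def small_truth(small_world):
    return small_world[1]
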
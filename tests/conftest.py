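import numpy as np
import pytest

import cgpromoter as cg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """Random 16 x 5 property table."""
    return cg.PropertyTable(rng.normal(size=(16, 5)))


@pytest.fixture
def stats_map(small_table):
    return cg.compute_dinuc_stats(small_table)


@pytest.fixture(scope="session")
def motif_study():
    """A small strong-motif study: dataset, property table, encoded matrix.

    Shared across model/evaluation tests to avoid re-encoding; treat as
    read-only.
    """
    spec = cg.SyntheticSpec(n_pos=100, n_neg=100, seed=7)
    table = cg.generate_property_table(spec)
    dataset = cg.generate_dataset(spec)
    stats = cg.compute_dinuc_stats(table)
    matrix = cg.encode_dataset(dataset, stats)
    return spec, dataset, table, matrix


def random_labeled_matrix(rng, n=20, d=10):
    """Random two-class feature matrix for selector/ANOVA tests."""
    values = rng.normal(size=(n, d))
    labels = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    return cg.FeatureMatrix(values, [f"f{j}" for j in range(d)], labels=labels)
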
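import numpy as np
import pytest

from colonyqc import SyntheticFeatureSpec, generate_feature_table


@pytest.fixture(scope="session")
def blobs60():
    """N=60, d=8, classes 20/20/20, means 10 x sd apart: the well-separated
    benchmark table used by protocol and recovery tests."""
    return generate_feature_table(
        SyntheticFeatureSpec(n_per_class=(20, 20, 20), dim=8, seed=1)
    )


@pytest.fixture(scope="session")
def blobs_small():
    """Tiny separable table (N=15, d=4) for fast unit-level protocol tests."""
    return generate_feature_table(
        SyntheticFeatureSpec(n_per_class=(5, 5, 5), dim=4, seed=7)
    )


@pytest.fixture(scope="session")
def table_shaped():
    """A table with the benchmark composition 41/74/58 (bad/good/semigood)."""
    return generate_feature_table(SyntheticFeatureSpec(dim=8, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
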
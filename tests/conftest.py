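import numpy as np
import pytest

from cavenet import tables


@pytest.fixture
def toy_table():
    """4 features x 5 samples with hand-checkable abundances."""
    counts = np.array(
        [
            [10, 10, 10, 10, 10],  # abundant, everywhere
            [0, 0, 0, 0, 5],  # present in 1/5 samples
            [1, 1, 1, 1, 1],  # rare, everywhere
            [89, 89, 89, 89, 84],  # dominant
        ]
    )
    return tables.FeatureTable(["fA", "fB", "fC", "fD"], [f"s{i}" for i in range(5)], counts)


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(2, 0.02, size=(30, 8))
    counts[:, 0] += 1  # no all-zero sample
    return tables.FeatureTable(
        [f"f{i}" for i in range(30)], [f"s{j}" for j in range(8)], counts
    )
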
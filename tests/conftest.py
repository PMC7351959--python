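import numpy as np
import pandas as pd
import pytest

from sinktrack.feature_table import FeatureTable, from_arrays
from sinktrack.metadata import SampleMetadata


@pytest.fixture
def tiny_table() -> FeatureTable:
    """3 taxa x 2 samples with column sums (10, 5)."""
    return from_arrays(
        np.array([[4, 2], [5, 0], [1, 3]]), ["t1", "t2", "t3"], ["s1", "s2"]
    )


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "role": ["source", "sink"],
                "env": ["EnvA", "Meat Truck"],
                "position": [pd.NA, "Truck"],
                "sample_type": ["surface", "meat"],
            },
            index=["s1", "s2"],
        )
    )


def random_table(rng: np.random.Generator, n_taxa=6, n_samples=4, max_count=50):
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    taxa = [f"ASV_{i:03d}" for i in range(n_taxa)]
    samples = [f"S{i}" for i in range(n_samples)]
    return from_arrays(counts, taxa, samples)
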
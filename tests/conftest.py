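import numpy as np
import pytest

from regatlas.exprio import ExpressionMatrix, SampleMetadata, average_replicates, scale_per_gene
from regatlas.synthetic import AtlasConfig, generate_atlas


@pytest.fixture(scope="session")
def default_atlas():
    """One default-config atlas shared across read-only tests."""
    return generate_atlas(AtlasConfig(seed=7))


@pytest.fixture(scope="session")
def low_noise_atlas():
    return generate_atlas(AtlasConfig(noise_sd=0.05, seed=7))


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples (2 regions x 2 replicates), hand-sized."""
    samples = [
        SampleMetadata("A_1", "A", "g1", 1),
        SampleMetadata("A_2", "A", "g1", 2),
        SampleMetadata("B_1", "B", "g2", 1),
        SampleMetadata("B_2", "B", "g2", 2),
    ]
    values = np.array(
        [
            [4.0, 6.0, 1.0, 3.0],
            [10.0, 10.0, 20.0, 20.0],
            [0.0, 0.0, 5.0, 5.0],
        ]
    )
    return ExpressionMatrix(values, ["g1", "g2", "g3"], samples)


@pytest.fixture(scope="session")
def default_profile(default_atlas):
    matrix, _ = default_atlas
    return average_replicates(matrix)


@pytest.fixture(scope="session")
def default_scaled(default_profile):
    return scale_per_gene(default_profile)
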
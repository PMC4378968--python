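import numpy as np
import pytest

from ahpfsam.dataio import ExpressionDataset
from ahpfsam.synthetic import SyntheticSpec, generate


@pytest.fixture
def tiny_dataset():
    """4 samples, 3 genes, labels [0, 0, 1, 1]; gene g2 separates classes."""
    matrix = np.array([
        [1.0, 2.0, 1.5, 2.5],   # uninformative
        [5.0, 5.1, 4.9, 5.0],   # near-constant
        [1.0, 2.0, 9.0, 10.0],  # separates the classes
    ])
    return ExpressionDataset(
        matrix,
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=np.array([0, 0, 1, 1]),
    )


@pytest.fixture(scope="session")
def separable_fixture():
    """200 genes x 60 samples, 5 informative at 3 sigma (study conditions)."""
    return generate(SyntheticSpec(
        n_genes=200, n_samples=60, n_informative=5, effect_size=3.0, seed=7,
    ))
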
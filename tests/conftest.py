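import numpy as np
import pytest

from tissueclass import (
    ClassifierParams,
    SyntheticSpec,
    aggregate_to_tissue,
    classify_matrix,
    generate_atlas,
)


@pytest.fixture(scope="session")
def params():
    return ClassifierParams()


@pytest.fixture(scope="session")
def small_atlas():
    """A quick noisy atlas shared by tests that only need realistic structure."""
    spec = SyntheticSpec(n_genes=400, n_tissues=16, replicates_per_tissue=4, seed=11)
    return generate_atlas(spec)


@pytest.fixture(scope="session")
def small_atlas_classified(small_atlas, params):
    matrix, manifest, truth = small_atlas
    expr = aggregate_to_tissue(matrix, manifest)
    return expr, classify_matrix(expr, params), truth


def random_profiles(rng: np.random.Generator, n_genes: int, n_tissues: int) -> np.ndarray:
    """Heterogeneous random FPKM profiles that exercise all six categories:
    broad log-normal levels with random drop-out and occasional spikes."""
    values = rng.lognormal(mean=1.0, sigma=1.5, size=(n_genes, n_tissues))
    off = rng.random((n_genes, n_tissues)) < rng.beta(1, 3, size=(n_genes, 1))
    values[off] *= 0.01
    spikes = rng.random(n_genes) < 0.3
    cols = rng.integers(0, n_tissues, size=n_genes)
    values[spikes, cols[spikes]] *= rng.uniform(1, 30, size=spikes.sum())
    return values
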
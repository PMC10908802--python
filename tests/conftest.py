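import numpy as np
import pytest

from tumortag import AnnotationTable, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_counts(rng, n_cells=100, n_genes=50, prefix="c"):
    """Random raw-count matrix with positive cell totals."""
    values = rng.poisson(3.0, size=(n_cells, n_genes)).astype(float)
    values[:, 0] += 1  # guarantee nonzero totals
    return ExpressionMatrix(
        values,
        [f"{prefix}{i}" for i in range(n_cells)],
        [f"g{j}" for j in range(n_genes)],
        "raw_counts",
    )


def random_annotations(rng, n_cells=100, n_domains=4, prefix="c"):
    labels = rng.integers(0, 2, size=n_cells)
    labels[:2] = [0, 1]  # ensure both classes exist
    domains = [f"tissue{int(i)}" for i in rng.integers(0, n_domains, size=n_cells)]
    return AnnotationTable([f"{prefix}{i}" for i in range(n_cells)], labels, domains)


@pytest.fixture
def counts_100x50(rng):
    return random_counts(rng)


@pytest.fixture
def annotations_100(rng):
    return random_annotations(rng)
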
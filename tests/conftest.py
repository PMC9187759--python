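import numpy as np
import pandas as pd
import pytest

from tnbcstrat import (
    ExpressionMatrix,
    cohort_gene_sets,
    generate_cohort,
    normalize_expression,
)


@pytest.fixture(scope="session")
def cohort100():
    """Seeded 100-sample cohort: (raw matrix, clinical, truth)."""
    return generate_cohort(n_samples=100, seed=42)


@pytest.fixture(scope="session")
def norm100(cohort100):
    matrix, _, _ = cohort100
    return normalize_expression(matrix)


@pytest.fixture(scope="session")
def gene_sets():
    return cohort_gene_sets()


@pytest.fixture
def small_matrix():
    """3 genes x 2 samples raw matrix with easy hand arithmetic."""
    return ExpressionMatrix(
        pd.DataFrame(
            {"s1": [1.0, 2.0, 4.0], "s2": [8.0, 2.0, 16.0]},
            index=["g1", "g2", "g3"],
        ),
        stage="raw",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
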
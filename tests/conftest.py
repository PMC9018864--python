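import numpy as np
import pandas as pd
import pytest

from scnctype.expr_io import RawCountMatrix
from scnctype.simulate import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts(rng):
    """8 genes x 4 samples of negative-binomial counts."""
    counts = rng.negative_binomial(10, 0.3, size=(8, 4))
    return RawCountMatrix(
        genes=[f"G{i}" for i in range(8)],
        samples=[f"S{j}" for j in range(4)],
        counts=counts,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort at the fixed default seed."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast integration tests."""
    spec = CohortSpec(
        seed=7, n_patients=30, n_samples=40, n_genes=900, n_pathways=60,
        n_nev2_pathways=20,
    )
    return generate_cohort(spec)


@pytest.fixture
def random_expr(rng):
    """200 genes x 10 samples of positive expression values."""
    vals = rng.lognormal(2.0, 1.0, size=(200, 10))
    return pd.DataFrame(
        np.log2(vals + 1),
        index=[f"G{i:03d}" for i in range(200)],
        columns=[f"S{j}" for j in range(10)],
    )
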
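import numpy as np
import pytest

from gutmaz.io_core import OtuTable, TaxonomyMap
from gutmaz.synthetic_cohort import CohortSpec, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return OtuTable(
        ["s1", "s2", "s3"],
        ["o1", "o2", "o3", "o4"],
        np.array([[10, 5, 5, 0], [0, 20, 0, 10], [3, 3, 3, 3]]),
    )


@pytest.fixture
def small_taxonomy():
    return TaxonomyMap(
        {
            "o1": {"kingdom": "Bacteria", "genus": "G1"},
            "o2": {"kingdom": "Bacteria", "genus": "G1"},
            "o3": {"kingdom": "Bacteria", "genus": "G2"},
            # o4 deliberately unassigned
        }
    )


@pytest.fixture
def random_table(rng):
    counts = rng.integers(0, 50, size=(20, 50))
    counts[:, 0] += 1  # avoid zero-depth rows
    return OtuTable(
        [f"s{i}" for i in range(20)],
        [f"o{j}" for j in range(50)],
        counts,
    )


@pytest.fixture(scope="session")
def healthy_cohort():
    """Healthy-only cohort reused by maturity tests (module-scope cache)."""
    spec = CohortSpec(
        n_samples=400, disease_prevalence=0.01, age_range=(0.0, 18.0), seed=11
    )
    return simulate_counts(spec)
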
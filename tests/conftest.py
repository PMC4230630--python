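import numpy as np
import pandas as pd
import pytest

from hapcc import studydata
from hapcc.genotypes import GenotypeDataset, Marker
from hapcc.synthetic_data import default_scenario, generate_dataset


@pytest.fixture(scope="session")
def markers():
    return studydata.MARKERS


@pytest.fixture(scope="session")
def table_counts():
    """Published diffuse/control genotype counts per marker."""
    return studydata.GENOTYPE_COUNTS


@pytest.fixture(scope="session")
def counts_dataset():
    """Dataset whose per-marker counts match the published tables."""
    return studydata.counts_dataset()


@pytest.fixture(scope="session")
def small_synthetic():
    """A study-sized synthetic dataset from the default scenario."""
    return generate_dataset(default_scenario(seed=11))


def make_dataset(markers, genotype_rows, statuses=None):
    """Build a dataset from explicit genotype tuples (test helper)."""
    n = len(genotype_rows)
    statuses = statuses or ["control"] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "status": statuses,
            "subtype": ["none"] * n,
            "age": [np.nan] * n,
            "sex": [None] * n,
        }
    )
    genos = np.empty((n, len(markers)), dtype=object)
    for i, row in enumerate(genotype_rows):
        genos[i, :] = [m.normalize_pair(g) for m, g in zip(markers, row)]
    return GenotypeDataset(markers=list(markers), samples=samples, genotypes=genos)


@pytest.fixture
def two_locus_markers():
    return [Marker("L1", "A", "a"), Marker("L2", "B", "b")]
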
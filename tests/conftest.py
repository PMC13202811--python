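import numpy as np
import pandas as pd
import pytest

from nasepi.containers import CountMatrix, TAXONOMY_RANKS
from nasepi.simulate import CohortParams, generate_cohort


def make_counts(values, taxa=None, samples=None, taxonomy=None) -> CountMatrix:
    values = np.asarray(values)
    taxa = taxa or [f"OTU{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    counts = pd.DataFrame(values, index=pd.Index(taxa, name="taxon_id"),
                          columns=samples)
    if taxonomy is not None:
        taxonomy = pd.DataFrame(taxonomy).T.reindex(columns=TAXONOMY_RANKS, fill_value="")
        taxonomy.index.name = "taxon_id"
    return CountMatrix(counts, taxonomy)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-sample, 600-CpG cohort shared by the slower integration tests."""
    return generate_cohort(
        CohortParams(
            n_samples=120,
            n_cpgs=600,
            cluster_weights=(0.30, 0.22, 0.21, 0.11, 0.09, 0.07),
            seed=20260926,
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size cohort at the default study conditions."""
    return generate_cohort(CohortParams(seed=42))
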
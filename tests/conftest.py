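import pandas as pd
import pytest

from mpnstkit.copynumber import map_genes_to_cn
from mpnstkit.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across the suite."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_gene_cn(default_cohort):
    return map_genes_to_cn(default_cohort.segmented_profiles,
                           default_cohort.gene_models)


@pytest.fixture(scope="session")
def truth_subtypes(default_cohort) -> pd.Series:
    return default_cohort.truth.samples.set_index("sample")["subtype"]
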
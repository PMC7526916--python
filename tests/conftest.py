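import numpy as np
import pytest

from brcalike.synthetic import CohortConfig, GroupSpec, generate_cohort, generate_signature_matrix


@pytest.fixture(scope="session")
def small_signatures():
    """Five well-separated sparse signatures."""
    return generate_signature_matrix(5, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient cohort with one enriched group and one null group."""
    cfg = CohortConfig(
        n_patients=120,
        n_signatures=8,
        n_genes_expression=30,
        group_specs=(
            GroupSpec("BRCA1", "germline_mutation", 8, 0.6, 0),
            GroupSpec("BRCA2", "hypermethylation", 6, 0.6, 0),
            GroupSpec("BARD1", "somatic_mutation", 10, 0.6, 1),
            GroupSpec("ATM", "somatic_mutation", 8, 0.0, 2),
        ),
        mutations_per_tumor=400,
        seed=17,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
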
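import numpy as np
import pytest

from keynet.synthetic_data import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared across tests (planted defaults, 300 genes)."""
    return generate_cohort(SimConfig(n_samples=150, n_genes_per_tissue=300, seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """No planted DE and no mediation chain: cases == controls in law."""
    return generate_cohort(
        SimConfig(
            n_samples=150,
            n_genes_per_tissue=300,
            de_log_fold_change=0.0,
            mediation_a=0.0,
            mediation_b=0.0,
            direct_c=0.0,
            seed=12,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
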
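import numpy as np
import pandas as pd
import pytest

from haqtl.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-tissue cohort with strong planted effects, reused across tests."""
    cfg = SimConfig(
        n_individuals_per_tissue={"t1": 80, "t2": 80},
        n_variants=200,
        n_ares=40,
        n_genes=15,
        haqtl_effect_sd=1.0,
        eqtl_effect_sd=1.0,
        seed=11,
    )
    return simulate_cohort(cfg, with_gwas=True, gwas_shared_fraction=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_ares():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100, 1000, 500],
            "end": [200, 1200, 700],
            "are_id": ["a1", "a2", "a3"],
        }
    )
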
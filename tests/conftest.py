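import numpy as np
import pytest

import vitdgwas as vg


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-ancestry cohort with one planted additive QTL, reused read-only."""
    cfg = vg.SimConfig(
        n_per_ancestry={"EUR": 600, "AFR": 600},
        m_variants=300,
        fst={"EUR": 0.1, "AFR": 0.1},
        ld_block_size=10,
        ld_rho=0.4,
        causal_additive=[(42, 0.25)],
        month_variance_frac=0.1,
        skin_effect_sd=-0.1,
        seed=1234,
    )
    geno, cohort, truth, freqs = vg.simulate_cohort(cfg)
    return cfg, geno, cohort, truth, freqs


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
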
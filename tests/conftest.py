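import numpy as np
import pytest

from sexqtl.simulate import SimConfig, simulate_expression, simulate_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """A ~400-sample cohort with planted effects, shared across tests."""
    cfg = SimConfig(
        n_samples=400, n_genes=12, snps_per_gene=8, fraction_x_genes=0.25,
        n_x_background=100, sex_effect_fraction=0.3, cis_fraction=0.5,
        interaction_fraction=0.2, n_hidden_factors=2, seed=42,
    )
    rng = np.random.default_rng(cfg.seed)
    g, sex, genes = simulate_genotypes(cfg, rng=rng)
    e, truth = simulate_expression(g, cfg, sex, genes, rng)
    return {"cfg": cfg, "g": g, "sex": sex, "genes": genes, "e": e, "truth": truth}


@pytest.fixture()
def sample_table(small_cohort):
    from sexqtl.simulate import simulate_metadata

    rng = np.random.default_rng(7)
    return simulate_metadata(
        small_cohort["cfg"], small_cohort["sex"], small_cohort["g"].sample_ids, rng
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
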
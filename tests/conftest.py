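import numpy as np
import pytest

import annofine as af


@pytest.fixture(scope="session")
def geno_cfg():
    return af.SimConfig(
        seed=1, n_blocks=3, n_variants=10, n_samples=600, rho=0.6,
        block_prior=1.0, effect_sd=0.3,
    )


@pytest.fixture(scope="session")
def geno_panel(geno_cfg):
    return af.simulate_reference_panel(geno_cfg)


@pytest.fixture(scope="session")
def geno_study(geno_cfg, geno_panel):
    """Panel + truth + genotype-backed marginal stats + the exact phenotype."""
    ann = af.simulate_annotations(geno_cfg, geno_panel)
    truth = af.simulate_causal_architecture(geno_cfg, ann, geno_panel, seed=12)
    stats = af.simulate_gwas_sumstats(geno_panel, truth, geno_cfg, mode="genotype", seed=42)
    # regenerate the phenotype the generator used (same seed, same draw order)
    rng = np.random.default_rng(42)
    G = geno_panel.genotypes.astype(float)
    y = rng.standard_normal(G.shape[0])
    for vid, eff in zip(truth.causal_ids, truth.causal_effects):
        y = y + eff * G[:, geno_panel.indices([vid])[0]]
    return geno_panel, truth, stats, y


@pytest.fixture(scope="session")
def single_block_panel():
    cfg = af.SimConfig(seed=9, n_blocks=1, n_variants=20, rho=0.9, block_prior=1.0)
    return cfg, af.analytic_panel(cfg)
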
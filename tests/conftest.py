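import numpy as np
import pytest

import rvpower as rv


@pytest.fixture(scope="session")
def mini_pool() -> rv.HaplotypePool:
    """Small but realistic haplotype pool shared by fast unit tests."""
    return rv.simulate_haplotype_pool(n_haplotypes=2000,
                                      region_length=50_000.0, seed=3)


@pytest.fixture(scope="session")
def mini_gene(mini_pool) -> rv.GeneReplicate:
    gene, _ = rv.sample_gene_replicate(mini_pool, n_individuals=500, seed=11)
    return gene


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_pheno(gene, seed=0, **cfg_kwargs):
    """Null-model phenotype for a gene (no causal variants)."""
    cfg = rv.ScenarioConfig(causal_fraction=0.0, c=0.0,
                            n=gene.n_individuals, m=1, seed=seed,
                            **cfg_kwargs)
    eff = rv.EffectAssignment(np.empty(0, dtype=np.intp), np.empty(0))
    return rv.generate_quantitative_trait(gene, eff, cfg, seed)
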
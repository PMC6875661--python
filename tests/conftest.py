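import numpy as np
import pytest

from invadapt import synthetic as syn


@pytest.fixture(scope="session")
def env6():
    """Six-layer environmental stack shared across tests."""
    return syn.make_env_stack(6, (60, 60), spatial_range=6.0, seed=2)


@pytest.fixture(scope="session")
def null_genotypes():
    """Structure-only genotype matrix (no planted clines)."""
    G, truth = syn.simulate_genotypes(
        n_pops=60, n_per_pop=8, n_snps=800, baseline_fst=0.10,
        n_causal=0, missing_rate=0.185, seed=51,
    )
    return G, truth


@pytest.fixture(scope="session")
def cline_genotypes():
    """Genotype matrix with 12 planted cline loci on PRJ (strength 3)."""
    G, truth = syn.simulate_genotypes(
        n_pops=60, n_per_pop=8, n_snps=800, baseline_fst=0.10,
        n_causal=12, cline_predictor="PRJ", cline_strength=3.0,
        missing_rate=0.185, seed=53,
    )
    return G, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
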
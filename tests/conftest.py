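import numpy as np
import pytest

from pansyn.simulate import (
    AdmixSimConfig,
    CrossSimConfig,
    PangenomeSimConfig,
    simulate_admixture_panel,
    simulate_f1_cross,
    simulate_pangenome,
)


@pytest.fixture(scope="session")
def small_pangenome():
    """Four WGD genomes, two ancestral chromosomes, no noise."""
    return simulate_pangenome(
        PangenomeSimConfig(
            n_chroms=2, genes_per_chrom=60, n_genomes=4, wgd=True, seed=101
        )
    )


@pytest.fixture(scope="session")
def pav_pangenome():
    """Four WGD genomes with gene loss, private genes and tandem arrays."""
    return simulate_pangenome(
        PangenomeSimConfig(
            n_chroms=2, genes_per_chrom=60, n_genomes=4, wgd=True,
            pav_rate=0.08, private_rate=0.02, tandem_rate=0.03, seed=102,
        )
    )


@pytest.fixture(scope="session")
def diagnostic_panel():
    """Fixed-difference admixture panel with one large planted donor block
    flanked by background runs longer than the culling threshold."""
    return simulate_admixture_panel(
        AdmixSimConfig(
            n_sources=4, n_markers=2000, fst_like_divergence=1.5,
            donor_blocks=[(0, (600, 1299))], n_relatives=2, seed=103,
        )
    )


@pytest.fixture(scope="session")
def f1_cross():
    """Error-free 143-progeny pseudo-testcross with a 50%-variance QTL."""
    return simulate_f1_cross(
        CrossSimConfig(
            n_progeny=143, n_markers=200, qtl=(0, 40.0, 0.5),
            genotyping_error=0.0, seed=104,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
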
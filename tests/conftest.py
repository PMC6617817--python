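import numpy as np
import pytest

from ucekit.synthetic_suite import ParalogSpec, SuiteConfig, generate_suite


@pytest.fixture(scope="session")
def small_suite():
    """5 taxa x 60 kb, 12 loci, 2.5% per-taxon divergence, no paralogs."""
    cfg = SuiteConfig(
        taxa=["t1", "t2", "t3", "t4", "t5"],
        genome_length=60_000,
        n_loci=12,
        core_length=300,
        flank_length=200,
        divergence=0.025,
        seed=11,
    )
    return generate_suite(cfg)


@pytest.fixture(scope="session")
def paralog_suite():
    """4 taxa, one locus duplicated in taxon t3 at low copy divergence."""
    cfg = SuiteConfig(
        taxa=["t1", "t2", "t3", "t4"],
        genome_length=50_000,
        n_loci=8,
        core_length=300,
        flank_length=150,
        divergence=0.02,
        paralogs=(ParalogSpec(2, "t3", copy_divergence=0.01),),
        seed=7,
    )
    return generate_suite(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
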
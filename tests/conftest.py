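import pytest

from methkit.simulate import SimConfig, simulate_genome, simulate_methylome


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small two-condition study: ~50 kb genome, 30 genes, +10-point effect."""
    return SimConfig(
        genome_length=50_000,
        n_chromosomes=2,
        n_genes=30,
        effect_size=10.0,
        affected_fraction=1.0,
        depth_mean=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_reports(small_cfg, small_genome):
    sequences, genes = small_genome
    control, truth_c = simulate_methylome(small_cfg, sequences, genes, "control")
    treated, truth_t = simulate_methylome(small_cfg, sequences, genes, "treated")
    return {"control": (control, truth_c), "treated": (treated, truth_t)}
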
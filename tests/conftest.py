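import numpy as np
import pytest

from mirounga.io import GenotypeMatrix, VariantAnnotation


@pytest.fixture
def gm_factory():
    """Build a small GenotypeMatrix from a (n_samples, n_sites) array.

    Positions default to 10-kb spacing on a single contig sized to fit.
    """

    def make(
        genotypes,
        positions=None,
        contig="chr1",
        contig_length=None,
        annotations=None,
        sample_ids=None,
    ):
        g = np.asarray(genotypes, dtype=np.int8)
        n_samples, n_sites = g.shape
        if positions is None:
            positions = np.arange(1, n_sites + 1) * 10_000
        positions = np.asarray(positions, dtype=np.int64)
        if contig_length is None:
            contig_length = int(positions.max() + 10_000) if n_sites else 10_000
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(n_samples)]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            contigs=[(contig, contig_length)],
            chrom=np.array([contig] * n_sites, dtype=object),
            pos=positions,
            ref=np.array(["A"] * n_sites, dtype=object),
            alt=np.array(["G"] * n_sites, dtype=object),
            genotypes=g,
            annotations=annotations,
        )

    return make


@pytest.fixture(scope="session")
def bottleneck_sim():
    """One medium bottleneck simulation shared across tests."""
    from mirounga.simulate import SimConfig, simulate_population

    cfg = SimConfig(
        seed=11,
        n_chromosomes=10,
        n_sites=200,
        n_anc=100,
        n_bottleneck=12,
        bottleneck_duration=3,
        growth_rate=0.7,
        final_n=80,
        burnin_generations=4,
        post_generations=2,
        n_sample_pre=12,
    )
    gm, truth = simulate_population(cfg)
    return cfg, gm, truth
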
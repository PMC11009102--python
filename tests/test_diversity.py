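"""Site filter, heterozygosity windows, and the ROH caller against a
directly-coded reference scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirounga.diversity import (
    RohParams,
    call_roh,
    f_roh,
    filter_sites,
    genome_heterozygosity,
    roh_result,
    windowed_heterozygosity,
)
from mirounga.io import MISSING


# ---------------------------------------------------------------------------
# Reference ROH scan: a literal, loop-based transcription of the definition,
# kept independent of the package implementation.
# ---------------------------------------------------------------------------

def reference_roh(pos, geno, params):
    n = len(pos)
    w = params.window_snps
    if n == 0:
        return []
    is_het = [g == 1 for g in geno]
    is_mis = [g == MISSING for g in geno]
    if n < w:
        windows = [list(range(n))]
    else:
        windows = [list(range(s, s + w)) for s in range(n - w + 1)]
    passing = []
    for win in windows:
        het = sum(is_het[i] for i in win)
        mis = sum(is_mis[i] for i in win)
        passing.append(het <= params.max_het and mis <= params.max_missing)
    eligible = []
    for i in range(n):
        covering = [k for k, win in enumerate(windows) if win[0] <= i <= win[-1]]
        hits = sum(passing[k] for k in covering)
        eligible.append(hits / len(covering) >= params.hit_threshold)
    segments = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        starts = [i]
        for k in range(i, j):
            if pos[k + 1] - pos[k] > params.max_gap_kb * 1000:
                starts.append(k + 1)
        bounds = starts + [j + 1]
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_snp = b - a
            length = pos[b - 1] - pos[a] + 1
            if (
                n_snp >= params.min_snps
                and length >= params.min_length_kb * 1000
                and length / n_snp <= params.max_density_kb_per_snp * 1000
            ):
                segments.append((int(pos[a]), int(pos[b - 1]), n_snp))
        i = j + 1
    return segments


def _random_instance(rng, n_snps, p_het=0.15, p_mis=0.05, spacing=2000):
    gaps = rng.integers(1, spacing, n_snps)
    pos = np.cumsum(gaps)
    u = rng.random(n_snps)
    geno = np.where(u < p_het, 1, np.where(u < p_het + p_mis, MISSING, rng.integers(0, 2, n_snps) * 2))
    return pos.astype(np.int64), geno.astype(np.int8)


@pytest.mark.parametrize("trial", range(12))
def test_roh_caller_matches_reference_scan(gm_factory, trial):
    """Randomized equivalence of the vectorized caller and the direct scan."""
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(30, 600))
    params = RohParams(
        window_snps=int(rng.integers(5, 40)),
        max_het=int(rng.integers(0, 3)),
        max_missing=int(rng.integers(0, 4)),
        hit_threshold=float(rng.uniform(0.05, 1.0)),
        min_snps=int(rng.integers(2, 20)),
        min_length_kb=float(rng.uniform(5, 60)),
        max_gap_kb=float(rng.uniform(10, 200)),
        max_density_kb_per_snp=float(rng.uniform(5, 100)),
    )
    pos, geno = _random_instance(rng, n)
    gm = gm_factory(geno[None, :], positions=pos)
    got = [(s.start, s.end, s.n_snps) for s in call_roh(gm, "S0", params)]
    want = reference_roh(pos.tolist(), geno.tolist(), params)
    assert got == want


def test_roh_trivial_cases(gm_factory):
    params = RohParams(window_snps=10, max_het=1, max_missing=2, min_snps=5,
                       min_length_kb=100, max_density_kb_per_snp=1000)
    # all heterozygous: no segments
    gm = gm_factory(np.ones((1, 200), dtype=np.int8))
    assert call_roh(gm, "S0", params) == []
    # fully homozygous 2-Mb contig: one segment spanning all SNPs
    pos = np.arange(1, 201) * 10_000
    gm = gm_factory(np.zeros((1, 200), dtype=np.int8), positions=pos, contig_length=2_000_000)
    segs = call_roh(gm, "S0", params)
    assert len(segs) == 1
    assert (segs[0].start, segs[0].end, segs[0].n_snps) == (10_000, 2_000_000, 200)


def test_roh_monotonicity(gm_factory):
    """Raising the minimum run length never increases F_ROH; tightening the
    het allowance never increases total run length."""
    rng = np.random.default_rng(5)
    pos, geno = _random_instance(rng, 800, p_het=0.08)
    gm = gm_factory(geno[None, :], positions=pos)
    base = RohParams(window_snps=15, max_het=2, max_missing=3, min_snps=5,
                     min_length_kb=20, max_density_kb_per_snp=1000)
    segs = call_roh(gm, "S0", base)
    genome = int(pos[-1] + 10_000)
    frohs = [f_roh(segs, t, genome) for t in (0, 50_000, 200_000, 10**6)]
    assert frohs == sorted(frohs, reverse=True)
    tight = RohParams(**{**base.__dict__, "max_het": 0})
    total_tight = sum(s.length for s in call_roh(gm, "S0", tight))
    assert total_tight <= sum(s.length for s in segs)


def test_froh_arithmetic():
    from mirounga.diversity import RohSegment

    assert f_roh([], 100_000, 10**7) == 0.0
    seg = RohSegment("S", "chr1", 1, 1_200_000, 500)
    assert f_roh([seg], 1_000_000, 12_000_000) == pytest.approx(0.1)
    assert f_roh([seg], 2_000_000, 12_000_000) == 0.0


def test_froh_tracks_true_inbreeding(bottleneck_sim):
    """Rank correlation between F_ROH and pedigree-IBD inbreeding is high."""
    from scipy.stats import spearmanr

    cfg, gm, truth = bottleneck_sim
    filt = filter_sites(gm)
    params = RohParams(window_snps=20, min_snps=5, min_length_kb=100,
                       max_density_kb_per_snp=1000)
    modern = truth.samples_in("modern")
    res = roh_result(filt, params, thresholds_bp=(100_000, 1_000_000), samples=modern)
    froh = res.froh[100_000]
    ftrue = np.array([truth.f_ibd[s] for s in modern])
    rho = spearmanr(froh.values, ftrue).statistic
    assert rho >= 0.8
    # longer threshold can only lower F_ROH
    assert (res.froh[1_000_000] <= res.froh[100_000] + 1e-12).all()


def test_filter_sites_boundaries(gm_factory):
    # 100 alleles (50 diploids); site 0: singleton; site 1: MAF exactly 0.01
    # is retained (strict '<'); site 2: monomorphic; site 3: common.
    g = np.zeros((50, 4), dtype=np.int8)
    g[0, 0] = 1          # singleton: AC = 1
    g[0, 1] = 1          # one het -> MAF 0.01 but AC 1: removed as singleton
    g[:10, 3] = 1
    gm = gm_factory(g)
    out = filter_sites(gm, maf_min=0.01, drop_singletons=True)
    assert out.n_sites == 1 and out.pos[0] == gm.pos[3]
    # MAF exactly at the threshold with AC > 1 is retained
    g2 = np.zeros((50, 1), dtype=np.int8)
    g2[0, 0] = 2  # AC = 2, MAF = 0.02
    gm2 = gm_factory(g2)
    assert filter_sites(gm2, maf_min=0.02).n_sites == 1
    assert filter_sites(gm2, maf_min=0.021).n_sites == 0


def test_windowed_heterozygosity_counts(gm_factory):
    g = np.array([[1, 1, 1, 0, MISSING]], dtype=np.int8)
    pos = np.array([10_000, 20_000, 60_000, 70_000, 130_000])
    gm = gm_factory(g, positions=pos, contig_length=150_000)
    win = windowed_heterozygosity(gm, "S0", window_bp=50_000)
    assert list(win["n_het"]) == [2, 1, 0]
    assert list(win["n_called"]) == [2, 2, 0]
    assert win["n_het"].sum() == (g == 1).sum()  # conservation


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    n=st.integers(5, 120),
    seed=st.integers(0, 10_000),
    window=st.integers(2, 15),
    threshold=st.floats(0.05, 1.0),
)
def test_roh_caller_oracle_property(n, seed, window, threshold):
    """Property form of the oracle equivalence on small random instances."""
    rng = np.random.default_rng(seed)
    params = RohParams(
        window_snps=window,
        max_het=int(rng.integers(0, 3)),
        max_missing=int(rng.integers(0, 3)),
        hit_threshold=threshold,
        min_snps=int(rng.integers(2, 10)),
        min_length_kb=float(rng.uniform(1, 50)),
        max_gap_kb=float(rng.uniform(5, 100)),
        max_density_kb_per_snp=float(rng.uniform(5, 100)),
    )
    pos, geno = _random_instance(rng, n)
    from mirounga.io import GenotypeMatrix

    gm = GenotypeMatrix(
        sample_ids=["S0"],
        contigs=[("chr1", int(pos[-1] + 10_000))],
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        genotypes=geno[None, :],
    )
    got = [(s.start, s.end, s.n_snps) for s in call_roh(gm, "S0", params)]
    assert got == reference_roh(pos.tolist(), geno.tolist(), params)


def test_genome_heterozygosity():
    assert genome_heterozygosity(5, 10_000) == pytest.approx(5e-4)
    assert genome_heterozygosity(0, 100) == 0.0
    with pytest.raises(ValueError):
        genome_heterozygosity(1, 0)
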
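"""Heterozygosity, the site filter, the ROH caller and F_ROH.

The ROH caller reimplements the PLINK ``--homozyg`` scanning definition:
a fixed-size SNP window slides along each contig; a window *passes* when it
contains at most ``max_het`` heterozygous and ``max_missing`` missing calls;
each SNP's hit rate is the fraction of windows covering it that pass; SNPs
at or above the hit-rate threshold are run-eligible, and maximal stretches
of eligible SNPs are reported as segments subject to minimum-SNP,
minimum-length, maximum-gap and density constraints.  F_ROH is the summed
length of segments above a length threshold divided by the genome length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RohParams",
    "RohSegment",
    "RohResult",
    "filter_sites",
    "windowed_heterozygosity",
    "genome_heterozygosity",
    "count_het",
    "call_roh",
    "f_roh",
    "roh_result",
]


@dataclass(frozen=True)
class RohParams:
    """Scan parameters; defaults mirror PLINK's documented --homozyg defaults.

    With sparse marker maps (few SNPs per 100 kb) ``window_snps``,
    ``min_snps`` and ``max_density_kb_per_snp`` should be reduced to match
    the marker spacing, exactly as PLINK users do for low-density panels.
    """

    window_snps: int = 50
    max_het: int = 1
    max_missing: int = 5
    hit_threshold: float = 0.05
    min_snps: int = 100
    min_length_kb: float = 100.0
    max_gap_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_snps) <= 0:
            raise ValueError("window/min SNP counts must be positive")
        if not 0.0 < self.hit_threshold <= 1.0:
            raise ValueError("hit threshold must lie in (0, 1]")
        if min(self.min_length_kb, self.max_gap_kb, self.max_density_kb_per_snp) <= 0:
            raise ValueError("length parameters must be positive")


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run; coordinates 1-based inclusive."""

    sample: str
    contig: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RohResult:
    """Segments per sample plus F_ROH at each requested length threshold."""

    segments: dict[str, list[RohSegment]]
    froh: pd.DataFrame  # index sample, one column per threshold (bp)
    genome_length: int


# ---------------------------------------------------------------------------
# Site filter
# ---------------------------------------------------------------------------

def filter_sites(
    gm: GenotypeMatrix, maf_min: float = 0.01, drop_singletons: bool = True
) -> GenotypeMatrix:
    """Remove singleton and rare sites before ROH assessment.

    A site is dropped when its minor-allele count is <= 1 (which also removes
    monomorphic sites) or its minor allele frequency, computed over
    non-missing alleles, is strictly below ``maf_min``; a site at exactly
    ``maf_min`` is retained.
    """
    ac = gm.allele_counts()
    mac = ac.min(axis=1)
    tot = ac.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, mac / tot, 0.0)
    keep = maf >= maf_min
    if drop_singletons:
        keep &= mac > 1
    if not keep.any():
        logger.warning("filter_sites removed every site")
    return gm.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def windowed_heterozygosity(
    gm: GenotypeMatrix, sample: str, window_bp: int = 50_000
) -> pd.DataFrame:
    """Het and called-genotype counts in non-overlapping windows.

    Windows are ``[k*w + 1, (k+1)*w]`` per contig, covering the full contig
    length (empty windows report (0, 0)).
    """
    i = gm.sample_index(sample)
    g = gm.genotypes[i]
    rows = []
    for contig, length in gm.contigs:
        mask = gm.contig_site_mask(contig)
        pos = gm.pos[mask]
        gc = g[mask]
        n_windows = max(1, int(np.ceil(length / window_bp)))
        win = (pos - 1) // window_bp
        het = np.bincount(win[gc == 1], minlength=n_windows)
        called = np.bincount(win[gc != MISSING], minlength=n_windows)
        for k in range(n_windows):
            rows.append(
                {
                    "contig": contig,
                    "start": k * window_bp + 1,
                    "n_het": int(het[k]),
                    "n_called": int(called[k]),
                }
            )
    return pd.DataFrame(rows)


def count_het(gm: GenotypeMatrix, sample: str) -> int:
    return int((gm.genotypes[gm.sample_index(sample)] == 1).sum())


def genome_heterozygosity(n_het: int, n_passing_sites: int) -> float:
    """Genome-wide heterozygosity: het calls over all sites passing filters."""
    if n_passing_sites <= 0:
        raise ValueError("n_passing_sites must be positive")
    return n_het / n_passing_sites


# ---------------------------------------------------------------------------
# ROH caller
# ---------------------------------------------------------------------------

def _eligible_snps(het: np.ndarray, miss: np.ndarray, params: RohParams) -> np.ndarray:
    """Hit-rate scan on one contig: bool eligibility per SNP."""
    n = len(het)
    w = params.window_snps
    if n == 0:
        return np.zeros(0, dtype=bool)
    if n < w:
        # truncated single window spanning the whole contig
        ok = het.sum() <= params.max_het and miss.sum() <= params.max_missing
        return np.full(n, ok and 1.0 >= params.hit_threshold)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(miss)])
    # window starting at s covers SNPs s..s+w-1, s = 0..n-w
    het_w = ch[w:] - ch[:-w]
    mis_w = cm[w:] - cm[:-w]
    passing = (het_w <= params.max_het) & (mis_w <= params.max_missing)
    cp = np.concatenate([[0], np.cumsum(passing)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(n - w, idx)
    hits = cp[hi + 1] - cp[lo]
    cover = hi - lo + 1
    return hits / cover >= params.hit_threshold


def _segments_from_eligible(
    sample: str,
    contig: str,
    pos: np.ndarray,
    eligible: np.ndarray,
    params: RohParams,
) -> list[RohSegment]:
    segs: list[RohSegment] = []
    n = len(pos)
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        # split the eligible stretch at gaps exceeding max_gap
        starts = [i]
        for k in range(i, j):
            if pos[k + 1] - pos[k] > params.max_gap_kb * 1000:
                starts.append(k + 1)
        bounds = starts + [j + 1]
        for a, b in zip(bounds[:-1], bounds[1:]):
            n_snp = b - a
            length = int(pos[b - 1] - pos[a] + 1)
            if n_snp < params.min_snps:
                continue
            if length < params.min_length_kb * 1000:
                continue
            if length / n_snp > params.max_density_kb_per_snp * 1000:
                continue
            segs.append(RohSegment(sample, contig, int(pos[a]), int(pos[b - 1]), n_snp))
        i = j + 1
    return segs


def call_roh(gm: GenotypeMatrix, sample: str, params: RohParams | None = None) -> list[RohSegment]:
    """PLINK-style ROH scan for one sample over every contig.

    Apply :func:`filter_sites` first, as the upstream workflow does.
    Contigs with fewer SNPs than the scan window are scanned with a single
    truncated window (warning logged).
    """
    params = params or RohParams()
    i = gm.sample_index(sample)
    g = gm.genotypes[i]
    out: list[RohSegment] = []
    for contig, _ in gm.contigs:
        mask = gm.contig_site_mask(contig)
        pos = gm.pos[mask]
        gc = g[mask]
        if len(pos) == 0:
            continue
        if len(pos) < params.window_snps:
            logger.warning(
                "contig %s has %d SNPs < window of %d; truncated window used",
                contig, len(pos), params.window_snps,
            )
        het = (gc == 1).astype(np.int64)
        miss = (gc == MISSING).astype(np.int64)
        eligible = _eligible_snps(het, miss, params)
        out.extend(_segments_from_eligible(sample, contig, pos, eligible, params))
    return out


def f_roh(
    segments: Iterable[RohSegment], min_length_bp: float, genome_length_bp: int
) -> float:
    """Proportion of the genome in runs at least ``min_length_bp`` long."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    total = sum(s.length for s in segments if s.length >= min_length_bp)
    return total / genome_length_bp


def roh_result(
    gm: GenotypeMatrix,
    params: RohParams | None = None,
    thresholds_bp: Sequence[int] = (100_000, 1_000_000),
    genome_length_bp: int | None = None,
    samples: Sequence[str] | None = None,
) -> RohResult:
    """Segments and F_ROH for every (or the given) sample.

    The F_ROH denominator defaults to the sum of contig lengths.
    """
    if genome_length_bp is None:
        genome_length_bp = sum(length for _, length in gm.contigs)
    samples = list(samples) if samples is not None else list(gm.sample_ids)
    segs = {s: call_roh(gm, s, params) for s in samples}
    froh = pd.DataFrame(
        {t: {s: f_roh(segs[s], t, genome_length_bp) for s in samples} for t in thresholds_bp}
    )
    froh.index.name = "sample_id"
    return RohResult(segments=segs, froh=froh, genome_length=genome_length_bp)


def segments_to_bed(segments: Iterable[RohSegment]) -> pd.DataFrame:
    """BED-style frame (0-based half-open) from 1-based inclusive segments."""
    return pd.DataFrame(
        [
            {
                "contig": s.contig,
                "start": s.start - 1,
                "end": s.end,
                "sample_id": s.sample,
                "n_snps": s.n_snps,
            }
            for s in segments
        ]
    )
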
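"""Genotype, phenotype, dive and alignment I/O.

Defines the in-memory genotype model (:class:`GenotypeMatrix`) consumed by
every analysis module, and readers/writers for the standard formats the
pipeline touches: multi-sample VCF with snpEff-style ``ANN``/``LOF``
annotations, phenotype/dive/copulation CSV tables, and aligned FASTA.

Conventions
-----------
* Genotypes are dosage codes ``0`` (hom-ref), ``1`` (het), ``2`` (hom-alt);
  missing and half calls are ``MISSING`` (= -1).  Phase is discarded.
* Coordinates are VCF-style 1-based inclusive throughout this module.
* Only biallelic SNPs are represented; other records are dropped on read
  with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing or half call.
MISSING: int = -1

_EFFECT_CLASSES = {
    "stop_gained",
    "start_lost",
    "stop_lost",
    "missense",
    "synonymous",
    "upstream",
    "other",
}

#: snpEff Sequence Ontology terms mapped onto the coarse effect classes
#: the burden module filters on.
_SNPEFF_EFFECT_MAP = {
    "stop_gained": "stop_gained",
    "start_lost": "start_lost",
    "stop_lost": "stop_lost",
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
    "upstream_gene_variant": "upstream",
}

_LOF_EFFECTS = {"stop_gained", "start_lost", "stop_lost"}


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional-effect annotation of one site (snpEff ANN convention)."""

    effect_class: str = "other"
    gene_symbol: str = ""
    lof_flag: bool = False

    def __post_init__(self) -> None:
        if self.effect_class not in _EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-SNP sites with dosage-coded genotypes.

    Attributes
    ----------
    sample_ids : list of str
    contigs : list of (name, length-in-bp) in header order
    chrom, pos, ref, alt : per-site arrays; ``pos`` is 1-based
    genotypes : int8 array of shape (n_samples, n_sites); -1 = missing
    annotations : optional list of :class:`VariantAnnotation` (or None
        per site), parallel to the site arrays
    """

    sample_ids: list[str]
    contigs: list[tuple[str, int]]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    annotations: list[VariantAnnotation | None] | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.genotypes.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.pos)} sites)"
            )
        if self.annotations is not None and len(self.annotations) != len(self.pos):
            raise ValueError("annotations length does not match site count")
        order = {name: k for k, (name, _) in enumerate(self.contigs)}
        prev = (-1, -1)
        for c, p in zip(self.chrom, self.pos):
            key = (order[c], int(p))
            if key <= prev:
                raise ValueError("sites must be strictly increasing within contigs")
            prev = key

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def sites(self) -> list[tuple[str, int, str, str]]:
        return list(zip(self.chrom, (int(p) for p in self.pos), self.ref, self.alt))

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def contig_length(self, name: str) -> int:
        for c, length in self.contigs:
            if c == name:
                return length
        raise KeyError(f"unknown contig {name!r}")

    # -- derived per-site statistics ------------------------------------
    def allele_counts(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """(n_sites, 2) counts of (ref, alt) alleles over non-missing calls."""
        g = self.genotypes
        if samples is not None:
            idx = [self.sample_index(s) for s in samples]
            g = g[idx]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return np.stack([total - alt, alt], axis=1)

    def maf(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Minor allele frequency per site over non-missing alleles (nan if none called)."""
        ac = self.allele_counts(samples)
        tot = ac.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = ac[:, 1] / tot
        return np.where(tot > 0, np.minimum(f, 1.0 - f), np.nan)

    # -- subsetting ------------------------------------------------------
    def take_sites(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        ann = None
        if self.annotations is not None:
            ann = [self.annotations[i] for i in idx]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            contigs=list(self.contigs),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[:, idx],
            annotations=ann,
        )

    def take_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(
            sample_ids=list(samples),
            contigs=list(self.contigs),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            genotypes=self.genotypes[idx],
            annotations=self.annotations,
        )

    def contig_site_mask(self, name: str) -> np.ndarray:
        return self.chrom == name

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.contigs == other.contigs
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.genotypes, other.genotypes)
            and (self.annotations or None) == (other.annotations or None)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def _parse_ann(ann_value: str, lof_value: str | None) -> VariantAnnotation:
    """First ANN entry -> coarse effect class; LOF INFO key forces lof_flag."""
    first = ann_value.split(",")[0]
    fields = first.split("|")
    if len(fields) < 2:
        raise ValueError(f"malformed ANN entry: {ann_value!r}")
    # ANN field 2 is the annotation (may be '&'-joined), field 4 the gene name
    effects = fields[1].split("&")
    effect = "other"
    for e in effects:
        if e in _SNPEFF_EFFECT_MAP:
            effect = _SNPEFF_EFFECT_MAP[e]
            break
    gene = fields[3] if len(fields) > 3 else ""
    lof = bool(lof_value) or effect in _LOF_EFFECTS
    return VariantAnnotation(effect_class=effect, gene_symbol=gene, lof_flag=lof)


def read_vcf(
    path: str | Path,
    region: str | None = None,
    contigs_include: Iterable[str] | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNPs are kept (multi-allelic sites and indels are dropped
    with a logged count, not split).  snpEff ``ANN``/``LOF`` INFO strings are
    parsed into :class:`VariantAnnotation` when present; a malformed ANN entry
    keeps the site with effect class ``other`` and a warning.

    Parameters
    ----------
    region : optional ``contig`` or ``contig:start-end`` restriction.
    contigs_include : optional explicit contig include-list (e.g. a set of
        chromosomal scaffolds); sites on other contigs are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    keep = set(contigs_include) if contigs_include is not None else None

    contigs: list[tuple[str, int]] = []
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        if keep is None or name in keep:
            contigs.append((name, int(length)))
    if not contigs:  # header without contig lines: lengths backfilled below
        contigs = []

    chrom, pos, ref, alt, rows, anns = [], [], [], [], [], []
    n_dropped = 0
    any_ann = False
    it = vcf(region) if region else vcf
    for var in it:
        if keep is not None and var.CHROM not in keep:
            continue
        if len(var.ALT) != 1 or var.REF not in _BASES or var.ALT[0] not in _BASES:
            n_dropped += 1
            continue
        if var.format("GT") is None and var.gt_types is None:
            raise ValueError(f"record {var.CHROM}:{var.POS} has no GT field")
        # gts012: 0/1/2 dosage, 3 = unknown; half calls come back as 3
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        rows.append(g)
        ann_val = var.INFO.get("ANN")
        lof_val = var.INFO.get("LOF")
        if ann_val is not None:
            any_ann = True
            try:
                anns.append(_parse_ann(str(ann_val), lof_val))
            except ValueError:
                logger.warning(
                    "malformed ANN at %s:%d; annotation set to 'other'",
                    var.CHROM,
                    var.POS,
                )
                anns.append(VariantAnnotation())
        else:
            anns.append(None)
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not contigs:
        seen: dict[str, int] = {}
        for c, p in zip(chrom, pos):
            seen[c] = max(seen.get(c, 0), p)
        contigs = [(c, l) for c, l in seen.items()]
    gm = GenotypeMatrix(
        sample_ids=samples,
        contigs=contigs,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.vstack(rows).T if rows else np.empty((len(samples), 0), np.int8),
        annotations=anns if any_ann else None,
    )
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_EFFECT_TO_SNPEFF = {v: k for k, v in _SNPEFF_EFFECT_MAP.items()}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF 4.2 with contig headers; ANN/LOF reconstructed."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in gm.contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.annotations is not None:
            fh.write(
                '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n'
            )
            fh.write(
                '##INFO=<ID=LOF,Number=.,Type=String,Description="Predicted loss of function">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            info = "."
            if gm.annotations is not None and gm.annotations[j] is not None:
                a = gm.annotations[j]
                term = _EFFECT_TO_SNPEFF.get(a.effect_class, a.effect_class)
                info = f"ANN={gm.alt[j]}|{term}|MODIFIER|{a.gene_symbol}"
                if a.lof_flag:
                    info += f";LOF=({a.gene_symbol}|{a.gene_symbol}|1|1.00)"
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "sample_id",
    "sex",
    "birth_year",
    "weaned_per_year",
    "total_weaned",
    "fecundity",
    "longevity",
    "cohort",
]

DIVE_COLUMNS = ["sample_id", "trip", "dive", "depth_m", "duration_s"]

COPULATION_COLUMNS = ["harem", "male_id", "copulation_share"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Per-individual phenotype table; missing cells stay NaN, never 0."""
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id",) if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype CSV lacks columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated individual IDs in phenotype table: {dupes}")
    for col in ("weaned_per_year", "total_weaned", "fecundity", "longevity"):
        if col in df.columns:
            bad = df[col].dropna() < 0
            if bad.any():
                raise ValueError(f"negative values in phenotype column {col}")
    return df


def read_dives(path: str | Path) -> pd.DataFrame:
    """Per-dive records; rows with non-positive depth/duration are rejected
    with a warning.  1-3 trips per individual is the expected range (warn
    outside it)."""
    df = pd.read_csv(path)
    missing = [c for c in DIVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dive CSV lacks columns {missing}")
    bad = (df["depth_m"] <= 0) | (df["duration_s"] <= 0)
    if bad.any():
        logger.warning("read_dives: rejected %d rows with non-positive depth/duration", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    trips = df.groupby("sample_id")["trip"].nunique()
    odd = trips[(trips < 1) | (trips > 3)]
    if len(odd):
        logger.warning("read_dives: %d individuals outside the 1-3 trip range", len(odd))
    return df


def read_copulations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"copulation CSV lacks columns {missing}")
    if ((df["copulation_share"] < 0) | (df["copulation_share"] > 1)).any():
        raise ValueError("copulation_share must lie in [0, 1]")
    return df


def read_tables(
    phenotype_path: str | Path,
    dive_path: str | Path,
    copulation_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    return (
        read_phenotypes(phenotype_path),
        read_dives(dive_path),
        read_copulations(copulation_path),
    )


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

_ALIGN_ALPHABET = set("ACGTN-")


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Aligned sequences as an ordered id -> uppercase sequence map.

    Ragged lengths are a hard error; characters outside {A,C,G,T,N,-} are a
    hard error too (ambiguity codes are not supported).
    """
    from Bio import SeqIO

    records: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"alignment is ragged: {rec.id} has length {len(seq)}, expected {length}"
            )
        extra = set(seq) - _ALIGN_ALPHABET
        if extra:
            raise ValueError(f"unsupported characters {sorted(extra)} in {rec.id}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records
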
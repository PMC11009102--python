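"""Loss-of-function locus selection and dosage-coded burden.

The burden codes each genotype at a LOF locus as 1 (homozygous for the LOF
allele), 0.5 (heterozygous) or 0 (unaffected) and totals across loci.  The
LOF allele is assumed to be the alt allele (snpEff annotates effects of the
alt allele) unless a per-site override is supplied.  Missing genotypes are
dropped from both the numerator and the per-individual locus count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["LofBurden", "select_lof_loci", "burden", "genotype_class_proportions"]

_STRICT_EFFECTS = {"stop_gained", "start_lost"}


@dataclass
class LofBurden:
    """Per-individual burden over a LOF locus set.

    ``per_individual`` columns: burden (sum of 1/0.5/0 codes),
    n_called (loci with a called genotype), relative_freq (burden / n_called),
    hom_count, het_count.  Individuals with no called locus report NaN.
    """

    locus_set: str
    site_indices: np.ndarray
    per_individual: pd.DataFrame
    prop_hom: float
    prop_het: float


def select_lof_loci(gm: GenotypeMatrix, mode: str = "strict") -> np.ndarray:
    """Site indices of LOF loci.

    ``strict``: stop-gained or start-lost only (the high-confidence set);
    ``all``: every site flagged LOF.  Monomorphic sites are excluded since
    they carry no burden information in this sample.
    """
    if gm.annotations is None:
        raise ValueError(
            "genotype matrix carries no functional annotations; "
            "provide a snpEff-annotated VCF (ANN/LOF INFO fields)"
        )
    if mode not in ("strict", "all"):
        raise ValueError(f"mode must be 'strict' or 'all', got {mode!r}")
    ac = gm.allele_counts()
    polymorphic = (ac[:, 0] > 0) & (ac[:, 1] > 0)
    idx = []
    for j, ann in enumerate(gm.annotations):
        if ann is None or not polymorphic[j]:
            continue
        if mode == "strict":
            if ann.effect_class in _STRICT_EFFECTS:
                idx.append(j)
        elif ann.lof_flag:
            idx.append(j)
    if not idx:
        logger.warning("select_lof_loci: no %s LOF loci found", mode)
    return np.asarray(idx, dtype=np.intp)


def burden(
    gm: GenotypeMatrix,
    loci: Sequence[int] | np.ndarray,
    lof_allele: str = "alt",
    locus_set: str = "custom",
) -> LofBurden:
    """Dosage-coded burden (hom = 1, het = 0.5, unaffected = 0) per individual."""
    loci = np.asarray(loci, dtype=np.intp)
    g = gm.genotypes[:, loci]
    if lof_allele == "ref":
        g = np.where(g >= 0, 2 - g, g)
    elif lof_allele != "alt":
        raise ValueError("lof_allele must be 'alt' or 'ref'")
    called = g >= 0
    hom = (g == 2) & called
    het = (g == 1) & called
    n_called = called.sum(axis=1)
    b = hom.sum(axis=1) + 0.5 * het.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(n_called > 0, b / n_called, np.nan)
    per = pd.DataFrame(
        {
            "burden": np.where(n_called > 0, b, np.nan),
            "n_called": n_called,
            "relative_freq": rel,
            "hom_count": hom.sum(axis=1),
            "het_count": het.sum(axis=1),
        },
        index=pd.Index(gm.sample_ids, name="sample_id"),
    )
    total_called = called.sum()
    prop_hom = hom.sum() / total_called if total_called else np.nan
    prop_het = het.sum() / total_called if total_called else np.nan
    return LofBurden(
        locus_set=locus_set,
        site_indices=loci,
        per_individual=per,
        prop_hom=float(prop_hom),
        prop_het=float(prop_het),
    )


def genotype_class_proportions(
    gm: GenotypeMatrix,
    loci: Sequence[int] | np.ndarray,
    samples: Sequence[str] | None = None,
    lof_allele: str = "alt",
) -> pd.DataFrame:
    """Per-sample proportions of hom-LOF and het genotypes over called loci,
    summarized as mean +/- s.d. across samples.

    Returns a two-row frame (index ``hom``, ``het``) with columns ``mean``
    and ``sd``; the per-sample values are attached as ``.attrs['per_sample']``.
    """
    sub = gm if samples is None else gm.take_samples(samples)
    b = burden(sub, loci, lof_allele=lof_allele)
    per = b.per_individual
    with np.errstate(invalid="ignore", divide="ignore"):
        hom_p = per["hom_count"] / per["n_called"]
        het_p = per["het_count"] / per["n_called"]
    out = pd.DataFrame(
        {
            "mean": [hom_p.mean(), het_p.mean()],
            "sd": [hom_p.std(ddof=1), het_p.std(ddof=1)],
        },
        index=pd.Index(["hom", "het"], name="genotype_class"),
    )
    out.attrs["per_sample"] = pd.DataFrame({"hom": hom_p, "het": het_p})
    return out
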
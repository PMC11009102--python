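"""Small published genotype-count fixtures bundled with the package.

``HYPOXIA_GENOTYPE_COUNTS`` holds the published genotype counts at six SNPs
in five hypoxia-associated loci (HIF1A carries two SNPs) for 46 high- and
46 low-dive-performance female northern elephant seals, as reported in the
study this pipeline reimplements.  They allow the candidate-locus MAF
contrast to be exercised against real printed numbers without any sequence
data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dive import MafTable, pooled_maf_table

__all__ = ["HYPOXIA_GENOTYPE_COUNTS", "hypoxia_maf_contrast"]

# counts are (high-performance, low-performance) individuals per genotype
HYPOXIA_GENOTYPE_COUNTS = [
    {
        "locus": "HIF1A",
        "snp": "96892683",
        "kind": "upstream",
        "genotypes": {"CC": (16, 11), "CA": (23, 21), "AA": (7, 14)},
    },
    {
        "locus": "HIF1A",
        "snp": "96894173",
        "kind": "upstream",
        "genotypes": {"CC": (12, 9), "CT": (22, 20), "TT": (12, 17)},
    },
    {
        "locus": "HIF3A",
        "snp": "45676640",
        "kind": "nonsynonymous",
        "genotypes": {"AA": (38, 37), "AG": (7, 9), "GG": (1, 0)},
    },
    {
        "locus": "SETX",
        "snp": "30169236",
        "kind": "nonsynonymous",
        "genotypes": {"CC": (42, 37), "CT": (4, 9), "TT": (0, 0)},
    },
    {
        "locus": "HYOU1",
        "snp": "30169060",
        "kind": "upstream",
        "genotypes": {"GG": (28, 21), "GT": (17, 21), "TT": (1, 4)},
    },
    {
        "locus": "MB",
        "snp": "30169078",
        "kind": "upstream",
        "genotypes": {"CC": (37, 28), "GC": (7, 17), "GG": (2, 1)},
    },
]


def _allele_counts(genotypes: dict[str, tuple[int, int]]) -> dict[str, np.ndarray]:
    """Per-allele (high, low) counts from genotype counts."""
    out: dict[str, np.ndarray] = {}
    for gt, (n_high, n_low) in genotypes.items():
        for allele in gt:
            acc = out.setdefault(allele, np.zeros(2))
            acc += (n_high, n_low)
    return out


def hypoxia_maf_contrast() -> MafTable:
    """Pooled high/low MAF contrast over the six published candidate SNPs.

    The minor allele at each SNP is defined in the pooled 92-female sample;
    allele counts are then summed across SNPs into one 2x2 table.
    """
    rows = []
    counts = {"high": np.zeros(2), "low": np.zeros(2)}
    for entry in HYPOXIA_GENOTYPE_COUNTS:
        ac = _allele_counts(entry["genotypes"])
        pooled = {a: c.sum() for a, c in ac.items()}
        minor = min(pooled, key=lambda a: (pooled[a], a))
        major = next(a for a in pooled if a != minor)
        row = {
            "locus": entry["locus"],
            "snp": entry["snp"],
            "minor_allele": minor,
        }
        for k, grp in enumerate(("high", "low")):
            n_minor = ac[minor][k]
            n_total = ac[minor][k] + ac[major][k]
            counts[grp] += (n_minor, n_total - n_minor)
            row[f"maf_{grp}"] = n_minor / n_total
            row[f"n_minor_{grp}"] = int(n_minor)
            row[f"n_total_{grp}"] = int(n_total)
        rows.append(row)
    return pooled_maf_table(pd.DataFrame(rows), counts, ("high", "low"))
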
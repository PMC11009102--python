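"""Composite dive-performance scoring and minor-allele-frequency contrasts.

The performance metric for each individual is

    mean per-trip maximum depth (m)
      x proportion of dives strictly deeper than the global median depth
      x relative mean dive duration (individual mean / largest individual mean)

with the median taken over the pooled dives of all individuals.  Individuals
are classed high/low either side of the score midpoint (min + max) / 2, with
scores exactly at the midpoint classed low.  MAF contrasts pool allele
counts across the candidate sites into a single 2x2 (minor/major x group)
table with a 1-df chi-square; per-site tables are emitted alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiveScore",
    "MafTable",
    "performance_scores",
    "classify_midpoint",
    "maf_contrast",
    "temporal_maf_shift",
    "pooled_maf_table",
]


@dataclass(frozen=True)
class DiveScore:
    individual: str
    mean_max_depth: float
    prop_deep: float
    rel_duration: float
    performance: float


@dataclass
class MafTable:
    """Pooled 2x2 allele-count contrast plus per-site detail.

    ``table`` rows are (minor, major) alleles, columns the two groups in
    ``group_names`` order.  ``sided`` records whether ``p`` is one- or
    two-sided; ``maf_by_group`` gives the pooled minor-allele frequency per
    group.
    """

    per_site: pd.DataFrame
    table: np.ndarray
    group_names: tuple[str, str]
    chi2: float
    p: float
    sided: str
    maf_by_group: dict[str, float]


# ---------------------------------------------------------------------------
# Performance
# ---------------------------------------------------------------------------

def performance_scores(dives: pd.DataFrame) -> pd.DataFrame:
    """Per-individual composite performance components and product.

    The depth threshold is the median over all dives of all individuals
    pooled (a single dataset-wide value); "deeper than" is strict.
    """
    if dives.empty:
        raise ValueError("empty dive table")
    median_depth = float(dives["depth_m"].median())
    per_trip_max = dives.groupby(["sample_id", "trip"])["depth_m"].max()
    mean_max = per_trip_max.groupby("sample_id").mean()
    prop_deep = dives.groupby("sample_id")["depth_m"].apply(
        lambda d: float((d > median_depth).mean())
    )
    mean_dur = dives.groupby("sample_id")["duration_s"].mean()
    rel_dur = mean_dur / mean_dur.max()
    out = pd.DataFrame(
        {
            "mean_max_depth": mean_max,
            "prop_deep": prop_deep,
            "rel_duration": rel_dur,
        }
    )
    out["performance"] = out["mean_max_depth"] * out["prop_deep"] * out["rel_duration"]
    out.attrs["median_depth"] = median_depth
    out.index.name = "sample_id"
    return out


def classify_midpoint(scores: pd.Series) -> pd.Series:
    """High/low classes either side of (min + max) / 2; midpoint ties -> low."""
    scores = pd.Series(scores)
    lo, hi = float(scores.min()), float(scores.max())
    if lo == hi:
        raise ValueError("all scores equal; midpoint classification undefined")
    midpoint = (lo + hi) / 2.0
    classes = pd.Series(
        np.where(scores > midpoint, "high", "low"), index=scores.index, name="class"
    )
    classes.attrs["midpoint"] = midpoint
    return classes


# ---------------------------------------------------------------------------
# MAF contrasts
# ---------------------------------------------------------------------------

def _group_allele_counts(
    gm: GenotypeMatrix, sites: np.ndarray, groups: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-site minor/major allele counts per group; minor allele fixed in
    the pooled sample (tie at 0.5 broken toward alt, flagged per site)."""
    pooled_samples = [s for grp in groups.values() for s in grp]
    rows = []
    counts: dict[str, np.ndarray] = {g: np.zeros(2) for g in groups}
    kept = []
    for j in sites:
        site = gm.take_sites([j])
        ac_pool = site.allele_counts(pooled_samples)[0]
        if ac_pool[0] == 0 or ac_pool[1] == 0:
            logger.warning(
                "site %s:%d monomorphic in the pooled sample; excluded",
                gm.chrom[j], gm.pos[j],
            )
            continue
        tie = ac_pool[0] == ac_pool[1]
        minor_is_alt = ac_pool[1] <= ac_pool[0]  # tie -> alt
        row = {
            "contig": gm.chrom[j],
            "pos": int(gm.pos[j]),
            "minor_allele": gm.alt[j] if minor_is_alt else gm.ref[j],
            "tie_broken_toward_alt": bool(tie),
        }
        for gname, members in groups.items():
            ac = site.allele_counts(members)[0]
            minor = ac[1] if minor_is_alt else ac[0]
            major = ac.sum() - minor
            counts[gname] += (minor, major)
            tot = ac.sum()
            row[f"maf_{gname}"] = minor / tot if tot else np.nan
            row[f"n_minor_{gname}"] = int(minor)
            row[f"n_total_{gname}"] = int(tot)
        rows.append(row)
        kept.append(j)
    return pd.DataFrame(rows), counts


def _pooled_chi2(table: np.ndarray) -> tuple[float, float]:
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def pooled_maf_table(
    per_site: pd.DataFrame,
    counts: Mapping[str, np.ndarray],
    group_names: tuple[str, str],
    one_sided_direction: str | None = None,
) -> MafTable:
    """Build a :class:`MafTable` from per-group (minor, major) allele counts.

    ``one_sided_direction`` names the group hypothesized to have the higher
    pooled MAF; when given and the observation matches, the reported p is
    the halved upper tail, flagged one-sided.
    """
    a, b = group_names
    table = np.stack([np.asarray(counts[a]), np.asarray(counts[b])], axis=1)
    chi2, p_two = _pooled_chi2(table)
    maf = {
        g: float(counts[g][0] / counts[g].sum()) if counts[g].sum() else np.nan
        for g in group_names
    }
    sided = "two-sided"
    p = p_two
    if one_sided_direction is not None and np.isfinite(p_two):
        other = b if one_sided_direction == a else a
        sided = "one-sided"
        p = p_two / 2.0 if maf[one_sided_direction] >= maf[other] else 1.0 - p_two / 2.0
    return MafTable(
        per_site=per_site,
        table=table,
        group_names=group_names,
        chi2=chi2,
        p=p,
        sided=sided,
        maf_by_group=maf,
    )


def maf_contrast(
    gm: GenotypeMatrix,
    candidate_sites: Sequence[int] | np.ndarray,
    classes: pd.Series | Mapping[str, str],
) -> MafTable:
    """Pooled minor-allele contrast between high- and low-performance groups."""
    classes = pd.Series(classes)
    groups = {
        "high": list(classes.index[classes == "high"]),
        "low": list(classes.index[classes == "low"]),
    }
    if not groups["high"] or not groups["low"]:
        raise ValueError("both performance classes must be nonempty")
    per_site, counts = _group_allele_counts(
        gm, np.asarray(candidate_sites, dtype=np.intp), groups
    )
    return pooled_maf_table(per_site, counts, ("high", "low"))


def temporal_maf_shift(
    gm: GenotypeMatrix,
    cohort_a: Sequence[str],
    cohort_b: Sequence[str],
    sites: Sequence[int] | np.ndarray,
    one_sided: bool = True,
) -> MafTable:
    """Pooled MAF change between two cohorts at the given sites.

    With ``one_sided`` the declared alternative is "cohort A has the higher
    pooled MAF" (the purifying-selection direction when A is the earlier
    cohort); the p value is the halved tail when the observation matches,
    flagged one-sided in the output.
    """
    if set(cohort_a) & set(cohort_b):
        raise ValueError("cohorts must be disjoint")
    per_site, counts = _group_allele_counts(
        gm, np.asarray(sites, dtype=np.intp), {"cohort_a": list(cohort_a), "cohort_b": list(cohort_b)}
    )
    return pooled_maf_table(
        per_site,
        counts,
        ("cohort_a", "cohort_b"),
        one_sided_direction="cohort_a" if one_sided else None,
    )
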
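"""KING-robust kinship, paternity assignment, and the mating-success tests.

The kinship estimator is the within-family KING-robust moment estimator
(the statistic behind VCFtools' ``--relatedness2``):

    phi_hat(i, j) = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j))

over jointly called sites.  It is 0.5 for self-comparison, ~0.25 for
parent-offspring pairs, ~0 for unrelated pairs, and is invariant to
ref/alt relabelling since it only uses heterozygote and opposite-homozygote
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "PaternityResult",
    "king_kinship_matrix",
    "king_kinship",
    "assign_paternity",
    "copulation_paternity_test",
    "lof_homozygosity_contrast",
]

#: Default assignment cut: midpoint 2^(-2.5) between first- and
#: second-degree kinship (the standard KING threshold).
FIRST_DEGREE_THRESHOLD = 2 ** -2.5  # ~0.177


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    phi: np.ndarray  # (n, n), NaN where undefined
    n_sites: np.ndarray  # (n, n) jointly called sites

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.phi[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PaternityResult:
    """Per-pup assignments and per-male paternity counts."""

    assignments: pd.DataFrame  # pup, assigned_sire (or None), kinship, runner_up
    paternity_counts: pd.Series  # per candidate male

    @property
    def n_assigned(self) -> int:
        return int(self.assignments["assigned_sire"].notna().sum())


def king_kinship_matrix(gm: GenotypeMatrix, samples: Sequence[str] | None = None) -> KinshipMatrix:
    """All-pairs KING-robust kinship (vectorized over the genotype matrix)."""
    sub = gm if samples is None else gm.take_samples(samples)
    g = sub.genotypes
    het = (g == 1).astype(np.float64)
    hom0 = (g == 0).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)
    called = (g >= 0).astype(np.float64)
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    denom = het @ called.T + called @ het.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    n_joint = (called @ called.T).astype(np.int64)
    return KinshipMatrix(sample_ids=list(sub.sample_ids), phi=phi, n_sites=n_joint)


def king_kinship(gm: GenotypeMatrix, i: str, j: str) -> float:
    """KING-robust kinship for one sample pair (NaN if the denominator is 0)."""
    return king_kinship_matrix(gm, samples=[i, j]).phi[0, 1]


def assign_paternity(
    kin: KinshipMatrix,
    pups: Sequence[str],
    candidate_males: Sequence[str],
    threshold: float = FIRST_DEGREE_THRESHOLD,
    mothers: Mapping[str, str] | None = None,
) -> PaternityResult:
    """Assign each pup to the candidate male with maximal kinship.

    A pup is assigned only when the best kinship reaches ``threshold``
    (first-degree cut); exact ties leave the pup unassigned.  Known mothers
    are excluded from the candidate list for their own pup; their kinship to
    the pup is reported for QC.
    """
    if set(pups) & set(candidate_males):
        raise ValueError("pups and candidate males must be disjoint")
    idx = {s: k for k, s in enumerate(kin.sample_ids)}
    rows = []
    for pup in pups:
        cands = [m for m in candidate_males if mothers is None or mothers.get(pup) != m]
        phis = np.array([kin.phi[idx[pup], idx[m]] for m in cands])
        order = np.argsort(np.nan_to_num(phis, nan=-np.inf))[::-1]
        best = order[0]
        runner = float(phis[order[1]]) if len(order) > 1 else np.nan
        tie = len(order) > 1 and phis[order[1]] == phis[best]
        assigned = (
            cands[best]
            if np.isfinite(phis[best]) and phis[best] >= threshold and not tie
            else None
        )
        rows.append(
            {
                "pup": pup,
                "assigned_sire": assigned,
                "kinship": float(phis[best]) if np.isfinite(phis[best]) else np.nan,
                "runner_up": runner,
                "mother_kinship": (
                    float(kin.phi[idx[pup], idx[mothers[pup]]])
                    if mothers and pup in mothers and mothers[pup] in idx
                    else np.nan
                ),
            }
        )
    assignments = pd.DataFrame(rows)
    counts = assignments["assigned_sire"].value_counts()
    counts = counts.reindex(list(candidate_males), fill_value=0).astype(int)
    counts.name = "paternities"
    return PaternityResult(assignments=assignments, paternity_counts=counts)


def copulation_paternity_test(
    copulation_share: float,
    paternities: int,
    n_pups: int,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """1-df goodness-of-fit of observed paternities against copulation share.

    Observed (assigned-to-focal, other) counts are compared with expected
    (share * n, (1 - share) * n); two-sided upper-tail p.
    """
    if n_pups <= 0:
        raise ValueError("n_pups must be positive")
    if not 0.0 < copulation_share < 1.0:
        raise ValueError("copulation_share must lie in (0, 1)")
    obs = np.array([paternities, n_pups - paternities], dtype=float)
    exp = np.array([copulation_share * n_pups, (1.0 - copulation_share) * n_pups])
    if (exp == 0).any():
        raise ValueError("expected cell count is zero")
    dev = np.abs(obs - exp)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev ** 2 / exp).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def lof_homozygosity_contrast(
    values_with_offspring: Sequence[float],
    values_without: Sequence[float],
) -> tuple[float, float]:
    """Mann-Whitney rank-sum contrast of LOF homozygote counts.

    Normal approximation with tie correction; returns the signed z and the
    one-sided p for the alternative "males with offspring carry fewer LOF
    homozygotes than males without".  All values tied -> (0, 0.5).
    """
    a = np.asarray(values_with_offspring, dtype=float)
    b = np.asarray(values_without, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0, 0.5
    z = float((u1 - mu) / np.sqrt(var))
    p_one = float(sps.norm.cdf(z))
    return z, p_one
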
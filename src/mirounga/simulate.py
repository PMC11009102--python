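"""Forward-in-time Wright-Fisher simulator of a bottlenecked, polygynous
diploid population.

The generator emulates the demographic history of a heavily hunted pinniped:
a large ancestral population crashes to a handful of individuals for a few
generations, then regrows.  It emits genotypes (as a
:class:`~mirounga.io.GenotypeMatrix` with cohort-labelled samples), a full
pedigree, per-individual realized inbreeding (segment-free identity-by-descent
tracked via founder-haplotype labels at every site), loss-of-function locus
annotations, phenotypes with a configurable linear inbreeding/burden effect,
and dive records whose depth/duration distributions shift with hypoxia-locus
minor-allele dosage.  Every downstream analysis stage is therefore testable
against known ground truth without any external data.

Model summary
-------------
* Discrete, non-overlapping generations; census sizes follow a trajectory
  (ancestral -> bottleneck -> geometric regrowth -> final size).
* Sex is assigned independently 1:1 at birth.
* Each offspring draws its dam uniformly from females.  Males are
  partitioned into harems each generation (rank = random permutation); the
  offspring's sire is the top-ranked male of a uniformly chosen harem with
  probability ``polygyny_share``, else uniform among the other males of that
  harem.
* Gametes are formed with Poisson-distributed crossovers at uniform
  positions and symmetric biallelic mutation (recurrent-flip model, so the
  site set is fixed and VCF-stable).
* No viability selection: fitness effects act only through the phenotype
  layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, VariantAnnotation

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_dives",
    "degrade_historical",
]


@dataclass
class SimConfig:
    """Parameters of the bottleneck simulation.

    The defaults describe a desk-scale version of the study system: a
    polygynous diploid population crashing from hundreds of breeders to ~20
    for a few generations and regrowing to an effective size near 100, with
    a 1 cM/Mb genetic map (0.1 expected crossovers on a 10-Mb chromosome).
    """

    seed: int = 1
    # genome
    n_chromosomes: int = 20
    chromosome_length: int = 10_000_000
    n_sites: int = 300  # segregating sites per chromosome at founding
    mutation_rate: float = 1e-8  # per site per generation, symmetric flip
    recombination_rate: float = 0.1  # expected crossovers per chromosome per meiosis
    # demography
    n_anc: int = 200
    n_bottleneck: int = 20
    bottleneck_duration: int = 3
    growth_rate: float = 0.6  # geometric post-bottleneck regrowth per generation
    final_n: int = 100
    burnin_generations: int = 10
    post_generations: int = 5
    trajectory: tuple[int, ...] | None = None  # explicit census override
    # mating system
    polygyny_share: float = 0.5
    n_harems: int = 4
    random_mating: bool = False  # bypass harems: sire uniform among all males
    # founder diversity
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    # phenotype / fitness layer
    n_lof_loci: int = 50
    lof_fitness_effect: float = 0.0  # reserved; selection acts via phenotypes only
    beta_froh: float = -5.0
    beta_lof: float = -0.05
    intercept: float = 1.8
    phenotype_noise_sd: float = 0.5
    # diving layer
    n_hypoxia_loci: int = 5
    dive_effect: float = 0.05  # per-minor-allele depth/duration multiplier decrement
    # sampling
    n_sample_pre: int = 10
    cohorts: tuple[tuple[str, int, int], ...] | None = None  # (label, generation, n | -1)

    def __post_init__(self) -> None:
        if min(self.mutation_rate, self.recombination_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.trajectory is None and self.n_bottleneck > self.n_anc:
            raise ValueError("bottleneck size exceeds ancestral size")
        for p in (self.polygyny_share, self.founder_maf_low, self.founder_maf_high):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def census_trajectory(self) -> list[int]:
        """Census size per generation, index 0 = founders."""
        if self.trajectory is not None:
            return [int(n) for n in self.trajectory]
        traj = [self.n_anc] * (self.burnin_generations + 1)
        traj += [self.n_bottleneck] * self.bottleneck_duration
        n = self.n_bottleneck
        while n < self.final_n:
            n = min(self.final_n, max(n + 1, int(round(n * (1.0 + self.growth_rate)))))
            traj.append(n)
        traj += [self.final_n] * self.post_generations
        return traj

    def default_cohorts(self) -> list[tuple[str, int, int]]:
        traj = self.census_trajectory()
        t_final = len(traj) - 1
        if self.cohorts is not None:
            return [(lab, g, n) for lab, g, n in self.cohorts]
        pre_gen = min(self.burnin_generations, t_final)
        out = []
        if t_final >= 2 and pre_gen < t_final - 1:
            out.append(("pre", pre_gen, self.n_sample_pre))
        if t_final >= 1:
            out.append(("parental", t_final - 1, -1))
        out.append(("modern", t_final, -1))
        return out


@dataclass
class SimTruth:
    """Ground truth emitted alongside the genotype matrix."""

    pedigree: dict[str, tuple[str | None, str | None]]
    sex: dict[str, str]  # 'F' / 'M'
    cohort: dict[str, str]
    generation: dict[str, int]
    f_ibd: dict[str, float]  # realized founder-IBD fraction of the genome
    lof_sites: np.ndarray
    hypoxia_sites: np.ndarray
    true_lof_burden: dict[str, float]
    hypoxia_dosage: dict[str, int]
    coefficients: dict[str, float]
    cohort_allele_freq: dict[str, np.ndarray]
    alpha_males: dict[int, str]
    pup_harem: dict[str, int]
    polygyny_share: float

    def __post_init__(self) -> None:
        for sid, f in self.f_ibd.items():
            if not 0.0 <= f <= 1.0 + 1e-12:
                raise ValueError(f"inbreeding of {sid} outside [0, 1]")
        # the pedigree must be acyclic: parents always belong to an earlier
        # generation, which the id scheme encodes; verified here
        for child, (sire, dam) in self.pedigree.items():
            g = self.generation.get(child)
            for par in (sire, dam):
                if par is not None and g is not None and self.generation.get(par, -1) >= g:
                    raise ValueError(f"pedigree cycle: {par} -> {child}")

    def samples_in(self, cohort: str) -> list[str]:
        return [s for s, c in self.cohort.items() if c == cohort]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "pedigree": self.pedigree,
            "sex": self.sex,
            "cohort": self.cohort,
            "generation": self.generation,
            "f_ibd": self.f_ibd,
            "lof_sites": [int(i) for i in self.lof_sites],
            "hypoxia_sites": [int(i) for i in self.hypoxia_sites],
            "true_lof_burden": self.true_lof_burden,
            "hypoxia_dosage": {k: int(v) for k, v in self.hypoxia_dosage.items()},
            "coefficients": self.coefficients,
            "cohort_allele_freq": {k: list(map(float, v)) for k, v in self.cohort_allele_freq.items()},
            "alpha_males": {str(k): v for k, v in self.alpha_males.items()},
            "pup_harem": self.pup_harem,
            "polygyny_share": self.polygyny_share,
        }
        Path(path).write_text(json.dumps(obj))


class ExtinctionError(RuntimeError):
    pass


def _meiosis(
    rng: np.random.Generator,
    hap: np.ndarray,
    anc: np.ndarray,
    parents: np.ndarray,
    chrom_slices: list[slice],
    chrom_pos: list[np.ndarray],
    chrom_length: int,
    recomb: float,
    mu: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete per row of ``parents``; returns (alleles, ancestry)."""
    n_off = len(parents)
    n_sites = hap.shape[2]
    choice = np.empty((n_off, n_sites), dtype=np.int8)
    for sl, pos in zip(chrom_slices, chrom_pos):
        start = rng.integers(0, 2, n_off)
        k = rng.poisson(recomb, n_off)
        kmax = int(k.max()) if n_off else 0
        if kmax > 0:
            x = rng.uniform(0, chrom_length, (n_off, kmax))
            x[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
            cnt = (x[:, None, :] < pos[None, :, None]).sum(axis=2)
        else:
            cnt = np.zeros((n_off, len(pos)), dtype=np.int64)
        choice[:, sl] = ((start[:, None] + cnt) % 2).astype(np.int8)
    ph = hap[parents]  # (n_off, 2, S)
    pa = anc[parents]
    gam = np.where(choice == 0, ph[:, 0, :], ph[:, 1, :])
    gam_anc = np.where(choice == 0, pa[:, 0, :], pa[:, 1, :])
    if mu > 0:
        flips = rng.random((n_off, n_sites)) < mu
        gam = np.where(flips, 1 - gam, gam)
    return gam.astype(np.int8), gam_anc


def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Run the forward simulation and emit cohort samples plus ground truth.

    Raises
    ------
    ExtinctionError
        If a generation contains zero females or zero males.
    """
    rng = np.random.default_rng(config.seed)
    traj = config.census_trajectory()
    t_final = len(traj) - 1
    cohort_plan: dict[int, list[tuple[str, int]]] = {}
    for label, gen, n in config.default_cohorts():
        if not 0 <= gen <= t_final:
            raise ValueError(f"cohort {label!r} at generation {gen} outside 0..{t_final}")
        cohort_plan.setdefault(gen, []).append((label, n))

    n_chrom, s_per = config.n_chromosomes, config.n_sites
    n_sites = n_chrom * s_per
    # fixed site map: sorted unique uniform positions per chromosome
    chrom_names = [f"chr{c + 1}" for c in range(n_chrom)]
    chrom_pos: list[np.ndarray] = []
    for _ in range(n_chrom):
        pos = np.sort(rng.choice(np.arange(1, config.chromosome_length + 1), size=s_per, replace=False))
        chrom_pos.append(pos.astype(np.int64))
    chrom_slices = [slice(c * s_per, (c + 1) * s_per) for c in range(n_chrom)]

    # founders
    n0 = traj[0]
    p0 = rng.uniform(config.founder_maf_low, config.founder_maf_high, n_sites)
    hap = (rng.random((n0, 2, n_sites)) < p0[None, None, :]).astype(np.int8)
    anc = np.arange(2 * n0, dtype=np.int32).reshape(n0, 2)[:, :, None] * np.ones(
        (1, 1, n_sites), dtype=np.int32
    )
    sex_f = rng.random(n0) < 0.5
    ids = [f"G0I{i}" for i in range(n0)]
    pedigree: dict[str, tuple[str | None, str | None]] = {i: (None, None) for i in ids}
    sex: dict[str, str] = {i: ("F" if f else "M") for i, f in zip(ids, sex_f)}
    generation: dict[str, int] = {i: 0 for i in ids}

    sampled: dict[str, np.ndarray] = {}
    cohort_of: dict[str, str] = {}
    f_ibd: dict[str, float] = {}
    alpha_males: dict[int, str] = {}
    pup_harem: dict[str, int] = {}

    def take_samples(gen: int) -> None:
        for label, n in cohort_plan.get(gen, []):
            n_cur = hap.shape[0]
            idx = np.arange(n_cur) if n < 0 or n >= n_cur else rng.choice(n_cur, n, replace=False)
            for i in idx:
                sid = ids[i]
                sampled[sid] = (hap[i, 0] + hap[i, 1]).astype(np.int8)
                cohort_of[sid] = label
                f_ibd[sid] = float(np.mean(anc[i, 0] == anc[i, 1]))

    take_samples(0)
    for t in range(1, t_final + 1):
        n_next = traj[t]
        females = np.flatnonzero(sex_f)
        males = np.flatnonzero(~sex_f)
        if len(females) == 0 or len(males) == 0:
            raise ExtinctionError(
                f"population extinct at generation {t}: "
                f"{len(females)} females, {len(males)} males"
            )
        # dams: uniform among females
        dams = rng.choice(females, n_next)
        # harems: random partition of males; first of each group is the alpha
        perm = rng.permutation(males)
        h = min(config.n_harems, len(males))
        harems = np.array_split(perm, h)
        harem_idx = rng.integers(0, h, n_next)
        if config.random_mating:
            sires = rng.choice(males, n_next)
        else:
            take_top = rng.random(n_next) < config.polygyny_share
            sires = np.empty(n_next, dtype=np.int64)
            for k in range(h):
                grp = harems[k]
                in_h = harem_idx == k
                sires[in_h & take_top] = grp[0]
                others = in_h & ~take_top
                n_oth = int(others.sum())
                if n_oth:
                    pool = grp[1:] if len(grp) > 1 else grp
                    sires[others] = rng.choice(pool, n_oth)
        gam_m, anc_m = _meiosis(
            rng, hap, anc, dams, chrom_slices, chrom_pos,
            config.chromosome_length, config.recombination_rate, config.mutation_rate,
        )
        gam_p, anc_p = _meiosis(
            rng, hap, anc, sires, chrom_slices, chrom_pos,
            config.chromosome_length, config.recombination_rate, config.mutation_rate,
        )
        new_ids = [f"G{t}I{i}" for i in range(n_next)]
        for i, nid in enumerate(new_ids):
            pedigree[nid] = (ids[sires[i]], ids[dams[i]])
            generation[nid] = t
        new_sex_f = rng.random(n_next) < 0.5
        for nid, f in zip(new_ids, new_sex_f):
            sex[nid] = "F" if f else "M"
        if t == t_final:
            for k in range(h):
                alpha_males[k] = ids[harems[k][0]]
            for i, nid in enumerate(new_ids):
                pup_harem[nid] = int(harem_idx[i])
        hap = np.stack([gam_m, gam_p], axis=1)
        anc = np.stack([anc_m, anc_p], axis=1)
        sex_f = new_sex_f
        ids = new_ids
        take_samples(t)

    sample_ids = list(sampled)
    G = np.vstack([sampled[s] for s in sample_ids])

    # annotations: LOF and hypoxia loci drawn among sites polymorphic in the
    # last cohort emitted (the "modern" population under the default plan)
    last_label = config.default_cohorts()[-1][0]
    modern = [s for s in sample_ids if cohort_of[s] == last_label]
    g_mod = G[[sample_ids.index(s) for s in modern]]
    freq_mod = g_mod.mean(axis=0) / 2.0
    poly = np.flatnonzero((freq_mod > 0.02) & (freq_mod < 0.98))
    rng_ann = np.random.default_rng(config.seed + 7)
    n_pick = min(config.n_lof_loci + config.n_hypoxia_loci, len(poly))
    picked = rng_ann.choice(poly, n_pick, replace=False) if n_pick else np.array([], int)
    lof_sites = np.sort(picked[: min(config.n_lof_loci, n_pick)])
    hyp_sites = np.sort(picked[min(config.n_lof_loci, n_pick):])
    annotations: list[VariantAnnotation | None] = []
    lof_set, hyp_set = set(lof_sites.tolist()), set(hyp_sites.tolist())
    lof_classes = rng_ann.choice(
        ["stop_gained", "start_lost", "stop_lost"], n_sites, p=[0.25, 0.21, 0.54]
    )
    bg_classes = rng_ann.choice(["synonymous", "missense", "other"], n_sites, p=[0.4, 0.3, 0.3])
    for j in range(n_sites):
        if j in lof_set:
            annotations.append(
                VariantAnnotation(str(lof_classes[j]), f"LOFG{j}", True)
            )
        elif j in hyp_set:
            annotations.append(VariantAnnotation("upstream", f"HYP{j}", False))
        else:
            annotations.append(VariantAnnotation(str(bg_classes[j]), f"G{j}", False))

    chrom_arr = np.repeat(np.array(chrom_names, dtype=object), s_per)
    pos_arr = np.concatenate(chrom_pos)
    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "G", dtype=object)
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        contigs=[(c, config.chromosome_length) for c in chrom_names],
        chrom=chrom_arr,
        pos=pos_arr,
        ref=ref,
        alt=alt,
        genotypes=G,
        annotations=annotations,
    )

    # ground truth extras
    burden: dict[str, float] = {}
    dosage: dict[str, int] = {}
    hyp_minor_is_alt = freq_mod[hyp_sites] <= 0.5 if len(hyp_sites) else np.array([], bool)
    for i, sid in enumerate(sample_ids):
        g_lof = G[i, lof_sites]
        burden[sid] = float((g_lof == 2).sum() + 0.5 * (g_lof == 1).sum())
        g_hyp = G[i, hyp_sites]
        d = np.where(hyp_minor_is_alt, g_hyp, 2 - g_hyp)
        dosage[sid] = int(d.sum())
    cohort_freq = {
        lab: G[[sample_ids.index(s) for s in sample_ids if cohort_of[s] == lab]].mean(axis=0) / 2.0
        for lab in {cohort_of[s] for s in sample_ids}
    }
    # keep only pedigree entries reachable from emitted samples (ancestors)
    needed: set[str] = set()
    stack = list(sample_ids)
    while stack:
        s = stack.pop()
        if s in needed:
            continue
        needed.add(s)
        for par in pedigree.get(s, (None, None)):
            if par is not None:
                stack.append(par)
    needed.update(alpha_males.values())
    truth = SimTruth(
        pedigree={k: v for k, v in pedigree.items() if k in needed},
        sex={k: v for k, v in sex.items() if k in needed},
        cohort=cohort_of,
        generation={k: v for k, v in generation.items() if k in needed},
        f_ibd=f_ibd,
        lof_sites=lof_sites,
        hypoxia_sites=hyp_sites,
        true_lof_burden=burden,
        hypoxia_dosage=dosage,
        coefficients={
            "intercept": config.intercept,
            "beta_froh": config.beta_froh,
            "beta_lof": config.beta_lof,
            "noise_sd": config.phenotype_noise_sd,
            "dive_effect": config.dive_effect,
        },
        cohort_allele_freq=cohort_freq,
        alpha_males=alpha_males,
        pup_harem=pup_harem,
        polygyny_share=config.polygyny_share,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Phenotype layer
# ---------------------------------------------------------------------------

# generation time used to map simulator generations to calendar birth years
_YEARS_PER_GENERATION = 5
_FINAL_YEAR = 2010


def simulate_phenotypes(truth: SimTruth, config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-individual phenotypes with the configured linear structure.

    Females: ``weaned_per_year = a + beta_froh * F_true + beta_lof * burden + eps``
    with Gaussian noise; fecundity and longevity carry no inbreeding effect.
    Males get paternity counts from the pedigree (offspring among emitted
    samples of later generations).
    """
    rng = np.random.default_rng(config.seed + 1000 if seed is None else seed)
    t_final = max(truth.generation.values())
    # paternity counts over emitted offspring
    pat = {s: 0 for s in truth.cohort}
    for child in truth.cohort:
        sire, _ = truth.pedigree.get(child, (None, None))
        if sire in pat:
            pat[sire] += 1
    rows = []
    for sid in truth.cohort:
        g = truth.generation[sid]
        # birth years scatter around the generation midpoint, as in a real
        # cohort where "one generation" spans several calendar years
        birth_year = _FINAL_YEAR - _YEARS_PER_GENERATION * (t_final - g) + int(
            rng.integers(-2, 3)
        )
        longevity = int(rng.integers(8, 22))
        is_f = truth.sex[sid] == "F"
        if is_f:
            weaned = (
                config.intercept
                + config.beta_froh * truth.f_ibd[sid]
                + config.beta_lof * truth.true_lof_burden[sid]
                + rng.normal(0.0, config.phenotype_noise_sd)
            )
            total = max(0, round(weaned * max(longevity - 3, 1)))
            fecundity = total + int(rng.poisson(1.0))
        else:
            weaned = np.nan
            total = np.nan
            fecundity = np.nan
        rows.append(
            {
                "sample_id": sid,
                "sex": truth.sex[sid],
                "birth_year": birth_year,
                "weaned_per_year": weaned,
                "total_weaned": total,
                "fecundity": fecundity,
                "longevity": longevity,
                "cohort": truth.cohort[sid],
                "first_weaning_year": birth_year + int(rng.integers(3, 7)) if is_f else np.nan,
                "paternity_count": pat[sid] if not is_f else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diving layer
# ---------------------------------------------------------------------------

# trip-count distribution: 8/92 one trip, 68/92 two, 16/92 three
_TRIP_PROBS = np.array([8.0, 68.0, 16.0]) / 92.0


def simulate_dives(
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
    cohort: str = "modern",
    females_only: bool = True,
) -> pd.DataFrame:
    """Per-dive depth/duration records for one cohort.

    Hypoxia-locus minor-allele dosage scales both depth and duration by
    ``1 - dosage * dive_effect``, so carriers dive shallower and shorter.
    """
    rng = np.random.default_rng(config.seed + 2000 if seed is None else seed)
    samples = [
        s
        for s in truth.samples_in(cohort)
        if not females_only or truth.sex[s] == "F"
    ]
    rows = []
    for sid in samples:
        mult = max(0.05, 1.0 - truth.hypoxia_dosage[sid] * config.dive_effect)
        quality = rng.lognormal(0.0, 0.25)
        n_trips = int(rng.choice([1, 2, 3], p=_TRIP_PROBS))
        for trip in range(1, n_trips + 1):
            n_dives = int(rng.integers(40, 61))
            depth = rng.lognormal(np.log(560.0), 0.30, n_dives) * quality * mult
            duration = (300.0 + 1.3 * depth) * rng.lognormal(0.0, 0.10, n_dives)
            for d in range(n_dives):
                rows.append(
                    {
                        "sample_id": sid,
                        "trip": trip,
                        "dive": d + 1,
                        "depth_m": depth[d],
                        "duration_s": duration[d],
                    }
                )
    return pd.DataFrame(rows)


def degrade_historical(gm: GenotypeMatrix, missing_rate: float, seed: int) -> GenotypeMatrix:
    """Independently set each genotype MISSING with the given rate
    (emulates the patchy coverage of degraded historical DNA)."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.genotypes.shape) < missing_rate
    g = gm.genotypes.copy()
    g[mask] = MISSING
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        contigs=list(gm.contigs),
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        genotypes=g,
        annotations=gm.annotations,
    )
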
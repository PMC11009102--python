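"""Simulator calibrations: reproducibility, drift, bottleneck signatures."""

import dataclasses

import numpy as np
import pytest

from mirounga.diversity import RohParams, roh_result
from mirounga.simulate import (
    ExtinctionError,
    SimConfig,
    degrade_historical,
    simulate_dives,
    simulate_phenotypes,
    simulate_population,
)


def _mean_het(gm, samples):
    idx = [gm.sample_index(s) for s in samples]
    g = gm.genotypes[idx]
    return float((g == 1).mean())


def test_seed_reproducibility():
    cfg = SimConfig(seed=21, n_chromosomes=2, n_sites=60, n_anc=30, n_bottleneck=6,
                    bottleneck_duration=2, final_n=20, burnin_generations=2,
                    post_generations=1, n_sample_pre=4)
    a_gm, a_truth = simulate_population(cfg)
    b_gm, b_truth = simulate_population(cfg)
    assert a_gm == b_gm
    assert a_truth.f_ibd == b_truth.f_ibd
    assert a_truth.pedigree == b_truth.pedigree


def test_monomorphic_start_stays_monomorphic():
    """No mutation, no founder variation: every genotype is hom-ref forever."""
    cfg = SimConfig(seed=2, n_chromosomes=2, n_sites=40, mutation_rate=0.0,
                    recombination_rate=0.0, founder_maf_low=0.0, founder_maf_high=0.0,
                    trajectory=(25,) * 6, cohorts=(("g0", 0, -1), ("g5", 5, -1)))
    gm, _ = simulate_population(cfg)
    assert (gm.genotypes == 0).all()


def test_heterozygosity_decay_matches_wright_fisher():
    """Mean het decays as (1 - 1/(2N))^t at constant N (replicate average)."""
    N, T, reps = 50, 12, 200
    h0 = []
    ht = []
    for r in range(reps):
        cfg = SimConfig(seed=1000 + r, n_chromosomes=1, n_sites=120,
                        chromosome_length=1_000_000, mutation_rate=0.0,
                        recombination_rate=0.01, random_mating=True,
                        founder_maf_low=0.2, founder_maf_high=0.5,
                        trajectory=(N,) * (T + 1),
                        cohorts=(("g0", 0, -1), ("gT", T, -1)))
        gm, truth = simulate_population(cfg)
        h0.append(_mean_het(gm, truth.samples_in("g0")))
        ht.append(_mean_het(gm, truth.samples_in("gT")))
    observed = np.mean(ht) / np.mean(h0)
    expected = (1.0 - 1.0 / (2 * N)) ** T
    se = np.std(np.array(ht) / np.mean(h0), ddof=1) / np.sqrt(reps)
    assert abs(observed - expected) < 4 * se + 0.01


def test_one_generation_drift_variance():
    """Allele-frequency change variance across replicates ~ p(1-p)/(2N)."""
    N, reps = 40, 250
    deltas = []
    p0s = []
    for r in range(reps):
        cfg = SimConfig(seed=5000 + r, n_chromosomes=1, n_sites=60,
                        chromosome_length=600_000, mutation_rate=0.0,
                        recombination_rate=0.0, random_mating=True,
                        founder_maf_low=0.5, founder_maf_high=0.5,
                        trajectory=(N, N), cohorts=(("g0", 0, -1), ("g1", 1, -1)))
        gm, truth = simulate_population(cfg)
        f0 = truth.cohort_allele_freq["g0"]
        f1 = truth.cohort_allele_freq["g1"]
        deltas.append(f1 - f0)
        p0s.append(f0)
    deltas = np.concatenate(deltas)
    p0s = np.concatenate(p0s)
    observed = float(np.mean(deltas ** 2))
    expected = float(np.mean(p0s * (1 - p0s)) / (2 * N))
    assert observed == pytest.approx(expected, rel=0.15)


def test_bottleneck_raises_froh_and_distorts_frequencies():
    """Post-bottleneck samples carry more ROH than pre; allele-frequency
    change through the bottleneck exceeds the constant-N control."""
    base = dict(n_chromosomes=6, n_sites=150, burnin_generations=2,
                post_generations=2, n_sample_pre=15)
    cfg_b = SimConfig(seed=31, n_anc=120, n_bottleneck=10, bottleneck_duration=3,
                      final_n=100, **base)
    gm_b, truth_b = simulate_population(cfg_b)
    params = RohParams(window_snps=20, min_snps=5, min_length_kb=100,
                       max_density_kb_per_snp=1000)
    pre = truth_b.samples_in("pre")
    post = truth_b.samples_in("modern")
    res = roh_result(gm_b, params, thresholds_bp=(100_000,), samples=pre + post)
    froh = res.froh[100_000]
    assert froh.loc[post].mean() > froh.loc[pre].mean()
    assert _mean_het(gm_b, post) < _mean_het(gm_b, pre)
    # frequency distortion vs constant-N control over the same generations
    t_final = max(truth_b.generation.values())
    cfg_c = SimConfig(seed=31, n_anc=120, n_bottleneck=120, bottleneck_duration=3,
                      final_n=120, **{**base, "post_generations": t_final - 2 - 3})
    gm_c, truth_c = simulate_population(cfg_c)
    d_b = np.abs(truth_b.cohort_allele_freq["modern"] - truth_b.cohort_allele_freq["pre"]).mean()
    d_c = np.abs(truth_c.cohort_allele_freq["modern"] - truth_c.cohort_allele_freq["pre"]).mean()
    assert d_b > d_c


def test_extinction_error_names_generation():
    cfg = SimConfig(seed=1, n_chromosomes=1, n_sites=10, trajectory=(3, 3, 3, 3))
    with pytest.raises(ExtinctionError, match="generation"):
        # with N=3 per generation a single-sex generation arrives quickly
        for s in range(200):
            simulate_population(dataclasses.replace(cfg, seed=s))


def test_phenotypes_constant_without_effects_or_noise(bottleneck_sim):
    cfg, gm, truth = bottleneck_sim
    flat = dataclasses.replace(cfg, beta_froh=0.0, beta_lof=0.0, phenotype_noise_sd=0.0)
    phen = simulate_phenotypes(truth, flat)
    females = phen[phen["sex"] == "F"]
    assert females["weaned_per_year"].nunique() == 1
    assert females["weaned_per_year"].iloc[0] == pytest.approx(flat.intercept)


def test_phenotype_effects_enter_linearly(bottleneck_sim):
    """With zero noise the phenotype equals the configured linear predictor."""
    cfg, gm, truth = bottleneck_sim
    noiseless = dataclasses.replace(cfg, phenotype_noise_sd=0.0)
    phen = simulate_phenotypes(truth, noiseless).set_index("sample_id")
    for sid in truth.samples_in("modern")[:20]:
        if truth.sex[sid] != "F":
            continue
        expected = (cfg.intercept + cfg.beta_froh * truth.f_ibd[sid]
                    + cfg.beta_lof * truth.true_lof_burden[sid])
        assert phen.loc[sid, "weaned_per_year"] == pytest.approx(expected)


def test_paternity_counts_sum_to_offspring(bottleneck_sim):
    cfg, gm, truth = bottleneck_sim
    phen = simulate_phenotypes(truth, cfg)
    males = phen[phen["sex"] == "M"]
    modern = set(truth.samples_in("modern"))
    sired = sum(1 for s in modern if truth.pedigree[s][0] in set(males["sample_id"]))
    assert males["paternity_count"].sum() == sired


def test_dive_effect_direction(bottleneck_sim):
    """Higher hypoxia dosage lowers mean dive depth when the effect is on."""
    cfg, gm, truth = bottleneck_sim
    strong = dataclasses.replace(cfg, dive_effect=0.1)
    dives = simulate_dives(truth, strong)
    mean_depth = dives.groupby("sample_id")["depth_m"].mean()
    dosage = np.array([truth.hypoxia_dosage[s] for s in mean_depth.index])
    lo = mean_depth[dosage <= np.median(dosage)].mean()
    hi = mean_depth[dosage > np.median(dosage)].mean()
    assert hi < lo
    trips = dives.groupby("sample_id")["trip"].nunique()
    assert trips.between(1, 3).all()


def test_degrade_historical_rates(bottleneck_sim):
    cfg, gm, truth = bottleneck_sim
    assert degrade_historical(gm, 0.0, seed=1) == gm
    assert (degrade_historical(gm, 1.0, seed=1).genotypes == -1).all()
    deg = degrade_historical(gm, 0.3, seed=2)
    frac = (deg.genotypes == -1).mean()
    n = deg.genotypes.size
    bound = 2.58 * np.sqrt(0.3 * 0.7 / n)
    assert abs(frac - 0.3) < bound + 1e-9
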
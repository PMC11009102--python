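# mirounga

Post-bottleneck fitness genomics for a recovering pinniped population.

The northern elephant seal (*Mirounga angustirostris*) was hunted to a
handful of individuals in the nineteenth century and has since rebounded to
hundreds of thousands.  Such an extreme bottleneck strips genetic diversity,
distorts allele frequencies, and can leave deleterious variants at high
frequency where purifying selection was overwhelmed by drift.  This package
is a tested, reusable reimplementation of the analysis pipeline used to ask
whether that genomic legacy is measurable in the fitness of living animals:
it connects multi-sample genotypes, long-term life-history records, and dive
telemetry.

It is written for population geneticists and ecologists who have a jointly
called, snpEff-annotated VCF plus per-individual phenotype tables, and for
methods developers who want every stage testable against simulated ground
truth.

## What it computes

* **Diversity** — per-genome heterozygosity, heterozygosity in 50-kb
  windows, and runs of homozygosity via a PLINK-style sliding-window scan.
  The genomic inbreeding coefficient is
  `F_ROH = (sum of ROH lengths >= L) / genome length` at length thresholds
  such as 100 kb and 1 Mb.
* **Loss-of-function burden** — LOF loci selected from ANN/LOF annotations
  (`strict` = stop-gained / start-lost; `all` = every flagged locus), each
  genotype coded 1 (hom LOF) / 0.5 (het) / 0, summed per individual.
* **Kinship and paternity** — the KING-robust moment estimator
  `phi = (N_het,het - 2 N_opp-hom) / (N_het(i) + N_het(j))`, paternity
  assignment at the first-degree cut (phi >= 2^-2.5), the copulation-share
  versus paternity chi-square, and the Mann-Whitney LOF contrast between
  sires and non-sires.
* **Fitness regressions** — OLS of pups weaned per year on `F_ROH` and LOF
  burden, multiple regression with centred pairwise interactions, pooled
  two-sample t tests; every fit reports r², F, P and n.
* **Dive performance** — the composite score
  `mean per-trip max depth x P(dive deeper than global median) x relative
  mean duration`, midpoint high/low classification, and pooled 2x2
  minor-allele-frequency contrasts (performance classes, or cohorts
  separated in time).
* **Current Ne from LD** — genotype-dosage r² in physical-distance bins,
  sample-size adjusted, inverted through Sved's relation
  `E[r²] = 1/(1 + 4Nc)` to give `Ne(t)` at `t = 1/(2c)` generations.
* **Mitogenome phylogenetics** — uncorrected p and Tamura-Nei (TN93)
  distances, Saitou-Nei neighbour joining, outgroup rooting and column
  bootstrap support.
* **Synthetic data** — a forward-in-time Wright-Fisher simulator of a
  bottlenecked, polygynous diploid population that emits genotypes (VCF),
  pedigree, realized founder-IBD inbreeding, LOF/hypoxia annotations,
  phenotypes and dive records, so every stage above can be validated
  against known truth.

## Worked example

```python
from mirounga import SimConfig, simulate_population
from mirounga import diversity, stats
from mirounga.simulate import simulate_phenotypes

cfg = SimConfig(seed=1)                     # 20 chromosomes; census 200 -> 20 -> 100
gm, truth = simulate_population(cfg)

pre, modern = truth.samples_in("pre"), truth.samples_in("modern")
het = lambda ids: (gm.genotypes[[gm.sample_index(s) for s in ids]] == 1).mean()
print(f"mean heterozygosity  pre={het(pre):.4f}  modern={het(modern):.4f}")

filt = diversity.filter_sites(gm)           # drop singletons and MAF < 0.01
params = diversity.RohParams(window_snps=20, min_snps=5,
                             min_length_kb=100, max_density_kb_per_snp=1000)
froh = diversity.roh_result(filt, params, thresholds_bp=(100_000,)).froh[100_000]
print(f"mean F_ROH(>100 kb)  pre={froh.loc[pre].mean():.4f}  modern={froh.loc[modern].mean():.4f}")

phen = simulate_phenotypes(truth, cfg).set_index("sample_id")
females = [s for s in modern if truth.sex[s] == "F"]
fit = stats.ols(phen.loc[females, "weaned_per_year"], froh.loc[females].to_frame("froh"))
print(f"weaned/yr ~ F_ROH:   slope={fit.params['froh']:.2f}  "
      f"r2={fit.r2:.3f}  F={fit.fvalue:.2f}  P={fit.f_pvalue:.2e}  n={fit.n}")
```

prints

```
mean heterozygosity  pre=0.3195  modern=0.2632
mean F_ROH(>100 kb)  pre=0.1257  modern=0.2863
weaned/yr ~ F_ROH:   slope=-5.38  r2=0.459  F=39.09  P=1.21e-07  n=48
```

Heterozygosity (here: fraction of assayed segregating sites that are
heterozygous) falls through the bottleneck while `F_ROH` rises, and the
regression recovers the simulated inbreeding depression (the generator's
default effect is -5 pups per year per unit of realized inbreeding; the
fitted slope carries the usual sampling noise at n = 48 females).

A command-line interface wraps the same stages
(`mirounga simulate | roh | lof | paternity | fitness | dive | ldne | mito | run`);
`mirounga run --config demo.cfg --seed 1 --out-dir out/` runs the synthetic
demo end to end and writes per-stage CSVs plus a JSON report, byte-identical
under a fixed seed.

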
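# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, in the order data flows through it.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Genotype model and I/O

Genotypes are held as an individuals x sites matrix of dosage codes
(0 hom-ref, 1 het, 2 hom-alt, -1 missing) over biallelic SNPs only.
Multi-allelic records and indels are dropped on read — not split — so that
site counts stay auditable; phased genotypes collapse to dosage because no
analysis here uses phase.  Coordinates are 1-based inclusive (the VCF
convention); windowing code converts internally.  snpEff-style `ANN`
strings are reduced to a coarse effect class
{stop_gained, start_lost, stop_lost, missense, synonymous, upstream, other}
from the first annotation entry, and the `LOF` INFO key forces the LOF
flag.  A malformed `ANN` keeps the site with class `other` and a warning.
When the historical and modern call sets must be restricted to a known set
of chromosomal scaffolds, `read_vcf` takes an explicit contig include-list
rather than assuming any particular assembly.

## The Wright-Fisher bottleneck simulator

The generator emulates the demography the analyses assume: a large
ancestral population (default census 200, after a 10-generation burn-in
from diverse founders) crashes to ~20 breeders for 3 generations, then
regrows geometrically (rate 0.6/generation) to a final census of 100 —
the scale of the LD-based current-Ne estimate for the study system.
Defaults are a desk-scale rendition: 20 chromosomes of 10 Mb with 300
segregating sites each, 0.1 expected crossovers per chromosome per meiosis
(a 1 cM/Mb map), symmetric per-site mutation at 1e-8.  The recurrent-flip
mutation model keeps the site set fixed so simulator output is VCF-stable;
at these rates its drift behaviour is indistinguishable from infinite
sites.

Generations are discrete and non-overlapping.  Sex is assigned 1:1 at
birth.  Each offspring draws its dam uniformly among females; males are
partitioned into harems (default 4) with a random rank order, and the sire
is the top-ranked male of a uniformly chosen harem with probability
`polygyny_share` (default 0.5, an illustrative value — the study system
reports copulation shares from ~26% to ~90% across harems), otherwise
uniform among the other males of that harem.  A `random_mating` switch
bypasses the harem scheme entirely (sire uniform among all males); the
Wright-Fisher calibrations use it, since polygyny deliberately inflates
male variance in offspring number and lowers Ne below census size.

Realized inbreeding is tracked exactly: every founder haplotype carries a
unique label inherited through meiosis alongside the alleles, and an
individual's `F` is the fraction of assayed sites at which its two
haplotypes carry the same founder label.  This ground truth exists
independently of the ROH caller, which is what makes caller validation
meaningful.  Phenotypes follow a linear model on that truth —
`weaned_per_year = a + beta_FROH * F + beta_LOF * burden + N(0, sigma)`
with defaults a = 1.8 pups/yr, beta_FROH = -5, beta_LOF = -0.05,
sigma = 0.5 — while longevity and fecundity carry no genetic effect, so
null regressions stay null.  Birth years scatter +/- 2 years around a
5-year generation midpoint so that calendar covariates (birth year, first
weaning year) are not collinear.  Dive records give each female 1-3
foraging trips (probabilities 8:68:16, the observed trip-count mix) of
40-60 dives; depths are lognormal around ~560 m and durations increase
with depth, both scaled by `1 - dosage * dive_effect` where dosage counts
minor alleles across five annotated hypoxia loci (default effect 0.05 per
allele).

What the generator does **not** emulate: overlapping generations, age
structure, viability selection during the simulation (fitness acts only
through the phenotype layer), linked-selection effects, genotyping error
beyond uniform missingness, and sequence-level realism (all sites are A/G
SNPs at random positions).  Passing tests therefore demonstrate that the
estimators recover truth under the stated model, not that the model
captures every property of real data.

## Site filter, heterozygosity and ROH

Before ROH assessment, sites are filtered to remove singletons
(minor-allele count <= 1, which also removes monomorphic sites) and minor
allele frequencies strictly below 0.01 computed over non-missing alleles —
a site at exactly the threshold is retained.  Windowed heterozygosity uses
non-overlapping 50-kb windows covering each contig, reporting het and
called counts (empty windows report zeros).  Genome-wide heterozygosity is
the het count divided by the number of sites passing filters, with the
denominator supplied explicitly so callable-site totals from upstream
pipelines can be used.

The ROH caller follows the PLINK `--homozyg` scanning definition: a window
of `window_snps` consecutive SNPs slides along each contig; a window
passes when it has at most `max_het` heterozygous and `max_missing`
missing calls; each SNP's hit rate is the passing fraction of windows
covering it; SNPs with hit rate >= `hit_threshold` are run-eligible; and
maximal eligible stretches are split at inter-SNP gaps above `max_gap_kb`,
then reported when they satisfy `min_snps`, `min_length_kb` and the
kb-per-SNP density cap.  Segment coordinates are the first and last SNP
positions.  Contigs with fewer SNPs than the window are scanned with a
single truncated window (with a warning).  Defaults mirror PLINK's
documented values (50 SNPs / 1 het / 5 missing / 0.05 / 100 SNPs / 1000 kb
gap / 50 kb-per-SNP) with 100-kb and 1-Mb length thresholds; for sparse
maps such as the simulator's (~30 kb marker spacing) the tests and the
demo pipeline use density-appropriate settings (window 20, min 5 SNPs,
density cap 1000 kb/SNP), exactly as PLINK users retune for low-density
panels.  `F_ROH` divides the summed length of segments above a threshold
by the genome length, defaulting to the sum of contig lengths in the VCF
header because no other denominator is universally available.  Whether
length thresholds are applied at call time or post hoc gives the same
result under this definition; the gap/density interplay is the one place a
different scanner could legitimately differ, so the caller is pinned by an
independent reference scan in the tests rather than by comparison to any
external binary.

## LOF burden

The LOF allele is taken to be the alt allele (snpEff annotates effects of
the alt allele); a per-site override is available.  `strict` selection
keeps stop-gained and start-lost sites; `all` keeps everything flagged
LOF.  Monomorphic sites are excluded since they carry no contrast.  The
burden codes hom-LOF as 1, het as 0.5, else 0, and sums across loci;
missing genotypes leave both the numerator and that individual's locus
count, so `relative_freq = burden / n_called` stays a frequency.  An
individual with no called locus reports missing, never zero.

## Kinship, paternity and male-success tests

KING-robust kinship is computed over jointly called sites from
heterozygote and opposite-homozygote counts, which makes it invariant to
ref/alt relabelling and equal to 0.5 for self-comparison.  Paternity
assigns each pup to the candidate male of maximal kinship when it reaches
2^-2.5 ~ 0.177, the midpoint between first- and second-degree expectation;
exact ties leave the pup unassigned, and known mothers are excluded as
candidates (their kinship to the pup is reported for QC).  The
copulation-vs-paternity test is a 1-df goodness of fit of observed
(focal, other) paternities against the copulation share, two-sided
upper-tail p, with Yates continuity correction behind a flag (off by
default; the published per-harem chi-square values are not exactly
reproducible from the printed shares and sample sizes under either
construction, so the package exposes the construction rather than
targeting them).  The sire/non-sire LOF contrast is a Mann-Whitney
rank-sum with tie-corrected normal approximation and no continuity
correction, reporting the signed z and the one-sided p for "sires carry
fewer LOF homozygotes"; fully tied data returns (0, 0.5).

## Regression battery

OLS uses listwise deletion with the effective n logged and reported, since
each analysis legitimately has its own n when phenotype columns have
different missingness.  The overall F is `(r²/k) / ((1-r²)/(n-k-1))`.  A
rank-deficient design is an error naming the collinear columns.  The
interaction model centres factors before forming pairwise products, and
per-term p values are coefficient t tests (type-III-equivalent for this
parameterization).  The two-sample t is pooled-variance by default
(df = n1 + n2 - 2) with Welch optional.  One-sided p values are never
silent: they appear only where a flag requests them, and outputs record
sidedness.

## Dive performance and MAF contrasts

The depth threshold is the median over the pooled dives of all individuals
(a single dataset-wide value), and "deeper than" is strict — with all
dives at one depth every score is zero, which the tests document.  The
high/low midpoint is (min + max)/2 with scores exactly at the midpoint
classed low.  MAF contrasts fix the minor allele in the pooled sample
(ties at 0.5 broken toward alt and flagged), then sum allele counts across
candidate sites into one 2x2 table for a 1-df chi-square without
continuity correction; per-site tables are emitted alongside, and
monomorphic candidates are excluded with a warning.  The temporal cohort
contrast halves the tail (flagged one-sided) when the observed direction
matches the declared alternative.  The package bundles the published
genotype counts at six hypoxia-candidate SNPs in 46 high- and 46
low-performance divers; the pooled-2x2 construction applied to those
counts gives a different combined chi-square than the one printed in the
source study (whose exact pooling is unstated), so the fixture asserts
the directional claim and group sizes and reports the statistic it
computes.

## LD-based Ne

Dosage r² (squared Pearson correlation, appropriate for unknown phase) is
computed for within-contig pairs between 50 kb and 4 Mb, adjusted by 1/n
for unphased samples (1/(2n) with phased data), binned by physical
distance (log-spaced bins by default), and inverted through
`Ne = (1/(4c)) (1/mean(r²_adj) - alpha)` with `t = 1/(2c)`.  The
distance-to-recombination map is linear at 1 cM/Mb by default — the
transparent baseline — with a finite-distance modifier `c = d(2-d)/2`
behind a `sved_feldman` flag and the mutation-adjusted `alpha = 2.2`
available beside the default 1.  Estimates from short-distance bins
reflect deeper time horizons (`t = 1/(2c)`) and should only be trusted
when the population has been at the relevant size for that long; the
calibration accordingly evaluates bins from 0.5-4 Mb after 120 generations
at constant size.

## Mitogenome distances and trees

p-distance uses pairwise deletion (gaps and N removed per pair, not per
column) because historical sequences are patchy.  TN93 uses the closed
form with base frequencies estimated from the sequence pair; a
non-positive logarithm argument (saturation) returns infinity, flagged by
downstream checks.  Neighbour joining is the Saitou-Nei Q-criterion
agglomeration with ties broken by the lowest taxon-index pair, negative
branch lengths clamped to zero, and optional rooting on an outgroup by
splitting its edge at the midpoint.  Bootstrap support resamples columns
with replacement and maps the support of each internal bipartition of the
point-estimate tree (not a consensus), matching how such trees are
usually presented.

## Problem sizes and acceptance checks

The validation suite sizes simulations to desk scale: ROH oracle
equivalence on 50 random 5,000-SNP instances; slope recovery with 200
modern females over 6,000 sites, 200 phenotype replicates (CI coverage)
plus a 500-replicate null for the type-I rate in the acceptance script;
paternity on a 220-individual two-generation pedigree at 6,000 SNPs;
heterozygosity-decay calibration over 200 replicates of a 120-site
chromosome at N = 50; and LD-Ne calibration at constant N in {50, 100,
200} after 120 generations.  These sizes make the whole suite run in well
under a minute per stage while leaving Monte-Carlo error comfortably
inside the asserted tolerances.

## Known limitations

The ROH caller is a scanning heuristic, not an HMM; very short or
marker-poor IBD segments are invisible, which attenuates `F_ROH` slightly
relative to pedigree truth (the recovery tests quantify the effect at
their marker density).  The KING estimator assumes a reasonably
homogeneous sample; strong substructure biases it.  The Sved inversion
assumes drift-recombination equilibrium at each bin's time horizon and a
correct genetic map.  The simulator's harem model is a two-parameter
caricature of elephant-seal polygyny, adequate for testing the paternity
machinery but not for demographic inference about real harems.
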
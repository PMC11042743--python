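# Methods

This note records the models, estimators and numerical conventions
behind `wpoly`, the choices made where several defensible options
existed, and what the synthetic cohorts do and do not establish.

## The inference problem

A discrete trait expressed only in females of a ZW species can be
controlled by the maternally co-inherited genome (W chromosome, mtDNA).
Establishing that architecture requires: (i) clean sex-aware genotypes,
since the W is haploid in females, absent in males, repeat-rich, and
prone to misassembly against the Z; (ii) evidence that trait-associated
variation is confined to the W (association scan, windowed F_ST);
(iii) evidence that the W haplogroups predate the species split
(topology weighting, net-divergence dating) rather than arising by
introgression (ABBA–BABA) or a recent sweep (Tajima's D).  `wpoly`
implements each step as a library function plus an estimator object
with `fit()`/`summary()`, and wires them into one pipeline.

## Synthetic cohorts

`simulate.simulate_cohort` draws, per chromosome class and window, a
genealogy from a Hudson-style structured coalescent: discrete lineages,
exponential waiting times with pairwise rate k(k−1)/(2N) per deme
(N in sequence copies), deterministic population merges at epoch times,
no recombination within a window, windows independent.  Window
independence mirrors the windowed estimators downstream; intra-window
recombination is deliberately absent (non-goal).

Demography. Autosomes: one panmictic deme per species (2·ne_auto
copies), merged at `t_species`.  Z: same topology with 1.5·ne_auto
copies (males carry two Z, females one).  W: four demes —
species × haplogroup — of ne_w/2 copies each; same-haplogroup demes
merge across species at `t_species`, haplogroups merge at `t_plumage`
into an ancestral W of ne_w copies.  The ne_w/2 split encodes a
balanced 50/50 polymorphism; balancing selection itself is not
modelled — two isolated allelic classes until `t_plumage` reproduce the
deep two-haplogroup genealogy without selection dynamics.  Each female's
morph label equals her W haplogroup by construction; males carry no W
and an "unknown" morph.

Mutation. Infinite sites within a window: Poisson(μ·L·branch) mutations
per branch, unique positions drawn without replacement, derived
(=ALT) coded against a known ancestral (=REF) state, which gives
ABBA–BABA exact truth.  Draws whose segregating-site count exceeds the
window length are redrawn; configurations whose *expected* count
exceeds 1.5·L are rejected as parameter errors.  Defaults are the study
conditions the estimators assume: μ_auto = 1.01×10⁻⁸ /site/generation,
μ_W = μ_auto/2 (maternal restriction shields the W from the
mutation-richer male germ line), 50-kb windows.

Extras. `gene_flow_p2p3` applies an admixture pulse at sampling time:
each optatus-rufous autosomal haplotype derives species-1 ancestry with
that probability — the simplest construction yielding excess ABBA
between P2 and P3.  `t_resize`/`resize_factor` apply a step size change
to all demes, enabling expansion (negative Tajima's D) and bottleneck
scenarios.  Reproducibility: every window has its own
`default_rng([seed, class, window])` stream, so outputs are
byte-identical for a config and windows are independent.

Coverage. `simulate_coverage` emits per-sample window depths around a
target mean: W ≈ half depth in females and zero in males, Z the
converse, autosomes full depth in both.  Injected "repetitive" W
windows gain depth in both sexes; "misassembled" Z windows show female
excess over males.  Gaussian noise (default SD 5% of the mean) stands in
for real depth dispersion; mask tests use 2% so that rule recovery is
exact.  What this does not emulate: mapping bias, GC effects,
batch/library structure, genotyping error — so passing mask tests shows
the rules are implemented correctly, not that the thresholds are optimal
for any particular dataset.

## Filtering and masks

Rules run in a fixed order so removal counts are reproducible:
site-level (QUAL < 20; site DP > 2× chromosomal mean; site DP below the
sample count; MQ < 30; RPBZ outside ±3), then genotype-level depth
(diploid < 4×, haploid < 2× → missing), then sites with > 20% missing
genotypes, then 5-bp linked-SNP pruning (chains of SNPs with
consecutive spacing < 5 bp keep only the highest-MAF SNP; ties break to
the lower coordinate).  Absent annotations never trigger a rule —
"not recorded" is distinct from "failing" — which also makes filtering
idempotent.  Heterozygous calls on haploid-expected chromosomes are
resolved by a two-sided exact binomial test on allele depths at p = 0.5:
P < 10⁻⁵ → major allele, otherwise missing.

Masks: W windows are masked on any male depth > 1× (raw depth; a
library-scaled variant was considered but raw matches the rule's intent
of "any male reads at all") or > 25% of females above their autosomal
reference (median of autosomal window depths); Z windows on > 25% of
males above 2× their reference or > 25% of females above theirs; mtDNA
windows on any sample outside (1/3, 2)× its own mtDNA mean.  NUMT-style
interval lists are consolidated by merging hits separated by less than
500 bp (transitively).  The log2(F/M) scan scales each sample to the
smallest library total and adds a 0.01 pseudocount to both means.

## Estimators

π uses the unbiased per-site form 2p(1−p)·n/(n−1) (equal to the mean
pairwise difference); D_XY is p₁(1−p₂)+p₂(1−p₁); both are divided by
the *callable* length of the window, not the SNP count, so monomorphic
sequence dilutes them correctly.  Windows below a callable fraction
(default 20%) are dropped.  F_ST is Hudson (1992) as a ratio of per-site
sums, numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
denominator p₁(1−p₂)+p₂(1−p₁); negative site numerators are retained,
so a window value may be slightly negative — that is information, not an
error.  Singletons (pooled minor-allele count of 1) are excluded from
π/D_XY/F_ST scans by default and always included for Tajima's D, which
follows the 1989 formulation with the standard a₁…e₂ constants and is
reported missing (not 0) when S = 0.  With missing data the per-site
sample size enters π and S directly while the constants use the group's
sequence count; at the simulator's complete-data output this is exact.

Association: per SNP, a binomial likelihood ratio comparing separate
case/control allele frequencies against the pooled frequency, 2Δℓ
referred to χ²(1).  Counting is ploidy-aware (haploid calls contribute
one allele).  This replaces a genotype-likelihood score test
deliberately: on called genotypes at moderate depth the two are
asymptotically equivalent, and no read-level data exist in scope.  At
small allele counts the test is slightly anticonservative/discrete; the
observed type-I rate at 2×20 alleles with a 0.15 MAF floor fluctuates
around 0.04–0.08 across simulation seeds, with sites inside a window
sharing one genealogy (hence the calibration check aggregates false
positives per window and uses a clustered standard error).  Permutation
nulls reshuffle phenotypes with group sizes fixed and recompute the full
scan.  The Bonferroni threshold defaults to the scan's own test count,
with an override to reproduce an externally fixed family size.

ABBA–BABA: frequency formulation, abba = (1−p₁)p₂p₃(1−p₄),
baba = p₁(1−p₂)p₃(1−p₄), D = Σ(abba−baba)/Σ(abba+baba).  With an
outgroup population its major allele defines the ancestral state (ties
skipped); with ancestral-coded input (the simulator) the reference
allele is ancestral and p₄ = 0.  Significance by delete-one block
jackknife over contiguous blocks of equal genomic span (equal SNP count
optional — the appropriate blocking is data-dependent and both are
provided); blocks without informative sites are dropped from the
jackknife and the effective count reported.

Topology weighting: non-overlapping 100-SNP windows (by SNP index);
windows where any individual has fewer than 10 scored genotypes are
skipped.  Per window, neighbor joining (scikit-bio) on the proportion
of differing alleles over pairwise-complete sites.  NJ on Hamming
distances replaces per-window ML tree inference deliberately: weighting
consumes only the topology, and NJ is deterministic and dependency-free.
Haplotype tips come from the table's allele slots; for real unphased
diploid data this treats the two slots as phased sequences — a caveat
for autosomal windows on real data (the simulator emits true
haplotypes).  Weights enumerate one-tip-per-group combinations
exhaustively up to a limit (default 20,000) and Monte-Carlo sample
beyond it; topologies are matched by canonical split sets, making the
encoding rotation-invariant.  Classification: Species if its weight
≥ 0.5 (inclusive), else Plumage, else ILS if the *summed* remaining
weight ≥ 0.5 (a single-topology variant is available), else unresolved;
unresolved windows stay in the denominator by default.  Category
proportions get percentile bootstrap CIs (default B = 1000).

Dating: D_a = D_XY − (π_X+π_Y)/2 (unclamped), τ = D_a/(2μ),
age = τ·g with g = 2.76 years; ka values are rounded to integers for
reporting.  D_a assumes the ancestral population held as much variation
as the contemporary ones.  W dating uses μ_W = μ/2; Z and autosomes use
μ.  The plumage/species ratio is computed per bootstrap replicate as the
ratio of window means (never a mean of per-window ratios, which explodes
when a window's species D_a nears zero); replicates with non-positive
species means are skipped and counted.  Extrapolating an absolute
polymorphism age multiplies the W ratio by the autosomal τ and g — an
interpretation helper, flagged as such.

PCA: alt-dosage matrix, singletons excluded, missing dosages
mean-imputed per site (a probabilistic treatment would be preferable at
high missingness; at simulated completeness it is irrelevant), SVD of
the centred matrix.  Scores are given a fixed orientation (the
largest-|score| sample positive) and min-max scaled to [0,1], removing
the sign ambiguity that otherwise breaks reproducibility.  Species and
morph effects per component: two-sided Wilcoxon rank-sum (exact for
small n), Bonferroni-multiplied with n = 24 by default (six components
× two factors × two chromosome sets).

## Problem sizes and reproducibility checks

The test-suite and acceptance-script simulations are sized for a single
CPU: split-time recovery uses the default study conditions (ne = 5×10⁴
per species, t_species = 5×10⁴ generations, 1500 windows of 50 kb —
window-to-window coalescent noise, not estimator bias, limits accuracy,
and ~10³ windows push the Monte-Carlo error of the mean to a few
percent); the W ratio uses 200 such windows with
t_plumage = 10·t_species; gene-flow controls use 200 × 20-kb windows.
Under these conditions the autosomal τ̂ lands within a few percent of
truth (the 15% band in the tests is dominated by coalescent noise, not
estimator bias), the W bootstrap ratio brackets 10, injected 20%
admixture yields jackknife Z ≫ 3 while the no-flow control stays within
3 SE of zero, pooled deep haplogroups give strongly positive windowed
Tajima's D and a 50-fold recent expansion strongly negative values.

## Known limitations

- No recombination within windows and free recombination between them;
  LD structure at intermediate scales is not represented.
- Balancing selection is modelled only through its genealogical
  consequence (long-isolated allelic classes), not its dynamics; morph
  frequencies are fixed at 50/50.
- Depth simulation is Gaussian around class means; no read-level error,
  mapping bias or batch structure, so filter thresholds are exercised,
  not validated against real noise.
- Tajima's D with heavy missingness uses the group sequence count for
  its normalising constants; acceptable at the near-complete call rates
  the pipeline targets.
- The allele-count LRT is mildly miscalibrated at very small allele
  counts; use the MAF floor or permutation thresholds when samples are
  few.
- mtDNA genotypes are not simulated (coverage fixtures only), matching
  the restricted role of mtDNA in the intended analyses.
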
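# Methods

This note documents the statistical models implemented in `rarepath`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that affect results.

## Synthetic cohort model

The generator (`rarepath.synthetic_data`) produces a case-control cohort on
one synthetic chromosome with known ground truth.

**Layout.** `n_genes` genes of `gene_length` bp (default 20 kb) separated
by `gene_gap` bp (5 kb), each holding `variants_per_gene` variants (default
8, matching an exome-like density of roughly eight sites per gene) at
positions uniform within the gene span. Coordinates are 0-based half-open
internally; files use the conventions of their formats (1-based VCF
positions, 1-based inclusive gene spans in the annotation TSV).

**Allele-frequency spectrum.** Each variant is assigned to one of three
strata — very rare (MAF < 1%), rare (1–5%), common (5–50%) — with
probabilities `very_rare_fraction` (default 0.74), `rare_fraction −
very_rare_fraction` (0.13) and the remainder, reproducing the observed
dominance of very rare sites in exome data. Ancestral MAFs are drawn from
Beta distributions skewed toward the low end of each stratum (Beta(1,3)
and Beta(1,2) rescaled) and Uniform(0.05, 0.5) for common sites.

**Population structure.** Subjects are split evenly into `n_populations`
(default 3) subpopulations. Per-population allele frequencies follow the
Balding-Nichols model: Beta draws around the ancestral frequency with
variance p(1−p)·F, where F is the single `divergence` parameter (default
0.10, a between-continental-population magnitude). Genotypes are
Hardy-Weinberg binomial draws within each population.

Two ascertainment steps keep the realized cohort faithful to its
configuration. First, a variant whose post-drift *expected sample MAF*
(the mean of the population frequencies, folded at 0.5) leaves its stratum
is redrawn, so the configured spectrum fractions hold in the sample, not
just ancestrally. Second, a variant monomorphic in the realized genotypes
is redrawn entirely: cohort variant lists describe observed, segregating
sites, and a rare-variant analysis of invariant columns is meaningless.
Both steps are rejection sampling on the variant, not edits to genotypes,
so within-population Hardy-Weinberg structure is preserved.

**Phenotype.** Affection is logistic:

    logit P(affected) = b0 + carrier_effect·carrier + smoke_effect·smoke
                         + pop_offset

with `carrier` the indicator of ≥ 1 minor allele at any rare (MAF < 0.05)
variant of a causal gene, smoking a Bernoulli(0.25) covariate with
log-odds `smoke_effect` (default 0.69, i.e. odds ratio 2, matching the
observed case/control smoking contrast), and small per-population offsets
(±0.1) giving mild confounding. When `base_rate` is unset, b0 is solved by
bisection so that the expected case fraction equals
`case_fraction_target` (default 0.30); an explicit `base_rate` is used
directly as logit(base_rate). Causal genes (default 5) are drawn from the
genes of designated pathways, so pathway enrichment has a ground truth.
Age and sex are simulated but carry no effect: they act as null covariates
downstream.

**What the generator does not emulate.** Realistic sequence content,
linkage disequilibrium beyond drift-induced structure (variants are
conditionally independent within a population), quantitative traits,
genotyping error and missingness processes. Passing tests therefore
demonstrate the statistical machinery under a clean generating model, not
robustness to the artefacts of real genotype data.

## Quality control

**HWE filter.** Per variant, a 1-df χ² goodness-of-fit of genotype counts
against p², 2pq, q² expectations from the sample allele frequency, computed
in controls only (a true association distorts genotype proportions among
cases); variants with p < 10⁻⁴ are removed. Monomorphic sites return p = 1
by convention. The χ² form (rather than an exact HWE test) is adequate at
n ≈ 700 and α = 10⁻⁴ for common variants, but is anti-conservative for
very rare alleles — a single minor-allele homozygote with no heterozygotes
yields a large statistic — so with a pooled multi-population cohort the
filter removes somewhat more than α of the sites (Wahlund effect plus rare
homozygotes). That behaviour mirrors what the same filter does in real
structured cohorts.

**LD pruning.** Greedy windowed pruning (window 50 variants, step 5,
r² > 0.2 drops the lower-MAF member, ties drop the later position) —
standard practice parameters; all exposed in the pipeline config.

**MDS.** Pairwise distance 1 − IBS with IBS the mean over non-missing
variant pairs of (2 − |dᵢ − dⱼ|)/2, followed by classical (Torgerson) MDS:
double-centre the squared distance matrix and take the top-k
eigencoordinates. Axis signs are arbitrary (eigendecomposition); missing
dosages are excluded pairwise. The first two components separate the three
simulated populations cleanly at divergence ≥ 0.05.

## Collapsing association

A unit's rare set is the subset of its variants with sample MAF strictly
below `maf_max` (default 0.05, covering both rare strata; the minor allele
is defined on the full sample). The carrier indicator is 1 iff the subject
has ≥ 1 minor allele in the rare set; missing dosages count as
non-carrying. The 2×2 carrier-by-status table is tested by Pearson χ²
(1 df, no continuity correction) when all four expected counts are ≥ 5
(Cochran's rule), else by the two-sided Fisher exact test (summing
hypergeometric probabilities ≤ the observed table's). Units with an empty
rare set or a degenerate carrier margin are flagged untestable and carry
no p-value — they are excluded, not imputed, downstream.

Sliding windows of 1/5/25/50/100 kb advance by half their size
(overlapping windows; the step is not dictated by the method and is
config-exposed), tiling from the first to the last variant-bearing
position with starts at multiples of the step and the final window
truncated at the span end. Common variants (MAF ≥ `maf_max`) are tested
per SNP on the allelic 2×2 table (minor-allele counts among 2n alleles,
cases vs controls) under the same expected-count rule; the genotypic 2×3
reading is deliberately not the default, the allelic test being the
minimal 1-df interpretation. No multiple-testing correction is applied at
this stage; downstream use is rank-based.

**Calibration note.** At the default exome-like density a 5-kb window
holds ~2 rare variants and few carriers, so most windows route to the
Fisher branch, whose discreteness makes the attainable p-values coarse.
The measured null type-I error of the window scan at α = 0.05 is ≈ 0.033
(60 null cohorts, 43k testable windows) — slightly conservative, as
expected for exact tests on sparse tables; the χ²-eligible subset sits at
≈ 0.04–0.05. Power at a realistic signal (carrier frequency 15% in 209
cases vs 5% in 488 controls) is ≈ 0.86 at α = 0.001.

## Gene scores and MLP enrichment

Five statistics map unit p-values to a per-gene score on the −log₁₀ p
scale: S1 = −log₁₀ of the gene-wise collapsing p; S2/S3 = −log₁₀ of the
minimum / the mean of −log₁₀ over the 5-kb windows overlapping the gene
(≥ 1 bp overlap on half-open coordinates; containment is available behind
a flag); S4/S5 likewise over the SNPs in the gene. Log base 10 throughout —
the base only rescales scores and cannot change ranks within a statistic.
Genes with no testable unit are omitted rather than scored 0: imputing
p = 1 would bias set statistics toward sparsely covered genes. S3 ≤ S2
always (mean ≤ max); S3 is kept on the score scale rather than converted
back to a p-value, which again cannot change within-statistic ranks.

A pathway's observed statistic is the arithmetic mean of its members'
scores, restricted to the scored universe; sets with fewer than
`min_set_size` (default 3 — a mean of fewer scores is unstable) scored
members are skipped with a reason. The null is *competitive gene-label
resampling*: each permutation draws a same-size set from the universe
without replacement and recomputes the mean; the set p-value is
(1 + #{null ≥ observed}) / (n_perm + 1) — the plus-one correction keeps
Monte-Carlo p-values off zero. Resampling gene labels (rather than
permuting phenotypes) matches the statistic's gene-expression origins and
avoids rerunning the genome scan per permutation; phenotype permutation is
a documented extension point, not implemented. Default n_perm is 10,000
for pipeline runs and 1,000 in tests and experiments. Sets are ordered by
permutation p ascending, ties broken by larger observed statistic, then
name; each set's null stream is an independent child of one master seed,
so results do not depend on analysis order. No across-set multiple-testing
correction is applied; the ranking itself is the product.

## Stochastic gradient boosting

Binomial-deviance boosting from the log-odds of the case fraction. Each of
`n_trees` iterations draws a `subsample_fraction` row sample (default 0.5,
without replacement), fits a least-squares regression tree to the current
residual y − p̂ — grown best-first to at most `max_terminal_nodes`
(default 8) leaves, splits maximizing squared-error reduction — sets each
leaf to the one-step Newton value Σ(y − p̂)/Σ p̂(1 − p̂) (clamped to ±8
against near-pure leaves), and adds the tree with weight `shrinkage`
(default 0.01). Split finding is histogram-based: features are pre-binned
(exact bins for ≤ 64 distinct values — which covers 0/1/2 dosages and
binary covariates — otherwise 64 quantile bins), making each node
expansion one weighted bincount; thresholds are reported on the raw scale
(midpoints between adjacent values), so prediction on unbinned data is
exact for binned cuts.

Variable importance accumulates each split's squared-error improvement on
its variable and rescales so the maximum is 100; the 1/n_trees averaging
constant cancels under rescaling. Variables at or above
`importance_cutoff` (default 7.00) on the scaled axis form the selected
set — with many correlated or noise features this set reliably contains
the causal variables *plus false positives*, which is the expected and
tested behaviour of importance screening. The pipeline feeds the model
preselected features: the top common SNPs by association p, the rare
variants inside the top 5-kb collapsing windows (both counts
config-exposed, default 100), the MDS components, and age/sex/smoking.

Agreement with an independent reference (scikit-learn's
`GradientBoostingClassifier`, matched hyperparameters, no subsampling) is
within 0.04 mean absolute predicted probability at 500 trees and shrinkage
0.01; residual differences trace to split-criterion details (plain vs
Friedman MSE) and tie-breaking.

## Pipeline determinism and scale

Every stage's outputs are pure functions of (inputs, config, master seed):
stage seeds are derived by hashing the master seed with the stage name,
TSVs are written at %.17g so floats round-trip exactly, and resume loaders
parse them back with round-trip precision — a rerun, full or partial,
reproduces every output byte for byte. The manifest records per-stage
output hashes, seeds and wall times; a stage whose recorded outputs are
intact is resumed from disk rather than recomputed.

Validation experiments run at reduced scale chosen to keep the full suite
fast while leaving Monte-Carlo error well inside the tested margins:
10 null cohorts (~7,000 windows) for carrier-test calibration, 1,000 set
tests × 1,000 permutations for MLP calibration, 100 runs for enrichment
recovery, 50 seeds × 500 trees for SGB recovery, and exhaustive
enumeration of all ~162,000 2×2 tables with margins ≤ 30 for the Fisher
oracle. These sizes are the package's own defaults in
`rarepath.experiments` and are arguments, not constants.

## Known limitations

- The generator's variants are exchangeable within strata; there is no LD
  beyond shared drift, so LD pruning is exercised only lightly and the
  false-positive structure of SGB screening on real, correlated SNPs will
  differ.
- The exact HWE test is not implemented; the χ² filter over-removes very
  rare variants (documented above) exactly as the same filter does in
  practice.
- Fisher discreteness leaves the sparse-window carrier scan mildly
  conservative (type-I ≈ 0.033 at α = 0.05 under the default density).
- Gene-label permutation tests the competitive null (is this set better
  than a random set of scored genes), not the self-contained
  phenotype-permutation null.
- Rare and common gene scores are never combined into one statistic; each
  of the five statistics is analysed separately.
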
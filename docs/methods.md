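# Methods

This note documents the models, numerical choices and known limitations of
`pathgwas`. It describes what the code does and why the defaults are what
they are; every empirical statement here is one the test suite or
`scripts/acceptance.py` computes.

## The problem setting

The package targets cohorts of a few hundred to a couple of thousand
individuals with related members (sibling pairs), several correlated
quantitative traits, and genome-wide SNP dosages. At these sample sizes a
complex polygenic trait yields no genome-wide-significant variants; the
pipeline therefore works with *suggestive* variants (p < 1e-5 by default)
and moves the unit of interpretation from the variant to the gene and from
the gene to the pathway. The end product is not an enrichment p-value but an
inventory of gene–pathway associations per trait plus a permutation-based
measure of how strongly two traits' pathway sets coincide.

## Synthetic cohorts

`pathgwas.sim` generates every input the pipeline consumes. What it emulates,
and how:

**Genotypes.** SNPs live on chromosomes in LD blocks of fixed size with
uniform 5 kb spacing, 1-based strictly increasing positions. Within a block,
founder haplotypes are drawn from a Gaussian-copula model: a per-haplotype
latent factor with loading √ρ induces equicorrelation, and alleles are
thresholds of the latent variables at Φ⁻¹(MAF). The latent ρ is calibrated
per block by bisection on the bivariate-normal orthant probability so that
the *binary* allele correlation squared matches the requested
`within_block_ld` at the block's mean MAF; because the calibration targets
the population correlation, the realized sample mean r² is attenuated
slightly below the target (finite panel, MAF spread), but between-block r²
is at the 1/n sampling floor — the property the downstream LD logic needs.
Each unrelated individual receives two fresh founder haplotypes per block;
each sibling pair receives Mendelian transmissions from four parental
haplotypes, so sib relatedness is 0.5 in expectation with the natural
transmission variance. Missing calls (sentinel −1) are uniform at
`missing_rate`. An optional two-subpopulation mode applies Balding–Nichols
frequency drift (default Fst 0.05) for exercising PC correction.

**Traits.** Per-SNP effects on *standardized* dosages are drawn from a
multivariate normal across traits with the requested genetic correlation
matrix (eigen square root, so rG = 1 is legal). When a non-identity
correlation is requested and no explicit causal sets are given, traits share
a nested causal pool — with disjoint causal sets the realized rG would be
zero no matter how effects correlate. The additive genetic value is
standardized and scaled to variance h²; environmental noise has variance
1 − h², so the realized genetic share of (genetic + environmental) variance
equals h² by construction up to the noise draw (verified at ±0.05 over 20
replicates at n = 500, m = 5000). Age (uniform 22–36) and sex effects are
added afterwards, i.e. h² is defined net of covariates. An `equal_effects`
option replaces the normal magnitudes with unit magnitude and random
(correlated) sign, for designs that need every causal variant detectable.

**Annotation.** Genes tile fixed genomic windows (a configurable number of
SNP spacings wide); tiling by position rather than by SNP count keeps gene
boundaries stable when QC removes SNPs. Each gene splits into UTR5 /
exon–intron alternation / UTR3 sub-intervals with boundaries midway between
SNPs (ncRNA genes use ncRNA_exonic/ncRNA_intronic), stored 0-based
half-open; SNP positions are 1-based and converted at lookup. eQTL rows
cover a configurable SNP fraction with q-values drawn below 0.05 at a
controlled rate. Pathway databases are gene-set collections with
configurable size range and cross-database redundancy (sets copied into a
second database under fresh ids).

What the generator does **not** emulate: realistic human LD decay,
imputation uncertainty, the X chromosome, non-Gaussian phenotypes (skew,
ceilings — memory-test scores in real batteries have both), assortative
mating, and admixture beyond two discrete subpopulations. Tests passing on
this generator show the machinery is correct under its stated model, not
that real-data results are unbiased under model violations.

## Quality control

Filters run in a fixed order — individual call rate, then SNP call rate, MAF
and HWE computed on the post-missingness data — with strict inequalities
(MAF > 0.05, call rates > 0.95, HWE p > 1e-6 by default). Each removed SNP
is attributed to the first filter it failed. The pass repeats until nothing
more is removed: a single pass is not exactly idempotent because removing
SNPs changes individual call rates, and idempotence is a contract the rest
of the pipeline (and the tests) rely on. Monomorphic SNPs fall to the MAF
filter. HWE is tested in all individuals, not founders only — with sib pairs
this slightly overcounts dependent genotypes and is a known divergence risk
on family data.

The HWE test is the conditional exact test: enumerate every heterozygote
count compatible with the observed allele counts, compute each
configuration's probability in closed form via log-gamma, and sum those no
more probable than the observed table (ties included, tolerance 1e-12
relative). It matches an exact-rational enumeration oracle for every table
with n ≤ 50. A 1-df chi-square variant is available for speed at very large
counts.

## GRM, PCs, REML

The GRM standardizes each SNP by its sample allele frequency and averages
cross-products; missing dosages are mean-imputed per SNP (contributing zero
after centring). The sparse variant zeroes off-diagonals with |A_jk| below
the cutoff (default 0.05), keeping the family block structure while
discarding estimation noise among unrelateds. PCs are the top eigenvectors
of the standardized-genotype covariance after greedy sliding-window LD
pruning (r² > 0.2, window 50, step 5 — conventional values, exposed in the
signature), signs fixed so each component's largest-magnitude entry is
positive.

Variance components are estimated by average-information REML with
safeguards: the AI step is accepted only if the restricted likelihood does
not decrease, backing off through step-halving (1, 1/2, 1/4, 1/10) and
falling to an EM-REML step otherwise; components are floored at 1e-8·var(y)
and flagged `constrained` when they sit on the floor; convergence is
|Δ log-likelihood| < 1e-6 within 100 iterations, with non-convergence
raising an error that carries the last iterate. SEs come from the inverse AI
matrix; the h² SE by the delta method. The implementation is cross-checked
in the tests against an independent grid maximization of the restricted
likelihood in the GRM eigenbasis. Supplying several GRMs (e.g. from
`maf_bin_grms`, MAF-quartile bins) gives a stratified variance partition;
LD-score stratification is deliberately not implemented at this scale.

## Association and genetic correlation

`mlma_loco` rebuilds the GRM excluding each target chromosome, re-estimates
variance components under that GRM (a fast approximate mode skips per-
chromosome re-estimation by forcing components), then tests the
chromosome's SNPs by GLS in the eigenbasis of the leave-one-out GRM. The
per-SNP residual scale is re-estimated (t-test with n − p degrees of
freedom), which makes the σ_g² = 0 case *identical* to ordinary least
squares — the anchor the acceptance suite verifies at 1e-6 relative — and
behaves like a standard mixed-model Wald test otherwise. Missing dosages are
mean-imputed so every SNP is tested on the full cohort. Each result set
records which chromosomes built each GRM.

Genetic correlation defaults to Haseman–Elston cross-product regression:
with residualized, standardized traits, E[y1_i·y2_j] = A_ij·σ_g12 for
i ≠ j, and analogously per trait; rG = σ_g12/√(σ_g1²·σ_g2²), clipped to
[−1, 1] with a flag, SE by delete-block jackknife (20 blocks). Bivariate
AI-REML is not implemented; HE is closed-form, stable at n of a few hundred,
and recovers a simulated rG = 0.6 to ±0.15 in the mean over 20 replicate
cohorts. Genomic inflation is λ = median(χ²)/χ²₁(0.5); per-SNP effect-size
correlation matches SNPs on (chrom, pos), flips the second study's beta when
its alleles are swapped, and drops strand-ambiguous A/T and C/G SNPs.

Calibration is demonstrated on a cohort of 200 (50 sib pairs) with a
polygenic trait whose causal SNPs occupy alternating LD blocks: on the
causal-free blocks MLMA-LOCO's λ lies in [0.9, 1.1] and its type-I error at
α = 0.05 within two binomial SEs, while naive OLS on the same data inflates.
λ is averaged over five trait replicates because a single 2000-SNP λ has a
sampling sd near 0.07; the type-I count uses one SNP per null block so the
binomial reference applies despite within-block LD.

## Variant mapping

Lead SNPs are those with p strictly below the lenient threshold, sorted
ascending. LD expansion takes, per lead, all same-chromosome panel SNPs with
squared Pearson dosage correlation ≥ 0.6 (inclusive; the lead tags itself at
r² = 1); genotype-based r² stands in for haplotype-based r² on a reference
panel. Positional mapping locates each SNP inside feature sub-intervals via
interval trees and keeps the exonic/intronic/ncRNA/UTR categories; 2 kb
up/downstream flanks are assigned but excluded by the default filter. eQTL
mapping accepts any tissue with q < 0.05. A gene reached both ways appears
once with two provenance rows; every row carries the lead SNP and r² that
produced it, so each gene is traceable to a lead. Gene lists are ordered,
deduplicated, and monotone: loosening any threshold can only add genes.

## Pathway networks and grouping

The harvest step records every (gene, pathway, database) membership for a
candidate list — databases are never merged, so redundant sets under
different ids stay distinct rows — and reports genes absent from all
databases. Networks are typed undirected graphs (gene/pathway/SNP nodes;
membership/positional_map/eqtl_map/ld/shared_snp edges) with per-node
trait-of-origin sets; merging across traits is a set union and therefore
idempotent. The reduced view replaces SNP nodes by direct gene–gene
shared-SNP edges. Redundancy grouping scores pathway pairs by the overlap
coefficient |A∩B|/min(|A|,|B|) (Jaccard optional) on the *full* database
gene sets, links pairs at or above the threshold (default 0.8), and takes
connected components — single linkage, so chains merge; the representative
is the lexicographically smallest id. The overlap coefficient is chosen
because the grouping exists to collapse near-duplicate and contained sets
across databases, which Jaccard under-scores for nested pairs. No pathway
size filter is applied; hooks exist in the calling code.

## Overlap inference

Gene overlap between traits is a plain intersection count (symmetric);
pathway overlap is reported row-relatively, 100·|P_row ∩ P_col|/|P_row|, so
the matrix is intentionally asymmetric and rows with empty pathway sets are
flagged and set to 0. The permutation test maps a gene list to its induced
pathway set (every pathway, in any database, containing at least one listed
gene) and compares the observed Jaccard index of two traits' induced sets
against draws of uniform random gene subsets — without replacement,
independent between the two lists — of the same sizes from the
pathway-annotated gene universe (union over databases by default;
intersection mode available). The percentile counts null values ≤ observed;
ties count toward the percentile, a conservative choice in the direction of
high percentiles. Grouping is *not* applied before the Jaccard computation
(grouping is a visualization device); a post-grouping sensitivity mode can
be composed from the public API. The engine matches exhaustive enumeration
on small universes and its percentiles are uniform for random observed
lists. Every result carries the standing caveat in its metadata: observed
gene lists are association-derived, not random, so the null is a calibration
reference, not a literal sampling model of the study.

## The end-to-end scenario

`pathgwas.scenario.run_shared_pathway_scenario` is the package's capstone
construction: three traits whose causal genes are disjoint (each causal gene
spans one LD block, so proxies cannot cross gene boundaries) but assigned to
common pathways, with equal-magnitude causal effects so each designed gene
is detectable at n = 400. The pathway databases also contain
annotation-only gene ids ("GX…"): real pathway databases cover the genome
while a study's candidate list is tiny, and the permutation null is only
meaningful when the sampling universe is much larger than the observed
lists. The pipeline run on this construction reports zero cross-trait gene
overlap with pathway-level Jaccard at the top of its permutation null, and
is bit-identical under a fixed seed.

## Problem sizes

Default measurement sizes, chosen to make each quantity's sampling noise
small relative to the band it is judged against: calibration uses one
200×2000 panel with five trait replicates; parameter recovery uses 20
replicate 500×5000 cohorts with 100 sib pairs; the permutation engine is
checked with 40 000 draws against a 7-gene enumeration and 200 repetitions
of a 500-draw percentile; the scenario runs 400×600 with 5 000 permutations
per trait pair.

## Known limitations

- Gaussian traits only; no liability/binary model, no dominance or epistasis.
- HE genetic correlation only (no bivariate REML); SEs by jackknife, not
  analytic.
- The mixed-model per-SNP test uses a t reference with re-estimated scale
  rather than the score test some tools use; differences are negligible at
  n in the hundreds but the choice matters below that.
- Genotype-based r² on the analysis panel replaces external reference-panel
  haplotype r²; with small panels the expansion is noisy near the threshold.
- Cross-database gene identifiers are assumed to share one namespace;
  reconciliation is the caller's job.
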
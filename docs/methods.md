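# Methods

This note documents the models, numerical choices and limitations of the
`acidarch` pipeline in the package's own terms. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic panels

**Genotypes.** Accessions are fully inbred, so genotypes are
haploid-equivalent minor-allele dosages in {0, 1}. The genome is five
chromosomes of evenly spaced SNPs (default spacing 600 bp, 20,000 SNPs,
i.e. the density of a ~200k-SNP genome-wide panel at reduced scale).
Ancestry follows an admixture model: each accession's proportions over K
subpopulations (default K = 6) are Dirichlet with concentration 0.2
(mostly-assigned accessions with a minority of admixed ones).

Linkage disequilibrium is generated block-wise. Each LD block (default
10 kb, the usual decay scale quoted for *A. thaliana*) carries a shared
pool of four haplotypes whose alleles are Bernoulli draws from the
ancestral frequency (uniform on [0.05, 0.95] per SNP). Subpopulations
differ in their haplotype *weights*: ancestral Dirichlet(1.5) weights are
drifted per subpopulation by a Dirichlet analogue of the Balding–Nichols
model whose variance scales with the divergence parameter F (default
0.25). Every accession copies one pool haplotype per block according to a
block-level ancestry draw from its admixture proportions. Consequences:
strong within-block LD (few segregating haplotypes per block), free
recombination between blocks, genome-wide background LD only through
ancestry, and a marginal dosage distribution that is exactly the Bernoulli
admixture likelihood the structure fitter inverts. About a third of
nominal SNP positions come out monomorphic or rare and are removed by the
standard MAF filter, mirroring the attrition from raw to analysis-ready
call sets. Missing calls are inserted uniformly at rate 0.02.

What this generator does *not* emulate: coalescent genealogies,
recombination-rate variation, heterozygosity, selection, and
non-uniform missingness. Because CV folds share population structure,
ridge prediction on structured panels retains a kinship-level component
that inflates absolute r2 relative to published real-data values; the
architecture *contrast* between presets is unaffected, which is why tests
assert the contrast and recovery properties rather than absolute r2
levels.

**Phenotypes.** The latent (true line-mean) RRL is
`mean + sum_q beta_q x_q + polygenic`, scaled so the genetic variance is
exactly `heritability x` the phenotypic variance implied by the target
coefficient of variation. Replicate root lengths are log-normal around
condition means (lengths and RRL stay positive); the replicate noise
variance is calibrated against E[latent^2] (noise is multiplicative) so
that one-way ANOVA line-mean repeatability recovers the target
heritability — verified unbiased to within ~0.01 in the recovery tests.
Per-replicate RRLs pair the top-five roots of each condition in recorded
order: stress and control replicates are different seedlings, and
rank-pairing would understate the replicate variance through
order-statistic correlation.

**Architecture presets** (the study conditions; defaults chosen once):

- `oligogenic_rare` (aluminum-like): 12 QTL with geometric(0.90) variance
  fractions summing to the full h2 = 0.95, CV 40%, five replicates. The
  unexplained phenotypic share is left to measurement error and rare
  alleles rather than a diffuse polygenic background, matching the
  interpretation that the gap between marker-predicted and observed Al
  tolerance reflects association-invisible variants. Two rare
  loss-of-function carriers (two natural ALMT1-null accessions are known
  in the real panel) have their latent RRL multiplied by 0.39 — the ratio
  of the flagship observed/predicted pair 6.6/16.9 — and are drawn from
  below-median genetic backgrounds, as in that observed scenario where
  both the observed and the predicted RRL sit far below the population
  mean. The causal alleles are private and absent from the SNP panel.
- `polygenic` (proton-like): 300 equal-effect QTL summing to 0.80 of
  h2 = 0.91, CV 16.5%, one mild (x0.6) rare carrier.

Overriding `heritability` or `n_qtl` on a preset regenerates the fraction
vector with the same shape and QTL share, so "matched h2" comparisons
change only what they claim to change.

## Population structure

The admixture likelihood is the product over accessions x SNPs of
Bernoulli(sum_k q_ik p_jk). It is maximised by EM block relaxation
(closed-form responsibility updates for Q and P), with 5 restarts,
convergence at delta-loglik < 1e-4, and a hard cap of 2,000 iterations;
monotonicity of the log-likelihood is asserted every step. K = 1 is
handled in closed form. This is the same likelihood a Bayesian MCMC
structure program samples from; the EM point estimate is deterministic
given the seed and desk-scale. Replicate log-likelihoods for the Evanno
delta-K statistic come from the restarts. delta-K is undefined where
replicate scatter is zero; that K is flagged rather than reported as
infinite, and an exactly linear log-likelihood curve yields an explicit
"ambiguous" selection.

Structure SNPs: MAF >= 0.10 (inclusive), zero missing calls, biallelic,
near-uniform genome-wide spacing via nearest-eligible-to-target walking.
Kinship: `K = Z Z' / sum_j f_j (1 - f_j)` on column-centered dosages
(missing entries contribute zero after centering), symmetrised, with a
1e-8 ridge before eigendecomposition. A centered cross-product was chosen
over other relatedness estimators because the mixed model requires only a
PSD relatedness matrix.

## Association scans

The Q+K model drops one ancestry column (rows of Q sum to one) and
estimates variance components once under the null by REML profiled over
lambda = sigma2_e/sigma2_g in the kinship eigenbasis — a 41-point grid on
log lambda in [-10, 10] refined by bounded minimisation to 1e-6. Each SNP
then gets an exact GLS one-degree-of-freedom t-test with those components
fixed (P3D). Since every accession contributes a single replicate-averaged
phenotype, compression reduces to identity grouping and P3D is the entire
approximation. SNPs with complete calls are tested in a single vectorised
Frisch–Waugh–Lovell pass in the whitened basis; SNPs with missing calls
take a per-missing-pattern Cholesky path (casewise deletion). With
kinship = I and an intercept-only design the scan reproduces ordinary
simple-regression p-values to < 1e-8 relative, and the GLM (eGWAS) scan is
exactly that degenerate case. p-values are clipped below at the smallest
positive double rather than reported as zero. No multiple-testing
correction is applied in the scan: significance is defined downstream by
the genomic-prediction effective-set cutoff.

The ELP test (expression ~ allele) is an OLS slope t-test, algebraically
the pooled-variance two-sample t-test; it refuses SNPs below 10% MAF and
errors on an empty allele class.

## Genomic prediction

Missing genotypes are mode-imputed per SNP (inbred haploid coding makes
LD-aware phasing unnecessary at this scale; ties at frequency 0.5 impute
0, a documented deterministic choice). SNPs are ranked by GWAS p-value
with (chromosome, position) tie-breaks for bitwise-stable ordering. For
each k on the 20–300 grid, each CV replicate partitions accessions into 5
folds; the ridge penalty is selected per training split by an inner 5-fold
search over a 13-point log grid from 1e-3 to 1e3 (no leakage into the
held-out fold), using one SVD per inner training set to evaluate the whole
penalty path. Predictors enter on the dosage scale without per-SNP
standardisation: standardising would amplify low-MAF SNPs, which is
undesirable when rare chance-tags of outlier accessions are a known
hazard. r2 is the squared Pearson correlation between assembled
out-of-fold predictions and observations (bounded in [0, 1], matching the
published axis); RMSE is on the RRL% scale.

The SNP ranking is computed once on the full data — the two-stage
GWAS-then-GP design — so the curves carry the optimism inherent to the
reproduced method. One measurable consequence: SNPs in chance LD with a
rare-carrier's genotype can enter the effective set and partially absorb
that carrier's phenotype gap, occasionally pulling its |difference rate|
under the 0.5 flag when the selected k is large. The outlier-detection
tests therefore pool carriers over several replicate panels.

`select_k` operationalises "the highest r2 before the plateau" as the
smallest k whose mean r2 is within one replicate standard deviation of the
global maximum; a curve still rising at the end of the grid selects the
largest k and is flagged `no_plateau`. The difference rate is
log2(observed/predicted) with |rate| >= 0.5 flagging unusual accessions;
non-positive observed or predicted values make the rate undefined (NaN,
never flagged).

## Candidate genes

Pairwise LD is the squared dosage correlation over jointly called
accessions (for homozygous inbred lines this equals haplotype-frequency
r2). The LD interval spans partners with r2 strictly > 0.80 within
+/- 10 kb. Gene models are promoter (2 kb upstream of the outer 5'UTR end,
strand-aware, truncated at chromosome edges) + UTRs + ORF; coordinates are
1-based inclusive at all interfaces. A SNP's candidates are every gene
whose extended model overlaps the LD span expanded to at least +/- 10 kb
around the SNP — the union rule, since gene counts in the source analysis
reflect the flanking window while the grouping language references the LD
region — with the single closest gene (ties reported with a flag) when no
LD partner exists.

## Haplotype networks

Variants are called per alignment column; contiguous gap columns with an
identical gap pattern collapse to one binary presence/absence character,
so an indel or transposon insertion of any length is a single mutation.
Runs of 50 bp or more are labelled TE insertions. Columns with more than
two bases are dropped with a warning (the promoter data this models is
effectively biallelic). Variants with MAF < 0.10 are dropped; haplotypes
with frequency > 0.10 are "major". The network uses haplotypes observed
at least twice (the frequency > 1 criterion): median (consensus-of-three)
closure to a fixpoint, then minimum-spanning connections added tier-by-tier
over Hamming distances with ties kept (so incompatible characters form
reticulations), then unobserved median vectors of degree <= 2 are
contracted away. On compatible (tree-like) data the result equals the
minimum spanning tree; the canonical 00/01/10/11 incompatibility yields a
single four-cycle. Character weights are uniform. Sequences with missing
characters at retained variants would be excluded with a logged count.

## Phenotype statistics

RRL is the ratio of top-five means per condition (not a mean of
per-rank ratios), times 100. Broad-sense heritability is one-way
random-effects ANOVA line-mean repeatability,
`H2 = sigma2_a / (sigma2_a + sigma2_e / r_bar)`, with negative
between-line variance estimates truncated at zero and the ANOVA n0 used
for unbalanced designs. CV is over accession means (the replicate-level
alternative is not used; the choice is documented here). Subpopulation
tests permute membership (two-sided, add-one correction, seeded), outliers
use strict 1.5 x IQR fences within subpopulations, and a Tukey HSD across
subpopulations is provided as a routine post-hoc for report parity.

## Problem sizes

Default analysis and acceptance sizes — 200 accessions, 20,000 nominal
SNPs (~12,000 after filtering), 10–20 CV replicates, five pooled panels
for outlier statistics, 500–1,000 null simulations for calibration — are
the package's chosen desk-scale study conditions; the generator and every
stage accept larger values unchanged.
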
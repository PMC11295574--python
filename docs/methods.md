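# Methods

`celliability` links cell populations defined by single-nucleus RNA-seq
to common- and rare-variant genetic liability for a trait. It implements
five statistical components around a synthetic-data generator with
planted ground truth, so every stage can be validated end to end without
access to the controlled or large external datasets such analyses
normally require.

## Expression specificity

For gene *g* and cell type *c*, specificity is

s(g, c) = mean_c(g) / Σ_{c'} mean_{c'}(g),

the gene's mean (normalized) expression in the type divided by the sum
of its means over all types. Each retained gene's scores form a
probability vector over cell types; a housekeeping gene is near uniform,
a perfect marker has s = 1 in one type.

Before scoring we apply, in order:

- **Cluster-size filter** (`min_cells = 10`): clusters below ten cells
  cannot give representative mean-expression estimates. Ten is the
  smallest round threshold that excludes the archetypal tiny
  oligodendrocyte clusters of 7 and 3 cells while keeping everything
  else.
- **Gene filters**: non-autosomal genes (sex-linked donor bias), genes
  overlapping the extended MHC region chr6:25–35 Mb (hg19; a region of
  extreme LD that would dominate downstream SNP-based tests — any base
  overlap with the closed interval removes the gene), genes expressed in
  fewer than 10 cells, and "uninformative" genes.
- **Uninformative genes** are operationalized as: no significant
  expression variation across cell types by one-way ANOVA on normalized
  values at Benjamini–Hochberg-adjusted α = 0.05. The reference
  workflow's exact informativeness criterion is not published; this is a
  deliberate, documented approximation with the same intent (drop genes
  whose specificity would be noise). Rows that are constant up to float
  jitter are always dropped.
- **Normalization**: `log_cp10k` (ln(1 + 10⁴·count/cell total); default)
  or `pearson_residual` with fixed inverse-dispersion θ = 100, clipped
  at ±√n_cells. A full regularized negative-binomial fit is deliberately
  not re-implemented: both options are deterministic, dependency-light
  and preserve the mean-ratio structure that specificity consumes.
  log-CP10K specificity is invariant to rescaling any single cell's
  counts.

Gene sets per cell type are the top specificity decile (size
⌈0.1·n_retained⌉, ties broken by specificity then ascending gene id so
sets are deterministic) or a fixed top-N (2000 by default for the
robustness variant; requesting more genes than exist is an error unless
explicitly allowed). Biotype splits (all / protein-coding / noncoding)
subset before ranking.

## Gene-level GWAS association (SNP-wise mean model)

Gene windows extend the transcribed region 35 kb upstream and 10 kb
downstream (strand-aware; configurable). Each SNP p-value inside a
window (closed interval; SNPs may belong to several genes) is converted
to a 1-df chi-square q = Φ⁻¹(1 − p/2)²; the gene statistic is T =
mean(q). Under the null, m·T is distributed as Σ λ_j χ²₁ where λ_j are
the eigenvalues of the SNP correlation matrix R estimated from the
reference panel (monomorphic SNPs are dropped to identity rows;
eigenvalues below 1e-10 are truncated).

The tail probability is computed by Imhof-type inversion of the
characteristic function. Because the integrand oscillates, naive
adaptive quadrature on [0, ∞) silently loses several digits; we instead
bracket every zero of sin θ(u) analytically (θ is unimodal, so roots of
θ = kπ are found by safeguarded Newton from the previous root),
integrate each lobe with 24-point Gauss–Legendre, and sum the resulting
alternating series with repeated Euler averaging. Against an
independent Ruben-series implementation this agrees to ~1e-12; the
equal-eigenvalue case (including R = I) is evaluated in closed form as
a scaled chi-square. A two-moment Satterthwaite approximation is
available as a fast fallback and is flagged by the caller.

The gene z-score is the upper-tail probit of the gene p, so more
significant genes get larger z.

## Competitive gene-set enrichment

OLS of gene z on a set-membership indicator plus covariates (default:
log window length and log SNP count, absorbing gene-size confounding),
intercept included. The enrichment p is the one-tailed upper t tail of
the membership coefficient ("set mean greater"). Between-gene LD
correlation is not modeled in the default regression — the exact
generalized-least-squares treatment used by the reference tool is not
fully published — so the test is slightly anti-conservative when set
genes are clustered in the genome; the synthetic null keeps gene windows
well separated and the measured type-I error is nominal.

GO over-representation uses the one-sided hypergeometric tail against a
caller-supplied background with BH adjustment across terms. The
decile × GO-term intersection analysis ranks terms by over-representation
of the decile, takes the top k (20 by default, Bonferroni threshold
0.05/k = 0.0025), and runs competitive enrichment on each intersection;
intersections below two genes are flagged untestable rather than tested.

## Stratified LD-score regression

Per-SNP, per-annotation LD scores: ℓ(j, c) = Σ_k a_kc · r̃²_jk over SNPs
k within 1 cM of j, with the bias-corrected estimator r̃² = r² −
(1 − r²)/(n − 2). The banded matrix of r̃² values is built once per panel
(chunked matrix products over the cM window) and reused for every
annotation. Gene-set annotations mark SNPs within 100 kb of any set gene
(strand-ignored). The synthetic genetic map is 1 cM/Mb.

The regression fits chi-square on N·ℓ per annotation plus an intercept.
Weights follow the two-pass convention: an unweighted base-only pass
estimates τ̂_base, then weights 1/(ℓ_base · 2(1 + N·τ̂_base·ℓ_base)²)
correct heteroskedasticity and over-counting in high-LD regions (the
exact weighting differs across published versions; this one is stated,
not asserted as identical). Standard errors come from a delete-one
block jackknife over contiguous SNP blocks (200 by convention;
configurable, reduced automatically on small simulations); the
per-annotation p is the one-tailed normal tail of τ̂/SE. Duplicated
(rank-deficient) annotation designs are rejected, not silently fit.
A noiseless construction (chi-square exactly linear in the LD scores)
is recovered exactly, which pins the linear algebra.

The 53-annotation baseline model is an input in real use; synthetic runs
use a generated stand-in (base column plus a few random binary
annotations) that preserves the joint-fit structure without bundling
reference data.

## Per-cell trait association and trajectory regression

Each cell's score is the t-statistic of its own expression in the
regression

gene_z ~ intercept + cell_expression + dataset_average_expression,

across all genes surviving the trajectory filter (expressed in ≥ 10
cells, then log-CP10K). The gene-level statistic regressed is the gene
z-score rather than p or −log10 p (configurable): z is the scale on
which the linear-model residual assumptions are least strained. Cells
with constant or collinear expression get score 0 with a flag.

The trajectory test regresses z-scored cell score on z-scored
pseudotime, so the coefficient is the standardized beta (equal to the
Pearson correlation, |β| ≤ 1) with a two-sided t-test. Pseudotime is an
input column in real use (produced by a trajectory tool); the built-in
`simple_pseudotime` (first principal component, oriented by root cells,
min-max scaled to [0, 1]) exists so synthetic runs are self-contained,
and recovers the planted ordering with Spearman ρ > 0.9 on generated
trajectories. Leave-one-donor-out re-runs the test excluding each
donor's cells to show independence from donor effects.

## Fine-mapped-gene rank tests

Per cell type, a one-sided Wilcoxon rank-sum test asks whether
fine-mapped genes rank higher in specificity than the other genes
expressed in that type, after removing genes with specificity exactly 0.
The exact null distribution is used when min(n₁, n₂) ≤ 8 and the data
are tie-free (validated against full enumeration); otherwise the normal
approximation with tie and continuity corrections. Bonferroni threshold
0.05/n_celltypes (5.95 × 10⁻⁴ at 84 types).

## Rare-PTV burden

QC order is enforced by stage flags: genotype QC → variant QC → PTV
definition → burden test.

- Sample QC: one member removed per pair with kinship > 0.177 (greedy by
  pair degree, so an A–B, B–C chain loses only B; ties broken by sample
  id — the published rule says only "one member", the tie-break is this
  package's choice), ancestry-flagged samples, mean depth < 20×.
- Genotype QC (failures → missing): DP ≥ 10, GQ ≥ 30, hom-ref allele
  balance ≤ 0.1, hom-alt ≥ 0.9, het in [0.25, 0.75]. Boundaries are
  inclusive as printed.
- Variant QC: VQSR fail, call rate < 0.9 (computed on post-genotype-QC
  missingness), Hardy–Weinberg exact p < 1 × 10⁻⁸, low-complexity flag.
  Exclusions are strict inequalities, so boundary values survive.
- Hardy–Weinberg: the standard exact test conditional on allele counts,
  summing probabilities of all same-parity heterozygote counts no more
  probable than observed, computed by the numerically stable recurrence
  (matches a direct log-factorial enumeration to ~1e-13 for all tables
  up to n = 50).
- Qualifying variants: stop-gain / frameshift / splice-donor /
  splice-acceptor consequences, exactly one heterozygous carrier and no
  hom-alt among retained samples, absent from the external reference
  (consequence and external-presence are input annotations).

The burden test is Firth penalized-likelihood logistic regression of
case status on the per-sample qualifying-PTV count in the tested gene
set, with the first 10 principal components, exome-wide synonymous
count, platform and sex as covariates, and optionally the count over
all expressed genes (so set tests are relative to the tissue-wide
background). The Firth penalty (½ log det Fisher information) keeps
estimates finite under separation; fitting uses modified-score Newton
steps with step halving, convergence when every score component is
below 1e-6, at most 100 iterations. On a saturated 2×2 design the
estimate equals the classic 0.5-cell-correction log odds ratio, which
is the test oracle. The one-tailed p (excess burden in cases) is the
upper Wald tail; a penalized-likelihood-ratio variant is not currently
implemented — Wald was chosen because the published analysis does not
specify and Wald composes with the covariate-adjusted design.

## Synthetic data

The generator emulates the shapes, not the scale, of the real inputs:

- **Counts**: negative binomial with log-normal gene means
  (var = μ + αμ², α = 0.5 default); each of k cell types gets a disjoint
  marker set (5% of genes by default) with means multiplied by
  `marker_fold` (8 by default); donors round-robin; two tiny clusters
  (7 and 3 cells) are always appended to exercise the cluster filter.
  The first type's markers double as the GWAS-enriched set, so the
  end-to-end scan has a planted answer.
- **Panel and summary statistics**: haplotypes follow a per-block Markov
  copy chain (copy probability ρ), giving exact AR(1) allele and dosage
  correlation ρ^d with closed-form block correlation matrices — which is
  what lets the quadratic-form null be validated analytically. GWAS
  z-scores are multivariate normal with that block correlation; SNPs
  inside enriched-set gene bodies receive a mean of ±√effect, inflating
  their expected chi-square by exactly `planted_set_effect`.
- **Trajectory**: cells ordered by a uniform pseudotime in [0, 1]; genes
  with high association z have log-mean expression rising linearly with
  pseudotime at a configurable slope (slope 0 is an exact null).
- **Rare variants**: singleton PTVs planted in a random 10% of
  protein-coding genes; case status assigned by a logistic model on the
  per-sample carrier count with odds ratio `planted_burden_or`, so the
  Firth estimand is well defined. One violator of every QC rule is
  planted deliberately.

All draws flow from `numpy.random.Generator` instances derived from the
config seed (seed sequences keyed per stage); there is no global random
state, and fixed seeds reproduce every artifact bit for bit.

What the generator does **not** emulate: empirical library-size
variation across cells and donors, batch effects, doublets, realistic
MAF spectra and LD beyond AR(1) blocks, population stratification
correlated with phenotype, and indel/annotation error. Passing tests
therefore demonstrate correctness of the statistics under their stated
models and calibrated error control under exchangeable nulls — not
robustness to every artifact of real data.

## Default problem sizes

Simulation-backed checks run at deliberately modest sizes chosen to make
the Monte-Carlo error bounds tight enough to be informative: 300–600
genes, 2,000–20,000 SNPs in 20–200 LD blocks, 200–500 panel
individuals, 6–10 cell types of 60–200 cells, and 2,000 per arm for
burden recovery. Null calibration uses 200–500 replicates with 99%
binomial acceptance bands; power checks use 10–50 seeds with stated
planted effects (chi-square inflation 3 per SNP for the scan, z-shift
+1 for enrichment, τ_set = 8 × 10⁻⁶ at N = 50,000 for the heritability
regression, odds ratio 2 for burden).

## Known limitations

- Competitive enrichment ignores between-gene LD correlation (optional
  whitening is left to the caller via the panel-based correlation).
- The SLDSR weighting and the MAGMA-style tail are stated conventions,
  not byte-level reproductions of the reference tools.
- `simple_pseudotime` is a one-component ordering, not a trajectory
  graph; branching topologies are out of scope.
- The uninformative-gene screen and the scTransform approximation are
  documented operationalizations where the upstream methods are not
  fully specified.
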
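# Methods

`latentfm` implements a latent-factor view of multi-trait GWAS: many
correlated quantitative traits are modeled as linear combinations of a small
number of uncorrelated latent factors, GWAS summary statistics are derived
for those factors (from individual-level data or from observed-trait summary
statistics alone), and association signals are fine-mapped jointly across
factors with a sharing-upweighted Bayesian posterior.

## Factor model

For P traits measured on N individuals, the model is

    Y = M + L F + eps

with Y the P x N trait matrix, M the trait means, L the P x K loading matrix
(K < P), F the K x N factor scores, and eps independent errors with
variances Psi (the uniquenesses).  Three estimation stages:

1. **Number of factors** — Horn's parallel analysis: the ordered eigenvalues
   of the observed trait correlation matrix are compared with the mean of
   the corresponding eigenvalues from `n_sims` simulated P x n_obs
   standard-normal datasets; K is the length of the leading run of observed
   eigenvalues exceeding their simulated counterpart.  Horn's original mean
   rule is the default (a 95th-percentile rule is exposed via `rule="q95"`),
   with `n_sims = 20`; both are parameters because different conventions
   exist and no single one is canonical.
2. **Loadings** — maximum likelihood on the correlation matrix, minimizing
   `log|Sigma| + tr(S Sigma^-1) - log|S| - P` with `Sigma = L L' + Psi`.
   The objective is profiled over L (for fixed Psi the optimal loadings come
   from the top-K eigenpairs of `Psi^-1/2 S Psi^-1/2`), leaving a smooth
   function of Psi minimized by L-BFGS-B on log-uniquenesses.  Numerical
   choices: uniqueness floor 0.005 (contains Heywood cases), starting values
   `Psi_0 = 1/diag(S^-1)` (one minus the squared multiple correlation),
   convergence tolerance 1e-8 on the discrepancy, at most 1000 iterations.
   Failure to converge raises with the final gradient norm.
3. **Rotation** — varimax, keeping factors orthogonal (hence factor scores
   uncorrelated) while maximizing loading-variance simple structure.  The
   implementation uses the standard simultaneous SVD iteration (as in R's
   `varimax`) rather than pairwise Kaiser sweeps: both maximize the same
   criterion; the SVD form is simpler and equally exact.  Kaiser
   row-normalization is on by default; tolerance 1e-10; deterministic output
   conventions (each column's largest-magnitude loading is positive, columns
   ordered by decreasing sum of squared loadings) so results are reproducible
   across runs.

Factor scores use the least-squares estimator
`F = (L'L)^-1 L' (Y - Ybar)`, which requires complete trait data.  With
missingness, the trait correlation matrix is estimated from pairwise-complete
observations and `n_obs` defaults to the median pairwise-complete count; the
summary-statistics path below then replaces score-level GWAS entirely.
Scaled loadings `C_ij = L_ij^2 / sum_k L_ik^2` quantify the contribution of
factor j to trait i; rows sum to one except for all-zero loading rows, which
are flagged.

## Latent-factor GWAS from summary statistics

Per variant, stacking the per-trait marginal regression coefficients into a
vector beta, the factor-score GWAS coefficients are exactly

    beta* = (L'L)^-1 L' beta,

because the scores are a fixed linear map of the traits.  This identity is
the module's headline contract: on a complete cohort the betas from this
transform equal OLS on the estimated factor scores to machine precision
(verified to < 1e-10 in the tests).  The covariance is approximated by

    Var(beta*) = (L'L)^-1 L' V L (L'L)^-1,
    V_ij = Cov(Y_i, Y_j) * se_i * se_j,

using the marginal trait covariance in place of the residual covariance — a
deliberate, documented approximation that makes the computation possible
from summary statistics; its accuracy is quantified in the tests (SEs within
2% of the individual-level ones at small per-variant variance explained) and
its null calibration is checked directly (Z^2 mean within 1 +/- 0.05,
type-I error within [0.045, 0.055] at alpha = 0.05 over 20,000 null tests).
Since V_ii reduces to se_i^2 only for unit-variance traits, the transform
expects standardized traits (e.g. rank inverse-normal transformed) and warns
otherwise.  Association uses `Z_k = beta*_k / sqrt([Var(beta*)]_kk)` with
normal p-values (the large-n GWAS convention); the printed form of the Z
statistic is implemented with the square root, the only dimensionally
correct reading.  Per-variant covariance matrices that fail positive
semi-definiteness (possible with inconsistent inputs) have negative
eigenvalues clipped to zero, with a counter reported.

Harmonisation aligns every trait's table to the first table's effect
alleles (swapped alleles negate beta and flip EAF; other mismatches are
dropped and logged), keeps only variants present in every table, and applies
`min(EAF, 1-EAF) > 0.005` and `INFO > 0.4` in every table.  Strand-ambiguous
(A/T, C/G) variants are kept by default — appropriate within a single cohort
— with a flag to drop them for cross-study use.

## Single-trait fine-mapping

Models are variant subsets scored from z-scores and LD with a conjugate
multivariate-normal Bayes factor (see `finemap.py`'s module docstring for
the closed form).  The per-SNP prior effect variance is `W = 0.04^2` on
standardized effects (the common fine-mapping convention), applied on the z
scale as `Phi = diag(W / se_j^2)`; single-SNP models reduce exactly to
Wakefield's approximate Bayes factor, which the tests verify against direct
numerical integration.  The model-space prior is independent Bernoulli with
`snp_prior = 1/p` by default (one causal variant expected per region).

All models of size 0..cmax are enumerated exhaustively (guard: 5e6 models);
sizes 1 and 2 use vectorized closed forms and larger sizes batched linear
algebra.  The dynamic rule starts at cmax = 1 and grows while the posterior
mass on models of the current maximum size exceeds 0.05 (hard cap 10, or
when the next size would exceed the enumeration guard); this growth
threshold is this package's operationalization of data-driven model-size
selection and is exposed as a parameter.  Near-singular LD submatrices
receive a 1e-6 ridge.

CS99 construction: variants ranked by decreasing MPP (ties by ascending
position) and accumulated until the cumulative MPP reaches the level; if the
total MPP is below the level (weak signals) all variants are returned and
flagged.  Variant groups use single-linkage clustering of MPP > 0.01
variants over r^2 > 0.8 edges, labeled by decreasing maximum member MPP,
with "0" for unassigned variants.

LD from imputed dosages uses best-guess genotypes: a dosage maps to the hard
call in {0,1,2} when within 0.2 of it and is otherwise missing; variants
with under 80% non-missing calls are excluded; correlations are
pairwise-complete Pearson.

## Joint fine-mapping of uncorrelated factors

For uncorrelated traits the joint Bayes factor factorizes into the marginal
ones, so only the model-space prior couples traits.  The joint prior for
models of two traits is `p_i p_j kappa^{1{overlap}} tau(|i|,|j|)`:
kappa >= 1 upweights configurations sharing at least one causal variant
(overlap is a yes/no indicator, not proportional to overlap size), and tau
keeps the prior over model-size pairs invariant to kappa.  The combinatorial
form used here is derived from that invariance requirement: with
`q(s1,s2) = 1 - C(p-s1,s2)/C(p,s2)` the probability that two uniformly
chosen models of those sizes overlap, `tau = 1/(1 - q + kappa q)` satisfies
the identity exactly under uniform-within-size priors, which the tests
verify by exhaustive summation for all p <= 8, sizes <= 3,
kappa in {1,2,5,10}.  Null models never share.

The trait-adjusted posterior for model i of trait t is

    PP_i^(t) * prod_{u != t} sum_j PP_j^(u) kappa^{overlap(i,j)} tau(|i|,|j|),

renormalized within the trait.  For M > 2 traits the pairwise sharing
factors between the focal model and each partner factorize across partners
— valid because the partners' posteriors enter independently when traits
are uncorrelated; this product-form generalization is an assumption of this
implementation (the two-trait form is exact) and is pinned down by
brute-force joint-enumeration oracles for M = 2 and M = 3 in the tests.
Default kappa = 4; the parameter has no canonical published value, so a
sensitivity sweep (kappa in {1,2,4,8,16}; adjusted PP of a shared top model
is non-decreasing in kappa) is part of the test suite and kappa is exposed
everywhere.  Overlap sums are computed with a dense model-by-variant
membership matrix and BLAS matrix products, exact and O(M m^2 p / flop).
For very large model spaces the wrapper prunes each factor to its top 4,000
models by PP before adjustment (renormalizing), a documented approximation
that is disabled in every oracle-agreement test.

Two consequences of tau worth knowing: (i) with kappa = 1 the adjustment is
exactly the identity; (ii) with disjoint causal support the adjustment
vanishes only as the region variant universe p grows (tau -> 1); at p in
the thousands — realistic regions — posterior changes are below 1e-3, while
tiny toy universes (p < 10) show visible size-rebalancing.  This is a
property of the prior, not an artifact.

## Signal bookkeeping

Greedy min-p LD clumping (PLINK-style, single absorption round, r^2 > 0.6),
distance clumping of leads (smaller p wins a 250 kb window), regions as
+/-250 kb flanks merged on overlap (1-based inclusive coordinates; 0-based
half-open only in BED export).  Conditional summary statistics use the
z-scale identity `z_cond = (z_t - R_tC R_CC^-1 z_C) / sqrt(1 - R_tC R_CC^-1
R_Ct)` with betas and SEs rescaled so the conditional beta approximates the
joint-regression coefficient; this is validated against individual-level
multiple regression at n = 20,000 (within 2%).  The trait-per-clump
cross-tabulation marks a clump as shared when any member variant is
genome-wide significant for a latent factor, and tests the trend of the
shared proportion over trait counts with a closed-form Cochran-Armitage
chi-square (equally spaced scores), cross-checked in the tests against the
N*r^2 identity.  Threshold constants: GWS p < 5e-8, suggestive band up to
1e-6, factor-trait linkage at 1% contribution for GWAS lookups and 20% for
fine-mapping, MPP > 0.90 for high-confidence variants.

## Synthetic cohort

Genotypes: two latent standard-normal haplotype processes per individual
with AR(1) correlation `rho` across variants, each thresholded at the
allele-frequency quantile and summed — Hardy-Weinberg by construction
(independent haplotypes, no inbreeding parameter), tunable LD without an
external reference panel, and adjacent-variant dosage correlation matching a
Monte-Carlo oracle of the same scheme to 0.02.  Traits follow
`Y = F L' + noise` with genotype-driven factor scores (planted causal
variants with additive effects).  INFO is 1.0 for simulated variants; a
uniform dosage-jitter option recomputes INFO as
`var(dosage)/(2 maf (1-maf))` so INFO filters can be exercised, and a
per-trait Bernoulli missingness injector exercises pairwise-complete paths.

What the generator does *not* emulate: coalescent LD structure, allele
frequency spectra, population structure or relatedness, imputation error
correlated with LD, phenotype measurement artifacts.  Passing tests
therefore demonstrate correctness of the algebra and calibration under the
stated model, not robustness to those real-data features.

## Study problem sizes

The simulation studies use: equivalence check at n = 2,000 individuals,
P = 12 traits, K = 3 factors, 300 variants; resolution gain over 100 regions
of p = 50 variants (AR(1) r = 0.9, n = 10,000, one causal variant with
standardized effect 0.09 shared by 3 factors, kappa = 4); CS99 coverage over
200 single-causal replicates of the same region design (10 genotype panels
reused with fresh phenotype noise — the usual fixed-LD fine-mapping
simulation design); null calibration over 20,000 variant-factor tests
(n = 1,000, P = 6, K = 2); factor-count recovery over 50 replicates
(P = 12, K = 3, n_obs = 5,000, communalities 0.6).  These sizes make the
identities exact where they should be exact and give binomial standard
errors of about 0.15-1.5% on the coverage and calibration rates.

## Known limitations

- GWAS uses per-variant least squares; mixed-model association (population
  structure, relatedness) is out of scope, adequate for the unstructured
  synthetic cohorts studied here.
- Var(beta*) uses the marginal trait covariance (see above); SEs are
  approximate at strongly associated variants.
- Exhaustive enumeration limits regions to roughly p <= 40 at cmax > 3;
  larger regions should be pre-thinned (stochastic search is not
  implemented).
- The M > 2 joint adjustment is the product-form generalization described
  above; equivalence to any external implementation is not claimed beyond
  the printed two-trait formula and its consistency property.
- Binary traits, functional-annotation priors, and multi-ancestry analyses
  are not supported.
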
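# Methods

This note documents the models, estimators and design choices behind
`eigenmap`, in the order the pipeline runs them.

## Synthetic cohorts

The generator (`eigenmap.synthetic`) produces cohorts with the statistical
structure the analysis assumes, plus a ground-truth record for recovery
scoring. Defaults describe the study conditions every benchmark runs under;
they are not tuning knobs.

**Genotypes.** Balding–Nichols model: ancestral allele frequency
p ~ U(0.1, 0.5) per variant; each of two populations draws its frequency
from Beta(p(1−F)/F, (1−p)(1−F)/F) with F = F_st = 0.1 (F = 0 degenerates to
the ancestral frequency); genotypes are Binomial(2, ·). Variants (default
500; 5,000 in calibration runs) are laid out on four chromosomes at 10 kb
spacing and are independent — no linkage disequilibrium is simulated, so
positional 1 Mb clumping, not LD clumping, is the locus definition
throughout. The true kinship returned alongside is the centered GRM of the
generated dosages.

**Expression.** Each coarse module (4 by default) holds two planted
submodules of 60 genes driven by latent factors, plus 10% weakly loading
noise genes. For submodule *s* the factor is built as

    base_s = √v · z_s + √(1−v) · e_s        (z_s: standardized QTL dosage)
    f_s    = standardize(base_s + sd(base_s) · shift_s)

where `e_s` is unit Gaussian noise orthonormalized against `z_s`, so the QTL
share of the within-cluster factor variance equals v =
`qtl_variance_explained` (default 0.15) exactly in each realization. Member
gene *i* is `x_i = λ_i f_s + √(1−λ_i²) ε`, λ ~ U(0.5, 0.9); noise genes use
λ ≤ 0.2. Sex, age-at-death and batch effects are added additively to every
gene with small per-gene coefficients (SDs 0.2 / 0.01 per year / 0.2), so
residualization is necessary but exactly verifiable. Expression is emitted
directly on a log2-normalized scale; no count model is simulated, because
the pipeline consumes harmonized normalized data.

**Case subtypes.** Roughly one third of samples are cases; 20% are an
MCI-like OTHER group counted among controls by default. Case subtype shifts
live in the span of the first two submodule factors: for K = 2 the diametric
pattern ±(r/√2)(1, −1) and for K ≥ 3 equally spaced points on a circle, with
the radius set so the minimum pairwise centroid distance equals
`subtype_shift` (default 2.0) in within-cluster factor SD units. Because the
shift is applied after scaling by the SD of the QTL+residual component, the
realized separation / within-SD ratio equals `subtype_shift` exactly.

**What the generator does not emulate:** family structure (population
structure alone supplies the confounding the mixed model must absorb),
LD, count-level noise, cohort-specific normalization artifacts, and
correlated covariates. Passing benchmarks therefore demonstrate correctness
of the estimators under the factor model, not robustness to every
real-data pathology.

## Preprocessing

Covariates are removed by per-gene OLS on an intercept + centered
quantitative + indicator-contrast design; the residuals are exactly
orthogonal to every design column, which the tests verify to ~1e-8.
Residualization runs on all samples jointly (cases and controls), before any
case-only step. Standardization is per gene to mean 0, variance 1 (n−1
denominator); all network math consumes standardized residuals, and
correlations are invariant to per-gene affine transforms.

## Submodule refinement

Unsigned soft-threshold adjacency |cor|^β with β = 6; a signed variant
((1+cor)/2)^β is available by config. TOM as defined in the README; a
brute-force triple-loop oracle pins the implementation in the tests. Gene
sets are detected by average-linkage clustering on 1−TOM with a static cut
at 0.99 × the maximum merge height — deterministic and parameter-light,
chosen over the dynamic hybrid tree cut. Because that cut always severs the
top merge, a module consisting of one homogeneous set would dissolve; when
no cluster survives the size floor the whole gene set is offered as a single
candidate and the kME pruning judges it. Each candidate is pruned to
|kME| ≥ 0.6 with the eigengene recomputed after every pass; detection and
pruning iterate (≤ 20 rounds) until the partition repeats, then residual
genes join the submodule maximizing |kME| where that value clears the
threshold, followed by a final pruning pass so the member invariant holds.
Non-convergence returns the current state with a warning flag rather than
raising. The minimum submodule size is 100 at cohort scale; the synthetic
benchmarks run with a floor of 20 because planted submodules hold 60 genes.
Eigengenes are computed over all samples (cases + controls), unit variance,
sign-aligned with the mean member profile.

## Subtyping

Nine validity indices stand in for NbClust's thirty, each implemented and
unit-tested rather than wrapped: Calinski–Harabasz (max), silhouette (max),
Davies–Bouldin (min), Dunn (max), C-index (min), gap statistic (Tibshirani
one-SE rule, B = 50 uniform-box references), Hartigan (first k with
H(k) ≤ 10), Krzanowski–Lai (max) and Ball–Hall (largest successive drop of
W_k/k). Every (method, index) pair casts one vote over k ∈ [2, 6]; the modal
k wins, ties toward smaller k. Reference datasets for the gap statistic are
clustered with a single-restart k-means (for the k-means method) because
only the average log W over references is needed; observed-data k-means
always uses 50 restarts. Method selection maximizes mean silhouette width at
k*, with one guard: partitions containing a cluster smaller than 5% of cases
are set aside (waived if all methods fail), because average-linkage methods
can win the silhouette contest with a near-singleton outlier split, and a
one-decedent subtype supports neither mapping nor differential expression.
Specificity traits are raw Euclidean distances to the centroids, not
re-standardized. Covariate balance uses uncorrected chi-square tests for
categorical variables and Student's t (pairwise above k = 2) for
quantitative ones.

A feasibility caveat: with the default geometry (separation 2 within-cluster
SDs, 8 eigengene dimensions of which two carry signal), K = 2 is recovered
essentially always, but a three-cluster mixture at that separation is so
overlapped that model selection cannot distinguish it from fewer clusters —
a Gaussian-mixture BIC oracle prefers k = 1 on the same data even at
n = 1000. Three-subtype recovery requires wider separations than the default
conditions provide; the benchmark reports the honest rate.

## Mixed-model association

REML profiles δ = σ_e²/σ_g² through one eigendecomposition of S K S (S the
fixed-effect annihilator), on a log10 grid over [−5, 5] with 100 intervals
refined by bounded scalar minimization in the best bracket; grid-edge
solutions are flagged. The scan fixes the variance components at the null
fit, whitens y, X and every dosage by V̂^(−1/2), and applies per-variant OLS
with a two-sided t test on n − rank(X) − 1 degrees of freedom — exact-t
rather than normal, for small-n fidelity. Identity kinship reduces the scan
to plain OLS (verified to 1e-10), and the whitened scan matches explicit
GLS with a full V̂ inverse to better than 1e-8 relative on every fixture.
Fixed effects default to the intercept only, since traits are residualized
upstream; a covariate design can be passed explicitly. Default kinship is
IBS ((2 − |g_i − g_j|)/2 averaged over variants); a GRM is available by
flag. λ_GC is the median association χ² over the χ²₁ median
(0.4549364…, computed from the distribution, not hard-coded). Hit classes
use p < 1e-5 / 5e-8 with no multiple-testing correction across traits —
per-scan thresholds exactly as is conventional, documented as a caveat.
Missing genotype calls are mean-imputed per variant at read time so the
sample set stays constant across the scan.

Calibration benchmark: null traits carry a within-population polygenic
component drawn from the genotypes (population means removed) at h² = 0.4
plus a 0.5 SD population mean shift — confounded by structure but linked to
no single variant. Uncorrected OLS inflates to λ ≈ 2.8 under these
conditions; the mixed model holds λ within [0.9, 1.1].

## Differential expression

Two-group design on residualized expression (covariates removed upstream
rather than inside the DE fit; both orderings are standard, this one mirrors
the pipeline order, and the logFC is therefore a difference of residualized
log2 means). Per-gene pooled variances are shrunk by empirical Bayes: with
e_g = log s_g² − ψ(df/2) + log(df/2), the prior degrees of freedom d0 solve
ψ′(d0/2) = Var(e) − ψ′(df/2) by monotone inversion and s0² comes from the
mean of e with digamma offsets; when the observed spread does not exceed the
sampling floor, d0 = ∞ and s0² is the plain mean of the variances. The
moderated t uses the posterior variance (d0·s0² + df·s²)/(d0 + df) on
df + d0 degrees of freedom; d0 = 0 reproduces the ordinary pooled t exactly,
and the full fit matches an independent empirical-Bayes implementation in R
to 1e-4 relative in the tests. Calls require BH-adjusted p < 0.05 and
|logFC| > 0.5.

## Enrichment

Upper-tail hypergeometric over-representation only (no depletion), universe
= the expressed genes in the matrix, BH within each query list, odds ratios
with a Haldane 0.5 correction for zero cells. Cell-type annotation assigns
the marker set with minimal q when q < 0.05, else "unassigned".

## Numerical and reproducibility choices

All randomness flows from integer seeds through `numpy.random.default_rng`;
identical spec + seed gives byte-identical cohort files. Eigengene signs are
fixed by the mean-profile rule; submodules are labelled parent + size rank;
cluster and locus orderings are deterministic. Degenerate inputs (constant
genes, zero-variance eigengenes, constant whitened dosages, empty control
sets, rank-deficient designs) raise early with the offending names, except
where the contract calls for a flagged result (constant dosage → p = 1,
β = 0). Benchmark problem sizes — 300 samples, 500–5,000 variants, 20
replicates for recovery rates, 10 for calibration medians — were chosen as
the smallest sizes at which the estimated rates and medians are stable.

## Known limitations

Independent variants only; positional clumping is a stand-in for LD-aware
locus definition. The refinement loop is one declared reading of iterative
module pruning (static cut, exact-membership convergence); dynamic tree
cutting is a plausible refinement. Silhouette-based method selection remains
fragile at weak separation even with the small-cluster guard. The DE logFC
is on the residualized scale and not directly comparable to raw fold
changes. Specificity traits are distances, hence non-Gaussian near zero;
the mixed model treats them as ordinary quantitative traits, as is standard
practice.
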
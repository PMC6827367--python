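# Methods

## Model

Genotypes at a diallelic SNP are coded 0/1/2 copies of the counted allele
(the ALT allele for VCF input). The structural HWE model gives each SNP
*i* and individual *j* its own allele frequency π<sub>ij</sub> and assumes

    x_ij ~ Binomial(2, π_ij), independent over individuals.

Classical HWE is the special case π<sub>ij</sub> = p<sub>i</sub>. The m×n
matrix F = (π<sub>ij</sub>) satisfies E[X] = 2F, and population structure
is modeled by giving F low rank: K latent dimensions, with the SNP-wise
mean (intercept) always counted as the first, so K=1 is the unstructured
model and every estimator reduces to marginal allele frequencies there.

## Frequency-surface estimators

All estimators clip their output to [1/(2n), 1 − 1/(2n)] — the frequency
corresponding to a single allele copy — so downstream Binomial simulation
and class probabilities are never degenerate.

**marginal** (K=1 only): π̂<sub>ij</sub> = p̂<sub>i</sub>, the mean
non-missing dosage divided by 2.

**pca** (truncated PCA): mean-impute missing dosages per SNP, take the row
mean plus the top K−1 principal components of the row-centered matrix,
scale by 1/2, clip. Exact SVD is used when min(m, n) ≤ 500; above that, a
seeded randomized SVD (7 power iterations), so results are deterministic
either way. Reconstruction error is non-increasing in K. Note one
consequence of the intercept-first convention: with m < n, K = min(m, n)
leaves the reconstruction one rank short of interpolating X/2 exactly;
with m ≥ n (the usual genotyping regime) full rank is reached.

**lfa** (logistic factor analysis): factorizes logit(F) = AH with an
explicit intercept row in H. The fitting pipeline authored here: (1) form
the clipped rank-K dosage reconstruction as in truncated PCA and map it
through the logit; (2) extract the top K−1 right singular vectors of that
row-centered logit matrix as logistic factors and append the intercept
column, giving the n×K design H; (3) fit each SNP's loading row a_i by
binomial (size-2) logistic regression of its genotypes on H. The m
regressions are advanced together by vectorized Newton/IRLS steps (default
40 iterations, step tolerance 1e−8, ridge 1e−10 on the Hessian). Missing
calls carry zero weight. Monomorphic or separated SNPs cannot converge in
coefficients even though their fitted probabilities stabilize at the clip
bounds, so steps are clamped to ±4 and coefficients to ±30 and the linear
predictor is capped at ±15; an error (with the iteration count) is raised
only if non-finite values appear. K=1 returns the marginal surface
directly, which is the exact intercept-only maximum likelihood fit.

Custom estimators can be registered by name; every output is validated
against the surface invariants (shape, clip bounds, reported K) on each
call, including inside the null-replicate loop.

## Test statistic

For one SNP, with v = (N(0), N(1)) the counts of genotypes 0 and 1 among
non-missing calls and p_j(G) the per-individual class probabilities
((1−π_j)², 2π_j(1−π_j), π_j²), the statistic is
T = (v − μ)ᵀ Σ⁻¹ (v − μ) with μ and Σ the exact mean and covariance of v
under the model. T is asymptotically χ²₂ regardless of the π values
(pivotal), and algebraically equals the three-category Pearson χ²
statistic when all π_j coincide; the test suite verifies this identity to
1e−9 relative error against an independently coded Pearson oracle.

Numerics: the 2×2 system is solved in closed form; a SNP is flagged
*undefined* (NaN, excluded from pooling and output with a flag) rather
than raising when Σ's eigenvalue-ratio condition number exceeds 1e12 or
its determinant is non-positive — this arises for SNPs rendered
effectively monomorphic by clipping. Individuals with missing calls are
dropped from v, μ, and Σ jointly. No continuity correction is applied.
Tiny negative values from round-off are clamped to 0.

## Empirical null and p-values

Because F̂ is estimated from the data being tested, the χ²₂ reference is
not used directly. Instead (per run): fit F̂ at the chosen K; compute
observed T_i; for b = 1..B (default B=3) simulate a complete matrix
x⁰_ij ~ Binomial(2, π̂_ij), refit the same estimator at the same K and
settings on it, and compute null statistics; pool all defined null
statistics; then p_i = #{T⁰ ≥ T_i}/#defined nulls, computed by one sort
and binary search. Ties use ≥; an optional add-one smoothing mode
((count+1)/(total+1)) is available but off by default, so the smallest
possible p-value is 0. Undefined statistics are excluded from both sides
and counted in the log. Replicate b's random stream is derived from the
master seed by spawn key, so it does not depend on B.

A diagnostic `marginal_null_pvalues` computes the non-pooled version (each
SNP against only its own B_large ≥ 100 null statistics); on small
simulated data its p-values agree in distribution with the pooled ones,
which is the empirical justification for pooling.

## Choosing K: entropy of the p-value distribution

For each candidate K, bin the defined p-values into C equal bins on [0, 1]
(default C=150; edges [c/C, (c+1)/C), last bin closed), drop the first bin
— it holds the genuinely significant SNPs — renormalize the remaining C−1
proportions, and compute the Shannon entropy −Σ f_c log f_c (natural log,
0·log 0 = 0). Under-fitting skews p-values toward zero and over-fitting
toward one; both depress the entropy, which peaks at log(C−1) for a
uniform profile. A warning is emitted when fewer than 50 p-values per bin
are available, since C should shrink for small datasets. Note the dropped
first bin has width 1/C: if C is made too small, the dropped bin swallows
the under-fit excess of small p-values and the entropy can no longer see
under-fitting — which is why the default C is kept at 150 even for
moderate m.

The selected K is the smallest candidate on the entropy plateau. The
plateau is defined by default in noise units: a candidate belongs to the
plateau when its entropy is within z = 3 standard errors of the maximum,
where the standard error of the plug-in entropy deficit for N near-uniform
p-values over C−1 bins is sqrt(2(C−2))/(2N) (the fluctuation of its
χ²-type bias term). A fixed relative band — entropy ≥ (1 − tol)·max — is
available by passing a fraction; we found a fixed band mis-scaled, because
the entropy lives near log(C−1) ≈ 5, so even a 1% band (~0.05) dwarfs both
the sampling noise (~0.005 at m=2000) and genuine under-fit deficits
(~0.01–0.04), making the selector blind to under-fitting on moderate-size
data.

In a K sweep, every candidate reuses the same master seed, so null
replicates are paired across K. Pairing cancels the Monte-Carlo noise
shared between candidates in their entropy difference and sharpens plateau
detection at no cost; it is a pure variance-reduction device and does not
bias any single-K result.

## Multiple testing

π₀ (the proportion of SNPs in structural HWE) uses the bootstrap variant
of the Storey estimator: π̂₀(λ) = #{p > λ}/(m(1−λ)) over the grid λ =
0.05, 0.10, …, 0.95; 100 bootstrap resamples estimate MSE(λ) against the
minimum π̂₀ over the grid; the λ minimizing it is used and the result is
clamped to [0, 1]. At least 100 defined p-values are required. q-values
are the usual step-up construction q_i = min_{p_j ≥ p_i} π₀ m p_j /
rank(p_j), clamped to 1, with NaN p-values propagated.

## Synthetic data

The generator draws, per SNP, a base frequency ~ Uniform(0.1, 0.5), K
ancestral frequencies from the Balding–Nichols law Beta(p(1−F_ST)/F_ST,
(1−p)(1−F_ST)/F_ST) with default F_ST = 0.15, per-individual admixture
proportions q_j ~ Dirichlet(α·1) with default α = 0.1 (strongly
differentiated, near-discrete subpopulations, as in classical
admixture-simulation practice), sets π = P·Q, and draws genotypes
Binomial(2, π). Positions are laid out 1 kbp apart on one chromosome so
distance-based operations are exercisable. Since the admixture columns sum
to one, the row-centered F has rank K−1; with the intercept counted first,
a model dimensionality equal to the number of ancestral populations is
exactly sufficient.

Violations are injected into a Bernoulli(fraction) subset of SNPs, either
by redrawing the row from inbreeding-perturbed class probabilities
((1−π)² + fπ(1−π), 2π(1−π)(1−f), π² + fπ(1−π)) or by replacing each call
with a uniform random genotype with probability ε; all labels and
parameters are recorded.

What the generator does *not* emulate: linkage disequilibrium between
SNPs (sites are independent), relatedness/family structure, spatially
continuous structure, genotyping-batch artifacts, and allele-frequency
spectra estimated from real panels. Passing tests therefore demonstrate
calibration and power under an idealized admixture model, not performance
under LD-induced dependence of the pooled null or cryptic relatedness.

## Problem sizes and defaults

Defaults mirror standard practice for this analysis: B = 3 null
replicates, C = 150 bins, MAF ≥ 0.05, completeness ≥ 0.99, LFA as the
estimator. The bundled validation simulations use m = 200–5000 SNPs and
n = 200–1000 individuals — large enough for the asymptotics to hold
(empirical mean of T within 0.1 of 2 at m=5000, n=1000) while keeping a
full test run to a few minutes on one core. Genome-scale inputs (10⁵–10⁶
SNPs) run through the same code paths; the SVD switches to its seeded
randomized variant above min(m, n) = 500.

## Known limitations

- The pooled null assumes approximately independent SNPs; strong LD makes
  the effective null sample smaller than mB and the p-values slightly
  over-confident. Distance thinning mitigates this.
- With B=3 and no smoothing, the minimum p-value is 0 and q-value
  rankings in the extreme tail are resolution-limited at 1/(mB).
- The LFA loadings fit uses clamped Newton steps rather than a line
  search; for pathological designs the fit stops at the clamp rather than
  reporting failure, which is visible as frequencies pinned to the clip
  bounds.
- Sex chromosomes, multi-allelic markers, and imputed dosages are out of
  scope; VCF records that are not biallelic SNPs are skipped with a count.
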
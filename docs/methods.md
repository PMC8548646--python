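# Methods

## Model and test construction

For D/R pair i with outcome `Y_i`, covariates `W_i` (K columns), recipient
genotypes `X_i` (m SNPs, minor-allele counts) and gene-based matching score
`Z_i`, the model is `g(mu_i) = a0 + W_i a + X_i b + Z_i g` with logit link
for binary outcomes and identity link for continuous ones.  The joint null
is `b = 0, g = 0`.

**Binary outcome.**  The null model `logit Pr(Y=1|W) = a0 + W a` is fitted
by IRLS (tolerance 1e-8 on the coefficient sup-norm, at most 100
iterations); fitted probabilities `p_i` give weights `w_i = p_i(1-p_i)`.
Each column of `(X, Z)` is residualised on `(1, W)` by weighted least
squares with those weights.  The per-pair score contributions are
`Q[i,c] = B_res[i,c](Y_i - p_i)`; the score vector is `U = colsum(Q)` and
its empirical covariance `V = Q'Q`.  (Some presentations carry an explicit
factor n in both the covariance and the quadratic form; it cancels, and this
package omits it throughout.)

**Continuous outcome.**  The null fit is OLS with unit weights and residual
variance `RSS/(n-K-1)`; the construction of Q, U and V is identical with
`p_i` replaced by the fitted mean.  Using the empirical `Q'Q` for both
outcome types keeps the covariance estimator structure uniform.

**Eigen reduction.**  The recipient-SNP block `V_R` (m x m) is
eigen-decomposed; numerically negative eigenvalues are clipped at zero and
eigenvalues below `1e-10 * lambda_1` discarded.  s is the smallest count of
leading eigenvalues whose cumulative fraction of the retained total reaches
the `var_explained` threshold (65–99% in practice; ties resolve
automatically under "smallest s").

**Statistic.**  Each retained PC score is standardised by the square root of
its eigenvalue, `U_P^R[l] = a_l' U_R / sqrt(lambda_l)`, so its null variance
is 1 and the middle matrix has an identity upper block:

```
T = (U_P^R, U_S)' [[ I_s , c ],[ c' , V_S ]]^{-1} (U_P^R, U_S),
c_l = a_l' C_RS / sqrt(lambda_l)
```

Under the null T is asymptotically chi-square with s+1 df.  The square-root
scaling is what makes the identity block correct; a raw `1/lambda` scaling
(available as `scaling="lambda"` for diagnosis) leaves the PC scores with
variance `1/lambda_l` and is not a calibrated test.  With
`var_explained = 1` and well-conditioned V the statistic equals the full
Hotelling form `U'V^{-1}U` exactly (congruence invariance), which the test
suite verifies against a direct matrix inverse.

**Degenerate inputs.**  Monomorphic SNP columns are dropped (logged) before
testing.  If Z has zero residual variance the score component carries no
information and the test reduces to the recipient-only statistic with s df
(logged prominently).  A singular middle matrix — the score numerically
collinear with the retained PCs — raises with a diagnostic rather than
returning a value.

## Matching scores

Genotype g at a diallelic SNP is identified with the allele multiset
{g alt copies, 2-g ref copies}.  The four distances are: IBS `|x_D - x_R|`,
incompatibility `1{x_D != x_R}`, allogenomics mismatch (number of donor
allele copies whose type is absent from the recipient — directional, since
it models what the recipient's immune system would see as non-self), and the
binary mismatch `1{AMS > 0}`.  Unweighted gene scores are plain sums over
the gene's SNPs; the weighted form `sum w_j D_j / sum w_j` with `w_j =
1/MAF_j` up-weights rare variants.  Which allele counts as "minor" is
decided per SNP on the pooled donor+recipient frequency, so both members of
a pair share one coding (a flag selects recipient-only or donor-only bases).
Pairs missing a genotype at SNP j contribute the mean distance of the
complete pairs at j (keeps n constant per gene); a strict mode errors
instead.  Multi-allelic sites are excluded on read.

## Comparator tests

**Joint GLM.**  Null `(1, W)` and alternative `(1, W, X, Z)` models are
fitted by the same IRLS (or OLS); the LRT refers `2(l1 - l0)` — for linear
models `n log(RSS0/RSS1)` — to chi-square(m+1).  A Rao score variant uses
the model-based information of the added block.  At low prevalence the
alternative fit estimates m+K+2 parameters from few cases and the
chi-square approximation is anti-conservative; non-convergent fits raise and
are counted per simulation cell, never silently dropped.

**Quadratic form (SKAT-style).**  `Q = (Y-mu)'K(Y-mu)` with K built from the
combined `B = (X, Z)` matrix: linear `K = BB'` (optional min–max scaling of
the score column to [0,1]), or average IBS similarity
`sum_c (2-|B_ic-B_i'c|) / (2(m+1))` with the score column min–max scaled to
[0,2] so it enters on the genotype scale (how an appended non-genotype
column should enter an IBS kernel is not standardised; a flag excludes it
instead).  The null distribution is the chi-square(1) mixture with weights
the non-zero eigenvalues of `P^{1/2} K P^{1/2}`, P being the null-residual
covariance adjusted for covariate estimation.  For the linear kernel the
weights are computed as eigenvalues of the (m+1)x(m+1) matrix `B'PB`, so no
n x n work is needed.  Tail probabilities use Liu-type moment matching by
default — accurate in the tail (within ~0.01 of exact beyond the 0.25
quantile in our checks) but coarse in the distribution body, where it can
return exactly 1 — with Imhof's inversion integral as the exact option (a
single eigenvalue short-circuits to the scaled chi-square(1) closed form).

## Synthetic cohorts

The generator replaces reference-haplotype resampling with a latent-Gaussian
model: each haplotype thresholds a block-equicorrelated standard normal at
`Phi^{-1}(MAF_j)`; the genotype is the sum of two independent haplotypes.
This gives Hardy–Weinberg marginals, MAFs exact by construction, and
within-block LD governed by the latent `rho` (the implied genotype
correlation follows the tetrachoric formula, verified against a bivariate
normal orthant-probability oracle).  Donors and recipients are independent
draws — unrelated pairs.  What it does **not** emulate: the irregular LD
decay, allele-frequency spectra and haplotype structure of real genes, or
D/R relatedness.  Calibration results under this generator therefore
support the tests' null behaviour under blocked LD, not their behaviour on
any particular real gene.

Gene presets span small/medium/large regions — "nat2" m=15, "chi3l2" m=40,
"asah1" m=80 — with MAFs evenly spaced on [0.08, 0.45], contiguous 5-SNP
blocks and rho=0.8.  The SNP counts and LD layouts are package assumptions
(chosen as realistic for genes of those sizes), not measured values; results
that depend on m — the joint-GLM inflation magnitude, the conservativeness
of near-full PC retention — reproduce in direction and approximate size but
not digit-for-digit.

Phenotypes: `W1 ~ Bernoulli(0.5)`, `W2 ~ N(0,1)`, coefficients 0.5 each;
binary outcomes with prevalence 5–20% (the intercept is solved by root
finding so the realised prevalence matches the target *under the full
generating model*, including any genetic effects), continuous outcomes with
standard normal noise.  Alternatives add log-odds `b` on a fraction of SNPs
(chosen from one LD block for the high-LD scenario, one SNP per block for
low-LD) or `g` times a matching score summed over the associated subset
only, while the full-gene score is used at test time.  Effect sizes 0.14,
0.41 and 0.69 are used on the log-odds scale and labelled by the
conventional odds-ratio names 1.25/1.50/2.00.  Replicate r of a study cell
draws its generator from `SeedSequence(seed, r)`, so any cell and replicate
is independently reproducible.

## Problem sizes and numerical choices

The packaged study cells use n=500 pairs, the m=15 preset and 2,000 null
replicates per cell (Monte-Carlo SE ~0.005 at the 0.05 level), which keeps a
full calibration run in the minutes range on one CPU; power checks use 300
replicates per effect size, where the effect-size grid separates rejection
rates by far more than the MC noise.  IRLS uses tolerance 1e-8 / 100
iterations and treats fitted probabilities within 1e-10 of 0/1 as
separation.  Eigen cut-off for "numerically zero" is `1e-10 * lambda_1`.
The full-rank statistic is scale-equivariant, but with PC truncation the
retained basis depends on column scales (as in any PCA), so genotype columns
are used on their natural 0/1/2 scale and not standardised.

## Pipeline conventions

BED input is 0-based half-open on disk and converted to 1-based inclusive
internally; a SNP at the converted end position is inside the gene, and
overlapping genes share SNPs.  No flanking window is added by default
(`flank` available).  The score SNP set equals the test SNP set by default;
a second region file can widen the score set.  Covariates are used as
supplied (categorical variables must be pre-encoded).  BH FDR is applied
within each score type across genes (a flag pools all tests); with a single
gene the q-value equals the p-value.

## Limitations

No decomposition of a joint signal into recipient-genotype vs matching
contributions; no relatedness adjustment between donor and recipient; no
rare-variant moment corrections for the quadratic tests; the simulator's LD
is block-stylised.  Real-cohort behaviour, particularly for genes whose LD
differs strongly from the presets, should be checked with permutation on the
data at hand.
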
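# jst — joint score test for paired donor/recipient genetic data

Transplant outcomes such as acute rejection can depend both on the
recipient's own genotypes and on how well the donor's genome *matches* the
recipient's — including outside the classical HLA region.  `jst` implements
a gene-based **joint score test (JST)** for paired donor/recipient (D/R)
cohorts: for each gene region it jointly tests whether the recipient's SNPs
or a D/R genetic matching score are associated with the outcome, under the
generalized linear model

```
g(mu_i) = a0 + W_i a + X_i b + Z_i g ,      H0: b = 0 and g = 0
```

where `W_i` are covariates, `X_i` the recipient's minor-allele counts at the
gene's m SNPs, and `Z_i` a single gene-based matching score for pair i.

## What is in the package

- **Matching scores** (`jst.matching_scores`): four per-SNP D/R distance
  functions — identity-by-state `|x_D - x_R|`, incompatibility `1{x_D != x_R}`,
  the allogenomics mismatch count (donor allele copies novel to the
  recipient), and a binary mismatch indicator — summed over a gene, with an
  optional `1/MAF` weighting for rare variants.
- **The JST** (`jst.jst_core`): marginal likelihood scores for the m SNPs
  and the score are formed from the covariate-only null fit; the recipient
  block of their empirical covariance is eigen-decomposed and only the
  leading principal components retaining a preset fraction (65–99%) of
  variance are kept.  The statistic is asymptotically chi-square with s+1
  degrees of freedom — typically far fewer than the m+1 of Hotelling's T²,
  which it reproduces exactly when all components are retained.
- **Comparators** (`jst.comparators`): the joint GLM likelihood-ratio/score
  test, and SKAT-style quadratic-form tests with unweighted linear and IBS
  kernels calibrated by a chi-square-mixture null (Liu moment matching, or
  exact Imhof inversion).
- **Simulator** (`jst.simulator`): latent-Gaussian block-LD genotypes,
  D/R pairing, null and alternative phenotype models, and a replicated study
  runner for type-I error and power.
- **Pipeline + CLI** (`jst.pipeline`, `jst` command): VCF/TSV loading,
  harmonisation and MAF filtering, BED gene grouping, gene-by-gene testing
  and Benjamini–Hochberg FDR across genes.

## Worked example

Simulate 500 D/R pairs for a 15-SNP gene in which D/R mismatch (IBS score,
log-odds 0.41 per mismatched allele copy) drives a binary outcome with 10%
prevalence, then test:

```python
import numpy as np
from jst.simulator import gene_preset, make_cohort, SimStudyConfig, simulate_phenotype
from jst.matching_scores import gene_score
from jst.jst_core import PairedCohort, jst_test

rng = np.random.default_rng(7)
model = gene_preset("nat2")                       # small gene: m=15, block LD
X_R, X_D = make_cohort(model, 500, rng)           # unrelated recipient/donor pairs
cfg = SimStudyConfig(scenario="score_effect", effect_size=0.41,
                     prop_associated=1.0, score_type="ibs", prevalence=0.10)
W, Y = simulate_phenotype(X_R, X_D, cfg, rng)

score = gene_score(X_D, X_R, "ibs")               # per-pair mismatch burden
print("mean IBS matching score:", round(score.z.mean(), 2))

cohort = PairedCohort(Y=Y, W=W, X=X_R, Z=score.z, outcome_type="binary")
res = jst_test(cohort, var_explained=0.85)
print(f"s={res.s} df={res.df} statistic={res.statistic:.2f} p={res.p_value:.2e}")
```

Output:

```
mean IBS matching score: 8.69
s=6 df=7 statistic=32.16 p=3.80e-05
```

The average pair mismatches by ~8.7 allele copies across the gene's 15 SNPs;
85% of the recipient-SNP score variance is captured by s=6 principal
components, so the joint test spends 7 degrees of freedom instead of 16 and
detects the planted matching-score effect at p ≈ 4e-5.

The same analysis runs from the shell on real files:

```bash
jst run --geno-r recipients.vcf --geno-d donors.vcf --regions genes.bed \
        --covar covar.tsv --pheno pheno.tsv --score ibs --score ams \
        --var-explained 0.85 --out report.tsv
```

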
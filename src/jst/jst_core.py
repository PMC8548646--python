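"""The joint score test (JST) for paired donor/recipient genetic data.

The model is a GLM ``g(mu_i) = a0 + W_i a + X_i b + Z_i g`` for outcome Y of
D/R pair i, with covariates W, recipient genotypes X (m SNPs) and a single
gene-based matching score Z.  The joint null hypothesis is ``b = 0 and g = 0``:
neither the recipient's own genotypes nor the degree of donor/recipient
mismatch in the gene is associated with outcome.

Construction, for a binary outcome:

1. Fit the covariate-only null model ``logit Pr(Y=1|W) = a0 + W a`` and obtain
   fitted probabilities ``p_i`` and IRLS weights ``w_i = p_i (1 - p_i)``.
2. Residualise each column of (X, Z) on (1, W) by weighted least squares with
   those weights.
3. Per-pair score contributions ``Q[i,c] = B_res[i,c] (Y_i - p_i)`` give the
   score vector ``U = colsum(Q)`` (length m+1) and its empirical covariance
   ``V_hat = Q'Q``.
4. Eigen-decompose the recipient-SNP block ``V_R`` and keep the leading s
   principal components explaining a preset fraction of total variance.
5. The statistic is a quadratic form in the s standardised PC scores plus the
   matching-score component; under the null it is asymptotically chi-square
   with s+1 degrees of freedom.

The PC truncation is the point: Hotelling's T^2 (all m+1 components) loses
power when m is large, while the leading components carry most of the
genotype-score variance at far fewer degrees of freedom.  Retaining all
components (``var_explained=1``) recovers the Hotelling statistic exactly.

A continuous outcome uses an OLS null fit, unit weights, and the same
empirical-covariance construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

logger = logging.getLogger(__name__)

_EIG_DROP_TOL = 1e-10  # eigenvalues <= tol * lambda_1 treated as numerically null


class SeparationError(RuntimeError):
    """Logistic null fit failed (perfect separation or non-convergence)."""


@dataclass
class PairedCohort:
    """Outcome, covariates, recipient genotypes and matching score for n pairs."""

    Y: np.ndarray
    W: np.ndarray  # (n, K); K may be 0
    X: np.ndarray  # (n, m) recipient minor-allele counts
    Z: np.ndarray  # (n,) gene-based matching score
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.W.size == 0:
            self.W = np.empty((self.Y.size, 0))
        if self.W.shape[0] != self.Y.size:
            self.W = self.W.T
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float).ravel()
        n = self.Y.size
        if self.X.shape[0] != n or self.Z.size != n or self.W.shape[0] != n:
            raise ValueError("Y, W, X, Z must agree on the number of pairs")
        if self.outcome_type not in ("binary", "continuous"):
            raise ValueError("outcome_type must be 'binary' or 'continuous'")
        if self.outcome_type == "binary":
            classes = np.unique(self.Y)
            if not np.isin(classes, (0.0, 1.0)).all():
                raise ValueError("binary outcome must be coded 0/1")
            if classes.size < 2:
                raise ValueError("binary outcome must contain both classes")
        if n < self.W.shape[1] + 2:
            raise ValueError("need n >= K + 2 pairs")

    @property
    def n(self) -> int:
        return self.Y.size

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class NullFit:
    fitted_mean: np.ndarray       # p1_hat(W_i) (binary) or OLS fit (continuous)
    weights: np.ndarray           # p(1-p) (binary) or ones (continuous)
    coefficients: np.ndarray      # (a0_hat, a_hat)
    outcome_type: str
    residual_variance: float | None = None  # continuous only: RSS/(n-K-1)
    n_iter: int = 0


@dataclass
class ResidualizedDesign:
    """Columns of (X, Z) residualised on (1, W) by weighted least squares."""

    B_res: np.ndarray  # (n, m+1); last column is the matching score residual


@dataclass
class ScoreComponents:
    U: np.ndarray       # (m+1,) score vector; recipient SNPs first, score last
    Q: np.ndarray       # (n, m+1) per-pair contributions; U = Q.sum(0)
    V_hat: np.ndarray   # (m+1, m+1) empirical covariance Q'Q

    @property
    def m(self) -> int:
        return self.U.size - 1

    @property
    def V_R(self) -> np.ndarray:
        return self.V_hat[:-1, :-1]

    @property
    def C_RS(self) -> np.ndarray:
        return self.V_hat[:-1, -1]

    @property
    def V_S(self) -> float:
        return float(self.V_hat[-1, -1])


@dataclass
class EigenReduction:
    A_s: np.ndarray       # (m, s) leading eigenvectors of V_R
    lambdas: np.ndarray   # (s,) eigenvalues, descending, all > 0
    s: int
    threshold: float
    all_lambdas: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class JSTResult:
    statistic: float
    s: int
    df: int
    p_value: float
    threshold_used: float
    n_snps_used: int = 0
    score_type: str | None = None
    score_degenerate: bool = False


def _design(W: np.ndarray, n: int) -> np.ndarray:
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.size == 0:
        return np.ones((n, 1))
    if W.shape[0] != n:
        W = W.T
    return np.column_stack([np.ones(n), W])


def fit_null(
    Y: np.ndarray,
    W: np.ndarray,
    outcome_type: str = "binary",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NullFit:
    """Fit the covariate-only null model.

    Binary: logistic regression of Y on (1, W) by iteratively reweighted least
    squares (IRLS).  Continuous: ordinary least squares, with the residual
    variance estimated as RSS/(n-K-1).
    """
    Y = np.asarray(Y, dtype=float).ravel()
    n = Y.size
    A = _design(W, n)
    K = A.shape[1] - 1
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("covariate matrix (1, W) is rank deficient")

    if outcome_type == "continuous":
        coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
        fitted = A @ coef
        rss = float(np.sum((Y - fitted) ** 2))
        dof = n - K - 1
        return NullFit(
            fitted_mean=fitted,
            weights=np.ones(n),
            coefficients=coef,
            outcome_type="continuous",
            residual_variance=rss / dof,
        )

    if outcome_type != "binary":
        raise ValueError("outcome_type must be 'binary' or 'continuous'")

    beta = np.zeros(A.shape[1])
    beta[0] = np.log(Y.mean() / (1 - Y.mean() + 1e-12) + 1e-12)
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        if np.any(w < 1e-12):
            # clamp to keep the working response finite near separation
            w = np.maximum(w, 1e-12)
        z = eta + (Y - p) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            break
    else:
        raise SeparationError(f"logistic null fit did not converge in {max_iter} iterations")

    p = 1.0 / (1.0 + np.exp(-(A @ beta)))
    if np.any(p < 1e-10) or np.any(p > 1 - 1e-10):
        raise SeparationError("fitted null probabilities at 0/1: perfect separation")
    return NullFit(
        fitted_mean=p,
        weights=p * (1.0 - p),
        coefficients=beta,
        outcome_type="binary",
        n_iter=it,
    )


def residualize(
    X: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    weights: np.ndarray,
) -> ResidualizedDesign:
    """Residualise each column of (X, Z) on (1, W) by weighted least squares.

    The weights are the null-model IRLS weights ``p(1-p)`` (unit weights for a
    continuous outcome), so each residual column is weighted-orthogonal to the
    covariate space.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float).ravel()
    n = Z.size
    B = np.column_stack([X, Z])
    A = _design(W, n)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("covariate matrix (1, W) is rank deficient")
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], B * sw[:, None], rcond=None)
    return ResidualizedDesign(B_res=B - A @ coef)


def score_components(
    Y: np.ndarray,
    null_fit: NullFit,
    design: ResidualizedDesign,
) -> ScoreComponents:
    """Score vector U, per-pair contributions Q and empirical covariance Q'Q.

    ``Q[i,c] = B_res[i,c] (Y_i - mu_i)``; the first m columns are the
    recipient-SNP scores, the last is the matching-score component.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    resid = Y - null_fit.fitted_mean
    Q = design.B_res * resid[:, None]
    U = Q.sum(axis=0)
    V_hat = Q.T @ Q
    return ScoreComponents(U=U, Q=Q, V_hat=V_hat)


def eigen_reduce(V_R: np.ndarray, threshold: float) -> EigenReduction:
    """Leading eigenpairs of V_R explaining at least ``threshold`` of total variance.

    Eigenvalues are sorted descending, numerically negative ones clipped at 0,
    and eigenvalues below ``1e-10 * lambda_1`` discarded before applying the
    cumulative-fraction rule.  s is the smallest count whose eigenvalues sum
    to at least ``threshold`` of the retained total.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    V_R = np.asarray(V_R, dtype=float)
    vals, vecs = np.linalg.eigh(V_R)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    if vals.size == 0 or vals[0] <= 0:
        raise ValueError("V_R has no positive eigenvalues: nothing to decompose")
    keep = vals > _EIG_DROP_TOL * vals[0]
    vals, vecs = vals[keep], vecs[:, keep]
    cumfrac = np.cumsum(vals) / vals.sum()
    s = int(np.searchsorted(cumfrac, threshold - 1e-12) + 1)
    s = min(s, vals.size)
    return EigenReduction(
        A_s=vecs[:, :s], lambdas=vals[:s], s=s, threshold=threshold, all_lambdas=vals
    )


def jst_statistic(
    components: ScoreComponents,
    reduction: EigenReduction,
    scaling: str = "sqrt",
) -> JSTResult:
    """JST statistic from score components and the eigen reduction.

    Each retained PC score is standardised as ``a_l' U_R / sqrt(lambda_l)`` so
    its null variance is 1 and the middle matrix has an identity upper block:

        T = (U_P^R, U_S)' [[I_s, c], [c', V_S]]^{-1} (U_P^R, U_S)

    with ``c_l = a_l' C_RS / sqrt(lambda_l)``.  Under the null T is
    asymptotically chi-square with s+1 degrees of freedom.  ``scaling="lambda"``
    keeps the identity upper block but scales the PC scores by ``1/lambda_l``
    instead; the PC scores then no longer have unit null variance, so this
    variant is for diagnostic comparison only.
    """
    if scaling not in ("sqrt", "lambda"):
        raise ValueError("scaling must be 'sqrt' or 'lambda'")
    lam = reduction.lambdas
    denom = np.sqrt(lam) if scaling == "sqrt" else lam
    U_R = components.U[:-1]
    U_S = float(components.U[-1])
    U_PR = (reduction.A_s.T @ U_R) / denom
    s = reduction.s

    V_S = components.V_S
    scale = float(np.max(np.abs(components.V_hat))) or 1.0
    if V_S <= 1e-12 * scale:
        # matching score constant after residualisation: recipient-only test
        logger.warning("matching score has zero residual variance; df reduced to s")
        T = float(U_PR @ U_PR)
        p = float(stats.chi2.sf(T, s))
        return JSTResult(
            statistic=T, s=s, df=s, p_value=p,
            threshold_used=reduction.threshold, score_degenerate=True,
        )

    c = (reduction.A_s.T @ components.C_RS) / denom
    M = np.empty((s + 1, s + 1))
    M[:s, :s] = np.eye(s)
    M[:s, s] = c
    M[s, :s] = c
    M[s, s] = V_S
    U_P = np.append(U_PR, U_S)
    try:
        cho = linalg.cho_factor(M)
        T = float(U_P @ linalg.cho_solve(cho, U_P))
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "JST middle matrix is singular: matching score is numerically "
            "collinear with the retained genotype PCs"
        ) from exc
    df = s + 1
    return JSTResult(
        statistic=T, s=s, df=df,
        p_value=float(stats.chi2.sf(T, df)),
        threshold_used=reduction.threshold,
    )


def jst_test(
    cohort: PairedCohort,
    var_explained: float = 0.85,
    scaling: str = "sqrt",
) -> JSTResult:
    """End-to-end joint score test on a paired cohort.

    Monomorphic (zero-variance) recipient SNP columns are dropped with a log
    record before testing.  Deterministic given its inputs.
    """
    keep = np.std(cohort.X, axis=0) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic SNP column(s)", n_dropped)
    X = cohort.X[:, keep]
    if X.shape[1] < 1:
        raise ValueError("no polymorphic SNPs available for testing")

    nf = fit_null(cohort.Y, cohort.W, cohort.outcome_type)
    design = residualize(X, cohort.Z, cohort.W, nf.weights)
    comp = score_components(cohort.Y, nf, design)
    red = eigen_reduce(comp.V_R, var_explained)
    res = jst_statistic(comp, red, scaling=scaling)
    res.n_snps_used = X.shape[1]
    return res


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
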
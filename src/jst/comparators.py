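"""Comparator tests: joint GLM (LRT/score) and SKAT-style quadratic forms.

Both comparators take the same n x (m+1) matrix B of recipient genotypes plus
the appended gene-based matching score that the joint score test uses.

The joint GLM test fits the outcome on (1, W) under the null and on
(1, W, B) under the alternative and refers the likelihood-ratio (or Rao
score) statistic to chi-square with m+1 degrees of freedom.  With a binary
outcome and few cases relative to m, the chi-square approximation for the
LRT is anti-conservative — the inflation grows as prevalence falls.

The quadratic-form (SKAT-style) test computes ``Q = (Y - mu)' K (Y - mu)``
for a kernel K built from B, and calibrates Q against its null distribution,
a weighted mixture of chi-square(1) variables whose weights are the non-zero
eigenvalues of P^{1/2} K P^{1/2} (P the covariance of the null residuals
after accounting for covariate estimation).  Mixture tail probabilities come
from Liu-type moment matching by default, or Imhof numerical inversion when
``method="imhof"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .jst_core import NullFit, SeparationError, _design, fit_null


@dataclass
class KernelSpec:
    """Kernel choice for the quadratic-form test.

    kind : {"linear", "ibs"}
    scale_scores_01 : bool
        Min-max scale the appended score column to [0, 1] before the linear
        kernel (improves power when the matching score drives the signal).
    include_score : bool
        If False, drop the score column from the kernel entirely.
    """

    kind: str = "linear"
    scale_scores_01: bool = False
    include_score: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "ibs"):
            raise ValueError("kernel kind must be 'linear' or 'ibs'")


@dataclass
class QuadTestResult:
    q_stat: float
    p_value: float
    method: str
    eigenvalues: np.ndarray | None = None


def _minmax(col: np.ndarray, hi: float) -> np.ndarray:
    rng = col.max() - col.min()
    if rng <= 0:
        return np.zeros_like(col)
    return hi * (col - col.min()) / rng


def build_kernel(B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """n x n kernel matrix from the combined genotype + score matrix.

    linear: ``K = B B'`` after optional [0,1] scaling of the score column.
    ibs: average per-column allele sharing
    ``K[i,i'] = sum_c (2 - |B[i,c] - B[i',c]|) / (2(m+1))`` with the
    (non-genotype) score column min-max scaled to [0, 2] so it enters on the
    genotype scale.
    """
    B = np.asarray(B, dtype=float)
    if not np.isfinite(B).all():
        raise ValueError("kernel input contains non-finite entries")
    B = B.copy()
    if not spec.include_score:
        B = B[:, :-1]
    if spec.kind == "linear":
        if spec.include_score and spec.scale_scores_01:
            B[:, -1] = _minmax(B[:, -1], 1.0)
        return B @ B.T
    # IBS kernel
    if spec.include_score:
        B[:, -1] = _minmax(B[:, -1], 2.0)
    n, p = B.shape
    K = np.zeros((n, n))
    for c in range(p):
        K += 2.0 - np.abs(B[:, c, None] - B[None, :, c])
    return K / (2.0 * p)


def liu_pvalue(q: float, lam: np.ndarray) -> float:
    """Upper tail of ``sum_k lam_k chi2_1`` at q by Liu-Tang-Zhang moment matching."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive mixture eigenvalues")
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t = (q - mu_q) / sigma_q
    mu_x = dof + delta
    sigma_x = np.sqrt(2 * (dof + 2 * delta))
    x = t * sigma_x + mu_x
    return float(stats.ncx2.sf(x, dof, delta)) if delta > 0 else float(stats.chi2.sf(x, dof))


def imhof_pvalue(q: float, lam: np.ndarray, limit: int = 400) -> float:
    """Upper tail of the chi-square mixture by Imhof's inversion integral.

    A single eigenvalue is handled in closed form (the mixture is then a
    scaled chi-square(1)); the oscillatory inversion integral converges
    quickly once a handful of eigenvalues are present.
    """
    import warnings

    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive mixture eigenvalues")
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0, np.inf, limit=limit, epsabs=1e-10)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


def _null_projection_factors(null_fit: NullFit, W: np.ndarray, n: int):
    """Return (D_sqrt, Qw) with P = D^1/2 (I - Qw Qw') D^1/2 the residual covariance.

    Qw holds an orthonormal basis of the weighted covariate space; for a
    continuous outcome D = sigma^2 I.
    """
    A = _design(W, n)
    if null_fit.outcome_type == "binary":
        d = null_fit.weights
    else:
        d = np.full(n, null_fit.residual_variance)
    sd = np.sqrt(d)
    Qw, _ = np.linalg.qr(A * sd[:, None])
    return sd, Qw


def quad_test(
    Y: np.ndarray,
    W: np.ndarray,
    K: np.ndarray | None,
    outcome_type: str = "binary",
    method: str = "liu",
    B_factor: np.ndarray | None = None,
    null_fit: NullFit | None = None,
) -> QuadTestResult:
    """SKAT-style quadratic-form test of the combined genotype + score matrix.

    Pass either the kernel ``K`` itself, or (for the linear kernel) its factor
    ``B_factor`` with ``K = B_factor B_factor'``, which avoids any n x n
    computation: the mixture weights are then the eigenvalues of
    ``B' P B``.
    """
    Y = np.asarray(Y, dtype=float).ravel()
    n = Y.size
    if null_fit is None:
        null_fit = fit_null(Y, W, outcome_type)
    resid = Y - null_fit.fitted_mean
    sd, Qw = _null_projection_factors(null_fit, W, n)

    if B_factor is not None:
        q_stat = float(np.sum((B_factor.T @ resid) ** 2))
        G = B_factor * sd[:, None]
        G = G - Qw @ (Qw.T @ G)
        lam = np.linalg.eigvalsh(G.T @ G)[::-1]
    else:
        K = np.asarray(K, dtype=float)
        if np.allclose(K, 0):
            raise ValueError("all-zero kernel")
        q_stat = float(resid @ K @ resid)
        C = K * sd[:, None] * sd[None, :]
        QtC = Qw.T @ C
        C = C - Qw @ QtC - QtC.T @ Qw.T + Qw @ (QtC @ Qw) @ Qw.T
        lam = np.linalg.eigvalsh(C)[::-1]

    lam = lam[lam > 1e-10 * max(lam[0], 1e-300)]
    if lam.size == 0:
        raise ValueError("null mixture has no positive eigenvalues")
    if method == "liu":
        p = liu_pvalue(q_stat, lam)
    elif method == "imhof":
        p = imhof_pvalue(q_stat, lam)
    else:
        raise ValueError("method must be 'liu' or 'imhof'")
    return QuadTestResult(q_stat=q_stat, p_value=p, method=method, eigenvalues=lam)


def _binary_loglik(Y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(Y * np.log(p) + (1 - Y) * np.log(1 - p)))


def _fit_logistic(Y: np.ndarray, A: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """IRLS logistic fit on an explicit design matrix; returns (coef, p, loglik)."""
    n, k = A.shape
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("design matrix is rank deficient")
    beta = np.zeros(k)
    ybar = np.clip(Y.mean(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        z = eta + (Y - p) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise SeparationError("alternative logistic fit did not converge")
    p = 1.0 / (1.0 + np.exp(-np.clip(A @ beta, -30, 30)))
    return beta, p, _binary_loglik(Y, p)


def glm_joint_test(
    Y: np.ndarray,
    W: np.ndarray,
    B: np.ndarray,
    outcome_type: str = "binary",
    variant: str = "lrt",
) -> float:
    """Joint GLM test of the m+1 columns of B added to the covariate model.

    LRT: ``2 (l_alt - l_null)`` against chi-square(m+1).
    score: Rao score test of the added columns against chi-square(m+1), using
    the model-based (Fisher information) variance.

    Returns the p-value.  Raises ``SeparationError`` on non-convergence of the
    binary alternative fit (callers in simulation loops count such failures).
    """
    Y = np.asarray(Y, dtype=float).ravel()
    B = np.asarray(B, dtype=float)
    n = Y.size
    A0 = _design(W, n)
    A1 = np.column_stack([A0, B])
    df = B.shape[1]
    if np.linalg.matrix_rank(A1) < A1.shape[1]:
        raise ValueError("alternative design (1, W, B) is rank deficient")
    if variant not in ("lrt", "score"):
        raise ValueError("variant must be 'lrt' or 'score'")

    if outcome_type == "continuous":
        r0 = Y - A0 @ np.linalg.lstsq(A0, Y, rcond=None)[0]
        r1 = Y - A1 @ np.linalg.lstsq(A1, Y, rcond=None)[0]
        rss0, rss1 = float(r0 @ r0), float(r1 @ r1)
        if variant == "lrt":
            stat = n * np.log(rss0 / rss1)
        else:
            # Rao score: projection of B onto the covariate complement
            Bh = B - A0 @ np.linalg.lstsq(A0, B, rcond=None)[0]
            u = Bh.T @ r0
            info = Bh.T @ Bh
            stat = float(u @ np.linalg.solve(info, u)) / (rss0 / n)
        return float(stats.chi2.sf(stat, df))

    if outcome_type != "binary":
        raise ValueError("outcome_type must be 'binary' or 'continuous'")
    n_cases = min(Y.sum(), n - Y.sum())
    if n_cases < df + A0.shape[1] + 1:
        import warnings

        warnings.warn(
            f"only {int(n_cases)} minority-class outcomes for {df + A0.shape[1]} "
            "parameters; joint GLM fit may be unstable",
            stacklevel=2,
        )
    _, p0, ll0 = _fit_logistic(Y, A0)
    if variant == "lrt":
        _, _, ll1 = _fit_logistic(Y, A1)
        stat = 2.0 * (ll1 - ll0)
    else:
        w0 = p0 * (1 - p0)
        sw = np.sqrt(w0)
        Qw, _ = np.linalg.qr(A0 * sw[:, None])
        G = B * sw[:, None]
        G = G - Qw @ (Qw.T @ G)
        u = B.T @ (Y - p0)
        info = G.T @ G
        stat = float(u @ np.linalg.solve(info, u))
    return float(stats.chi2.sf(max(stat, 0.0), df))
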
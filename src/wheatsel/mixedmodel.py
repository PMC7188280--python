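"""Single-variance-component REML machinery.

Everything heavier in this package — augmented-design variance components,
RRBLUP, and the kinship-corrected association scan — reduces to the same
mixed model

    y = X beta + u + e,    u ~ N(0, sigma_g^2 * A),    e ~ N(0, sigma_e^2 * I)

with one positive-semidefinite covariance structure ``A`` (a genomic
relationship matrix, or ``Z Z'`` for a genotype incidence ``Z``).  The
restricted likelihood is profiled over the variance ratio
``delta = sigma_e^2 / sigma_g^2`` after a single spectral decomposition
(the EMMA trick), and maximised by Brent search on ``log(delta)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["REMLFit", "reml_fit", "gls_blup"]

LOG_DELTA_LO = -10.0
LOG_DELTA_HI = 10.0
#: floor applied to variance components that REML drives to the boundary
VARIANCE_FLOOR = 1e-10


@dataclass
class REMLFit:
    """Result of a profiled-REML fit of the one-component mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float          # sigma_e2 / sigma_g2 at the optimum
    beta: np.ndarray      # GLS fixed-effect estimates at the optimum
    loglik: float         # restricted log-likelihood at the optimum
    n: int
    p: int                # rank of X
    boundary: bool        # optimum hit the log-delta search bound
    diagnostics: dict = field(default_factory=dict)

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(np.clip(self.sigma_g2 / tot, 0.0, 1.0)) if tot > 0 else np.nan


def _restricted_loglik(log_delta: float, lam: np.ndarray, eta2: np.ndarray, df: int) -> float:
    delta = np.exp(log_delta)
    denom = lam + delta
    s = float(np.sum(eta2 / denom))
    if s <= 0:
        return -np.inf
    return 0.5 * (df * (np.log(df / (2.0 * np.pi)) - 1.0 - np.log(s))
                  - float(np.sum(np.log(denom))))


def reml_fit(y: np.ndarray, X: np.ndarray, A: np.ndarray) -> REMLFit:
    """REML estimates of (sigma_g^2, sigma_e^2) for ``y = X beta + u + e``.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) full-column-rank fixed-effect design (an intercept at least).
    A : (n, n) symmetric PSD covariance structure of the random effect.

    Notes
    -----
    Follows Kang et al.'s efficient exact formulation: eigendecompose
    ``S (A + I) S`` with ``S`` the projection orthogonal to ``X``; the
    ``n - p`` eigenvalues above the X-null-space give the profiled
    restricted likelihood in O(n) per candidate ``delta``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    p = int(np.linalg.matrix_rank(X))
    if p < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    df = n - p
    if df < 2:
        raise ValueError("not enough residual degrees of freedom for REML")

    Q, _ = np.linalg.qr(X)
    B = A + np.eye(n)
    M = B - Q @ (Q.T @ B)
    M = M - (M @ Q) @ Q.T
    M = 0.5 * (M + M.T)
    w, U = linalg.eigh(M)
    idx = np.argsort(w)[::-1][:df]        # the df non-null eigenpairs
    lam = np.clip(w[idx] - 1.0, 0.0, None)
    eta = U[:, idx].T @ y
    eta2 = eta ** 2

    # coarse grid then Brent refinement around the best bracket
    grid = np.linspace(LOG_DELTA_LO, LOG_DELTA_HI, 41)
    vals = np.array([_restricted_loglik(g, lam, eta2, df) for g in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_restricted_loglik(g, lam, eta2, df),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x)
    boundary = k in (0, grid.size - 1)
    delta = float(np.exp(log_delta))
    loglik = _restricted_loglik(log_delta, lam, eta2, df)

    sigma_g2 = float(np.sum(eta2 / (lam + delta)) / df)
    sigma_e2 = delta * sigma_g2
    if sigma_g2 < VARIANCE_FLOOR:
        warnings.warn("REML genetic variance at boundary; clamped to floor")
        sigma_g2 = VARIANCE_FLOOR
    if sigma_e2 < VARIANCE_FLOOR:
        warnings.warn("REML residual variance at boundary; clamped to floor")
        sigma_e2 = VARIANCE_FLOOR

    beta, _, _ = gls_blup(y, X, A, sigma_g2, sigma_e2)
    return REMLFit(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta, beta=beta,
        loglik=loglik, n=n, p=p, boundary=boundary,
        diagnostics={"log_delta": log_delta, "grid_max": float(vals[k])},
    )


def gls_blup(y, X, A, sigma_g2, sigma_e2):
    """GLS fixed effects, V^{-1} residual, and BLUP ``u`` at given variances.

    Returns ``(beta, Vinv_resid, u_blup)`` where
    ``u_blup = sigma_g2 * A @ Vinv_resid`` and
    ``Vinv_resid = V^{-1} (y - X beta)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    V = sigma_g2 * A + sigma_e2 * np.eye(n)
    cf = linalg.cho_factor(V, lower=True)
    ViX = linalg.cho_solve(cf, X)
    Viy = linalg.cho_solve(cf, y)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    resid = y - X @ beta
    Vir = linalg.cho_solve(cf, resid)
    u = sigma_g2 * (A @ Vir)
    return beta, Vir, u
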
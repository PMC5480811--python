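"""Restricted-maximum-likelihood linear mixed models via spectral rotation.

Two variance-component structures are used in the analyses:

* a general kernel ``V = sigma_g^2 K + sigma_e^2 I`` (realized-relationship
  matrix for the fitness association), handled by eigendecomposing K once
  and profiling the restricted likelihood over ``delta = sigma_e^2 /
  sigma_g^2`` on a log grid refined by golden section;
* a rank-1 kernel ``V = sigma_u^2 v v^T + sigma_e^2 I`` (the first LD
  eigenvector as a random effect), where every quantity reduces to scalar
  projections on ``v`` and the profile over ``gamma = sigma_u^2 / sigma_e^2``
  is closed-form per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["KernelLmm", "LmmFitResult", "fit_rank1_lmm", "Rank1Fit"]


@dataclass
class LmmFitResult:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray  # two-sided Wald per coefficient
    sigma_g2: float
    sigma_e2: float
    delta: float
    h2: float
    reml_loglik: float


class KernelLmm:
    """REML mixed model ``y = X beta + g + e`` with ``g ~ N(0, sigma_g^2 K)``.

    The kernel is eigendecomposed once; repeated fits (permutations,
    per-SNP tests) reuse the rotation. ``delta = sigma_e^2 / sigma_g^2``.
    """

    #: log10-delta profile grid (21 points over ten orders of magnitude)
    LOG_DELTA_GRID = np.linspace(-5.0, 5.0, 21)

    def __init__(self, kernel: np.ndarray, psd_tol: float = 1e-6):
        kernel = np.asarray(kernel, dtype=float)
        if not np.allclose(kernel, kernel.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        s, u = np.linalg.eigh(kernel)
        if s[0] < -psd_tol * max(1.0, s[-1]):
            raise ValueError(f"kernel is not PSD (min eigenvalue {s[0]:.3g})")
        self.eigvals = np.clip(s, 0.0, None)
        self.eigvecs = u

    def rotate(self, m: np.ndarray) -> np.ndarray:
        return self.eigvecs.T @ m

    def _neg2_reml(self, log10_delta: float, ytil: np.ndarray,
                   xtil: np.ndarray) -> float:
        delta = 10.0 ** log10_delta
        w = 1.0 / (self.eigvals + delta)
        xtw = xtil * w[:, None]
        a = xtw.T @ xtil
        b = xtw.T @ ytil
        beta = np.linalg.solve(a, b)
        r = ytil - xtil @ beta
        n, p = xtil.shape
        rss = float(r @ (w * r))
        sigma_g2 = rss / (n - p)
        sign, logdet_a = np.linalg.slogdet(a)
        return ((n - p) * np.log(sigma_g2)
                + float(np.sum(np.log(self.eigvals + delta)))
                + logdet_a + (n - p))

    def fit(self, y: np.ndarray, X: np.ndarray,
            delta: float | None = None) -> LmmFitResult:
        """REML fit; ``delta`` may be fixed (skips the profile)."""
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        ytil = self.rotate(y)
        xtil = self.rotate(X)
        if delta is None:
            grid = self.LOG_DELTA_GRID
            vals = [self._neg2_reml(g, ytil, xtil) for g in grid]
            k = int(np.argmin(vals))
            lo = grid[max(k - 1, 0)]
            hi = grid[min(k + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                self._neg2_reml, bounds=(lo, hi), args=(ytil, xtil),
                method="bounded", options={"xatol": 1e-6})
            delta = float(10.0 ** res.x)
            if res.fun > min(vals) + 1e-9:  # guard: keep the grid optimum
                delta = float(10.0 ** grid[k])
        return self._gls_at(delta, ytil, xtil)

    def _gls_at(self, delta: float, ytil: np.ndarray,
                xtil: np.ndarray) -> LmmFitResult:
        n, p = xtil.shape
        w = 1.0 / (self.eigvals + delta)
        xtw = xtil * w[:, None]
        a = xtw.T @ xtil
        a_inv = np.linalg.inv(a)
        beta = a_inv @ (xtw.T @ ytil)
        r = ytil - xtil @ beta
        sigma_g2 = float(r @ (w * r)) / (n - p)
        sigma_e2 = sigma_g2 * delta
        se = np.sqrt(np.diag(a_inv) * sigma_g2)
        z = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        _, logdet_a = np.linalg.slogdet(a)
        neg2 = ((n - p) * np.log(sigma_g2)
                + float(np.sum(np.log(self.eigvals + delta)))
                + logdet_a + (n - p))
        return LmmFitResult(
            beta=beta, se=se, p=pvals, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
            delta=delta, h2=sigma_g2 / (sigma_g2 + sigma_e2),
            reml_loglik=-0.5 * neg2)

    def scan(self, y: np.ndarray, W: np.ndarray, X_snps: np.ndarray,
             delta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """GLS association of each column of ``X_snps`` given covariates ``W``.

        Variance ratio ``delta`` is held fixed (estimated once under the
        covariate-only model, the usual spectral-LMM strategy). Returns
        (beta, se, p) per SNP via the partitioned-regression identity.
        """
        ytil = self.rotate(np.asarray(y, dtype=float))
        wtil = self.rotate(np.asarray(W, dtype=float))
        stil = self.rotate(np.asarray(X_snps, dtype=float))
        n, p = wtil.shape
        wts = 1.0 / (self.eigvals + delta)
        ww = wtil * wts[:, None]
        a_inv = np.linalg.inv(ww.T @ wtil)
        e = ww.T @ ytil
        b = ww.T @ stil  # p x m
        c = np.einsum("ij,ij->j", stil * wts[:, None], stil)
        d = (stil * wts[:, None]).T @ ytil
        ab = a_inv @ b
        denom = c - np.einsum("ij,ij->j", b, ab)
        denom = np.where(denom <= 0, np.nan, denom)
        beta = (d - b.T @ (a_inv @ e)) / denom
        ywy = float(ytil @ (wts * ytil))
        base_rss = ywy - float(e @ (a_inv @ e))
        rss = base_rss - beta ** 2 * denom
        dof = n - p - 1
        sigma2 = np.clip(rss, 1e-300, None) / dof
        se = np.sqrt(sigma2 / denom)
        pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
        return beta, se, pvals


# ---------------------------------------------------------------------------
# rank-1 random effect (first LD eigenvector)
# ---------------------------------------------------------------------------

@dataclass
class Rank1Fit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    sigma_u2: float
    sigma_e2: float
    gamma: float  # sigma_u^2 / sigma_e^2
    reml_loglik: float


def _rank1_profile(gamma: float, xtx, xty, yty, xtv, ytv, n: int):
    """GLS pieces for C = I + gamma v v^T (v unit norm); all O(p^2)."""
    f = gamma / (1.0 + gamma)
    a = xtx - f * np.outer(xtv, xtv)
    b = xty - f * xtv * ytv
    beta = np.linalg.solve(a, b)
    # r' C^-1 r = y'C^-1 y - 2 beta' X'C^-1 y + beta' X'C^-1 X beta
    quad = (yty - f * ytv ** 2) - 2 * beta @ b + beta @ a @ beta
    return a, beta, float(quad)


def _rank1_neg2_reml(gamma, xtx, xty, yty, xtv, ytv, n):
    p = xtx.shape[0]
    a, _, quad = _rank1_profile(gamma, xtx, xty, yty, xtv, ytv, n)
    sigma_e2 = max(quad, 1e-300) / (n - p)
    _, logdet_a = np.linalg.slogdet(a)
    return (n - p) * np.log(sigma_e2) + np.log1p(gamma) + logdet_a + (n - p)


def fit_rank1_lmm(y: np.ndarray, X: np.ndarray, v: np.ndarray,
                  gamma: float | None = None) -> Rank1Fit:
    """REML fit of ``y = X beta + u v + e`` with ``u ~ N(0, sigma_u^2)``.

    ``v`` is normalized to unit length; the covariance is ``sigma_u^2 v v^T
    + sigma_e^2 I``. ``gamma`` (``sigma_u^2 / sigma_e^2``) may be fixed:
    0 reduces exactly to OLS; a very large value approaches OLS with ``v``
    as a fixed covariate.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"{n} observations cannot support {p} coefficients")
    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    xtv = X.T @ v
    ytv = float(y @ v)
    args = (xtx, xty, yty, xtv, ytv, n)

    if gamma is None:
        grid = np.concatenate([[0.0], 10.0 ** np.linspace(-6, 12, 19)])
        vals = [_rank1_neg2_reml(g, *args) for g in grid]
        k = int(np.argmin(vals))
        if 0 < k < len(grid) - 1:
            lo = np.log10(max(grid[k - 1], 1e-12))
            hi = np.log10(grid[k + 1])
            res = optimize.minimize_scalar(
                lambda lg: _rank1_neg2_reml(10.0 ** lg, *args),
                bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
            gamma = float(10.0 ** res.x)
            if res.fun > vals[k] + 1e-9:
                gamma = float(grid[k])
        else:
            gamma = float(grid[k])

    a, beta, quad = _rank1_profile(gamma, *args)
    sigma_e2 = max(quad, 1e-300) / (n - p)
    a_inv = np.linalg.inv(a)
    se = np.sqrt(np.clip(np.diag(a_inv), 0, None) * sigma_e2)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    neg2 = _rank1_neg2_reml(gamma, *args)
    return Rank1Fit(beta=beta, se=se, p=pvals, sigma_u2=gamma * sigma_e2,
                    sigma_e2=sigma_e2, gamma=gamma, reml_loglik=-0.5 * neg2)
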
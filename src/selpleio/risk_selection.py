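"""Gene-level association between disease genetic risk and selection signals.

Per gene and population, per-SNP |ln(OR)| disease risk is regressed on
per-SNP |iHS| under a mixed model whose random effect is the gene's first
LD eigenvector (rank-1 covariance), absorbing correlated-SNP structure.
Both variables are standardized to unit variance, so the slope is a scaled
regression coefficient. Two permutation nulls attach to each fit: shuffling
iHS across SNPs within the gene, and refitting the same model on random
length-matched genes from elsewhere in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import Rank1Fit, fit_rank1_lmm

__all__ = [
    "AssociationResult",
    "fit_selection_risk_model",
    "permute_association",
    "gene_matched_null",
    "rank_genes",
]


@dataclass
class AssociationResult:
    gene: str
    population: str
    n_snps: int
    beta_scaled: float
    nominal_p: float
    sigma_u2: float
    sigma_e2: float
    perm_p_shuffle: float = float("nan")
    perm_p_genes: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.perm_p_shuffle < 0.05


def _prepare(ln_or: np.ndarray, ihs: np.ndarray, v: np.ndarray,
             use_abs: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ln_or = np.asarray(ln_or, dtype=float)
    ihs = np.asarray(ihs, dtype=float)
    v = np.asarray(v, dtype=float)
    keep = np.isfinite(ln_or) & np.isfinite(ihs)
    ln_or, ihs, v = ln_or[keep], ihs[keep], v[keep]
    if len(ln_or) < 3:
        raise ValueError(f"only {len(ln_or)} SNPs with defined scores; need >= 3")
    if use_abs:
        ln_or, ihs = np.abs(ln_or), np.abs(ihs)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("eigenvector is zero after dropping undefined SNPs")
    return ln_or, ihs, v / nrm


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def fit_selection_risk_model(ln_or: np.ndarray, ihs: np.ndarray, v: np.ndarray,
                             use_abs: bool = True,
                             gamma: float | None = None) -> tuple[float, float, Rank1Fit]:
    """Mixed-model slope of standardized |ln(OR)| on standardized |iHS|.

    SNPs with undefined iHS are dropped listwise (the eigenvector is
    subset and renormalized). Returns ``(beta_scaled, nominal_p, fit)``;
    ``beta_scaled`` is NaN (flagged undefined) when either variable has
    zero variance. ``gamma`` fixes the variance ratio for the degenerate
    limits (0 = OLS; large = eigenvector as fixed covariate).
    """
    ln_or, ihs, v = _prepare(ln_or, ihs, v, use_abs)
    try:
        y = _standardize(ln_or)
        x = _standardize(ihs)
    except ValueError:
        nanfit = Rank1Fit(beta=np.array([np.nan, np.nan]),
                          se=np.array([np.nan, np.nan]),
                          p=np.array([np.nan, np.nan]), sigma_u2=np.nan,
                          sigma_e2=np.nan, gamma=np.nan, reml_loglik=np.nan)
        return float("nan"), float("nan"), nanfit
    X = np.column_stack([np.ones_like(x), x])
    fit = fit_rank1_lmm(y, X, v, gamma=gamma)
    return float(fit.beta[1]), float(fit.p[1]), fit


def permute_association(ln_or: np.ndarray, ihs: np.ndarray, v: np.ndarray,
                        n_perm: int = 10_000, seed: int = 0,
                        use_abs: bool = True) -> tuple[float, float]:
    """Permutation p from shuffling iHS across SNPs (risk and LD fixed).

    The model is refit per shuffle and |beta_scaled| magnitudes compared:
    ``perm_p = (1 + #{|beta_perm| >= |beta_obs|}) / (n_perm + 1)``.
    Returns ``(beta_scaled_observed, perm_p_shuffle)``.
    """
    rng = np.random.default_rng(seed)
    beta_obs, _, _ = fit_selection_risk_model(ln_or, ihs, v, use_abs=use_abs)
    if not np.isfinite(beta_obs):
        return beta_obs, float("nan")
    ln_or0 = np.asarray(ln_or, dtype=float)
    ihs0 = np.asarray(ihs, dtype=float)
    count = 0
    for _ in range(n_perm):
        b, _, _ = fit_selection_risk_model(
            ln_or0, rng.permutation(ihs0), v, use_abs=use_abs)
        if np.isfinite(b) and abs(b) >= abs(beta_obs):
            count += 1
    return beta_obs, (1.0 + count) / (n_perm + 1.0)


def gene_matched_null(observed_nominal_p: float,
                      null_gene_inputs: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                      use_abs: bool = True) -> float:
    """Permutation p from length-matched random genes.

    Each element of ``null_gene_inputs`` is ``(ln_or, ihs, v)`` for one null
    gene; the same mixed model is fit to each and
    ``perm_p = (1 + #{null nominal_p <= observed}) / (n_null + 1)``.
    Unfittable null genes are skipped (callers redraw).
    """
    null_ps = []
    for ln_or, ihs, v in null_gene_inputs:
        try:
            _, p, _ = fit_selection_risk_model(ln_or, ihs, v, use_abs=use_abs)
        except ValueError:
            continue
        if np.isfinite(p):
            null_ps.append(p)
    if not null_ps:
        return float("nan")
    count = int(np.sum(np.asarray(null_ps) <= observed_nominal_p))
    return (1.0 + count) / (len(null_ps) + 1.0)


def rank_genes(results: pd.DataFrame, alpha: float = 0.05,
               min_count: int = 4) -> pd.DataFrame:
    """Rank genes by significant selection-risk associations across populations.

    ``results`` needs columns gene, population, perm_p_shuffle. Genes sort
    by descending count of populations with ``perm_p_shuffle < alpha``
    (ties alphabetically); those with at least ``min_count`` are flagged as
    the headline panel.
    """
    sig = results.assign(sig=results["perm_p_shuffle"] < alpha)
    counts = (sig.groupby("gene")["sig"].sum().astype(int)
              .rename("n_significant").reset_index())
    counts = counts.sort_values(["n_significant", "gene"],
                                ascending=[False, True]).reset_index(drop=True)
    counts["headline"] = counts["n_significant"] >= min_count
    return counts
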
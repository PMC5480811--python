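"""cis-eQTL regression with permutation p-values and the selected-vs-random
p-value distribution comparison.

Each SNP-probe pair is tested by ordinary least squares of expression on
derived-allele dosage with sex as a covariate; permutation p-values come
from shuffling expression across samples. The selection contrast compares
the permuted eQTL p-values of candidate-signal apex SNPs (one per
gene-population combination) against an equal number of SNPs drawn from LD
blocks containing no significant-selection SNP, by a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats_io import logger

__all__ = ["fit_eqtl", "permute_eqtl", "compare_selected_vs_random", "KsComparison"]


def _dosage_t(y_matrix: np.ndarray, X: np.ndarray, xtx_inv: np.ndarray,
              dof: int) -> np.ndarray:
    """t statistic of the dosage column (index 1) for each column of y."""
    beta = xtx_inv @ (X.T @ y_matrix)  # p x k
    resid = y_matrix - X @ beta
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    se = np.sqrt(np.clip(xtx_inv[1, 1] * sigma2, 1e-300, None))
    return beta[1] / se


def fit_eqtl(dosage: np.ndarray, sex: np.ndarray,
             expression: np.ndarray) -> tuple[float, float]:
    """OLS of expression on genotype dosage + sex; returns (beta, p).

    The p-value is the two-sided t-test of the dosage coefficient. Raises
    for constant dosage (association undefined) or n < 10.
    """
    dosage = np.asarray(dosage, dtype=float)
    sex = np.asarray(sex, dtype=float)
    y = np.asarray(expression, dtype=float)
    if len(y) < 10:
        raise ValueError(f"need >= 10 complete samples, got {len(y)}")
    if np.all(dosage == dosage[0]):
        raise ValueError("constant dosage: eQTL effect undefined")
    X = np.column_stack([np.ones_like(dosage), dosage, sex])
    if np.all(sex == sex[0]):  # sex column collinear with intercept
        X = X[:, :2]
    xtx_inv = np.linalg.pinv(X.T @ X)
    dof = len(y) - X.shape[1]
    t = float(_dosage_t(y[:, None], X, xtx_inv, dof)[0])
    beta = float((xtx_inv @ (X.T @ y))[1])
    return beta, float(2.0 * stats.t.sf(abs(t), dof))


def permute_eqtl(dosage: np.ndarray, sex: np.ndarray, expression: np.ndarray,
                 n_perm: int = 10_000, seed: int = 0) -> float:
    """Permutation p from shuffling expression across samples.

    ``permuted_p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1)``; the
    shuffle breaks the genotype-expression link while keeping the design.
    """
    rng = np.random.default_rng(seed)
    dosage = np.asarray(dosage, dtype=float)
    sex = np.asarray(sex, dtype=float)
    y = np.asarray(expression, dtype=float)
    X = np.column_stack([np.ones_like(dosage), dosage, sex])
    if np.all(sex == sex[0]):
        X = X[:, :2]
    xtx_inv = np.linalg.pinv(X.T @ X)
    dof = len(y) - X.shape[1]
    t_obs = abs(float(_dosage_t(y[:, None], X, xtx_inv, dof)[0]))
    count = 0
    chunk = 500
    for lo in range(0, n_perm, chunk):
        k = min(chunk, n_perm - lo)
        perms = np.column_stack([y[rng.permutation(len(y))] for _ in range(k)])
        t = _dosage_t(perms, X, xtx_inv, dof)
        count += int(np.sum(np.abs(t) >= t_obs))
    return (1.0 + count) / (n_perm + 1.0)


@dataclass
class KsComparison:
    d_stat: float
    ks_p: float
    n_selected: int
    n_random: int
    selected_p: np.ndarray
    random_p: np.ndarray


def compare_selected_vs_random(eqtl_p_by_snp: dict[str, float],
                               apex_snps: list[str],
                               snp_blocks: dict[str, tuple[str, int]],
                               seed: int = 0,
                               alternative: str = "two-sided") -> KsComparison:
    """KS comparison of apex-SNP eQTL p-values against non-signal blocks.

    ``apex_snps`` lists the top-significant-selection SNP of each
    gene-population combination (with repetition allowed across
    combinations). ``snp_blocks`` maps snp_id -> (gene, block label).
    Stratum A collects the permuted eQTL p of each apex SNP; stratum B
    draws, per combination, one SNP uniformly from the LD blocks of the
    same gene that contain no apex SNP. Combinations whose gene has no
    eligible block are skipped (logged). ``alternative='less'`` tests that
    stratum A is stochastically smaller.
    """
    if len(apex_snps) < 5:
        raise ValueError("need >= 5 gene-population combinations with a signal")
    rng = np.random.default_rng(seed)
    signal_blocks = {snp_blocks[s] for s in apex_snps if s in snp_blocks}
    by_gene: dict[str, list[str]] = {}
    for sid, (gene, block) in snp_blocks.items():
        if (gene, block) not in signal_blocks and sid in eqtl_p_by_snp:
            by_gene.setdefault(gene, []).append(sid)

    sel, rnd = [], []
    for snp in apex_snps:
        if snp not in eqtl_p_by_snp or snp not in snp_blocks:
            logger.info("apex SNP %s lacks eQTL result; combination skipped", snp)
            continue
        gene = snp_blocks[snp][0]
        pool = by_gene.get(gene, [])
        if not pool:
            logger.info("gene %s has no non-signal LD block; combination skipped",
                        gene)
            continue
        sel.append(eqtl_p_by_snp[snp])
        rnd.append(eqtl_p_by_snp[pool[rng.integers(0, len(pool))]])

    if len(sel) < 5:
        raise ValueError("fewer than 5 usable combinations after skipping")
    a = np.asarray(sel)
    b = np.asarray(rnd)
    # exact KS for small strata, asymptotic otherwise
    method = "exact" if max(len(a), len(b)) <= 25 else "asymp"
    scipy_alt = {"two-sided": "two-sided", "less": "greater"}[alternative]
    res = stats.ks_2samp(a, b, alternative=scipy_alt, method=method)
    return KsComparison(d_stat=float(res.statistic), ks_p=float(res.pvalue),
                        n_selected=len(a), n_random=len(b),
                        selected_p=a, random_p=b)
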
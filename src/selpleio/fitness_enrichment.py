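"""Fitness association of disease loci: relatedness-corrected mixed models on
lifetime reproductive success (LRS), permutation and enrichment batteries,
and a sum-of-chi-squares gene-based test.

LRS is first adjusted for secular demographic change (per birth-year-group
mean division). Per-SNP association uses a linear mixed model with a
realized-relationship-matrix (RRM) random effect built from LD-pruned SNPs
kept clear of the tested loci (avoiding proximal contamination), with
education, smoking, birthplace and estrogen use as fixed covariates.
Permutation p-values resample nominal p-values within minor-allele-frequency
bins; set-level enrichment draws MAF-matched SNP samples; the gene-based
test sums squared z statistics against a weighted chi-square null with
weights from the gene's LD correlation eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import HaplotypePanel, logger
from .lmm import KernelLmm

__all__ = [
    "Grm",
    "adjust_lrs",
    "compute_grm",
    "lmm_assoc",
    "permute_snp_p",
    "set_enrichment_test",
    "SetEnrichment",
    "gene_based_test",
    "GeneTest",
    "gene_perm_p",
    "gene_set_enrichment",
    "multiple_testing",
]

COVARIATE_COLUMNS = ["education", "smoking", "born_in_country", "estrogen_use"]


# ---------------------------------------------------------------------------
# phenotype adjustment
# ---------------------------------------------------------------------------

def adjust_lrs(phenotypes: pd.DataFrame, n_groups: int = 6) -> pd.DataFrame:
    """Secular adjustment: divide LRS by its birth-year-group mean.

    Samples are split into ``n_groups`` equal-count groups by birth year
    (quantile cuts; ties broken by table order) and ``lrs_adjusted =
    lrs_raw / group mean``. Each group's adjusted mean is exactly 1.
    """
    out = phenotypes.copy()
    order = out["birth_year"].rank(method="first")
    groups = pd.qcut(order, q=n_groups, labels=False)
    means = out.groupby(groups)["lrs_raw"].transform("mean")
    if (means == 0).any():
        raise ValueError("a birth-year group has zero mean LRS")
    out["lrs_adjusted"] = out["lrs_raw"] / means
    out["birth_group"] = groups
    return out


# ---------------------------------------------------------------------------
# relatedness kernel
# ---------------------------------------------------------------------------

@dataclass
class Grm:
    sample_ids: list[str]
    kernel: np.ndarray
    source_snp_ids: np.ndarray = field(default_factory=lambda: np.array([]))


def _greedy_prune(hap: np.ndarray, positions: np.ndarray, prune_r2: float,
                  window_bp: int = 500_000) -> np.ndarray:
    """Left-to-right LD pruning: keep a SNP unless r^2 with a kept SNP in
    the trailing window exceeds the threshold."""
    from .locus_mapping import ld_r2

    kept: list[int] = []
    for j in range(hap.shape[1]):
        ok = True
        for k in reversed(kept):
            if positions[j] - positions[k] > window_bp:
                break
            if ld_r2(hap[:, k], hap[:, j]) > prune_r2:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.asarray(kept, dtype=np.int64)


def compute_grm(panel: HaplotypePanel, prune_r2: float = 0.2,
                exclude_intervals: list[tuple[int, int]] | None = None,
                excl_window_bp: int = 1_000_000, r2_excl: float = 0.8,
                min_snps: int = 50) -> Grm:
    """Realized relationship matrix from an LD-pruned SNP subset.

    SNPs inside (or within ``excl_window_bp`` of) an excluded interval, or
    with r^2 >= ``r2_excl`` to any SNP inside one, are removed before
    pruning so the kernel shares no LD with the tested loci. The kernel is
    the allele-frequency-standardized cross-product

        K_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)).
    """
    from .locus_mapping import ld_r2

    pos = panel.positions_bp
    keep = np.ones(panel.n_snps, dtype=bool)
    if exclude_intervals:
        in_locus = np.zeros(panel.n_snps, dtype=bool)
        for start, end in exclude_intervals:
            in_locus |= (pos >= start) & (pos <= end)
            keep &= ~((pos >= start - excl_window_bp) & (pos <= end + excl_window_bp))
        locus_idx = np.flatnonzero(in_locus)
        for j in np.flatnonzero(keep):
            for k in locus_idx:
                if abs(pos[j] - pos[k]) > excl_window_bp:
                    continue
                if ld_r2(panel.hap_matrix[:, j], panel.hap_matrix[:, k]) >= r2_excl:
                    keep[j] = False
                    break
    idx = np.flatnonzero(keep)
    daf = panel.daf()[idx]
    idx = idx[(daf > 0) & (daf < 1)]
    if prune_r2 < 1.0:
        pruned = _greedy_prune(panel.hap_matrix[:, idx], pos[idx], prune_r2)
        idx = idx[pruned]
    m = len(idx)
    if m < min_snps:
        raise ValueError(f"only {m} SNPs left for the kernel; need >= {min_snps}")
    x = panel.dosage()[:, idx].astype(float)
    p = x.mean(axis=0) / 2.0
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    kernel = z @ z.T / m
    return Grm(sample_ids=list(panel.sample_ids), kernel=kernel,
               source_snp_ids=panel.snp_ids[idx])


# ---------------------------------------------------------------------------
# mixed-model association
# ---------------------------------------------------------------------------

def lmm_assoc(lrs_adjusted: np.ndarray, covariates: pd.DataFrame | np.ndarray,
              grm: Grm | np.ndarray, dosage: np.ndarray,
              snp_ids=None) -> pd.DataFrame:
    """Per-SNP mixed-model association with adjusted LRS.

    ``y = W alpha + x beta + g + e`` with ``g ~ N(0, sigma_g^2 K)``. The
    kernel is eigendecomposed once and the variance ratio estimated by
    REML under the covariate-only model (log-grid profile plus golden
    section); each SNP is then tested by generalized least squares at that
    ratio with a two-sided Wald p. Returns a table with beta, se,
    nominal_p, maf, and the shared variance components.
    """
    y = np.asarray(lrs_adjusted, dtype=float)
    W = np.asarray(covariates, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), W])) < W.shape[1] + 1:
        cols = (list(covariates.columns)
                if isinstance(covariates, pd.DataFrame) else "covariates")
        raise ValueError(f"singular covariate design: {cols}")
    W = np.column_stack([np.ones(len(y)), W])
    kernel = grm.kernel if isinstance(grm, Grm) else np.asarray(grm)
    if kernel.shape[0] != len(y):
        raise ValueError("kernel and phenotype are not sample-aligned")
    model = KernelLmm(kernel)
    null_fit = model.fit(y, W)
    dosage = np.asarray(dosage, dtype=float)
    beta, se, p = model.scan(y, W, dosage, delta=null_fit.delta)
    maf = dosage.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1 - maf)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(dosage.shape[1])]
    return pd.DataFrame({
        "snp_id": np.asarray(snp_ids, dtype=object),
        "beta": beta, "se": se, "nominal_p": p, "maf": maf,
        "sigma_g2": null_fit.sigma_g2, "sigma_e2": null_fit.sigma_e2,
        "delta": null_fit.delta, "h2": null_fit.h2,
    })


def permute_snp_p(target_p: np.ndarray, target_maf: np.ndarray,
                  pool_p: np.ndarray, pool_maf: np.ndarray,
                  n_perm: int = 10_000, maf_bin: float = 0.05,
                  seed: int = 0, min_bin_size: int = 100) -> np.ndarray:
    """MAF-binned permutation p per target SNP.

    For each target, ``n_perm`` nominal p-values are drawn uniformly with
    replacement from pool SNPs in the same MAF bin;
    ``permuted_p = (1 + #{drawn p <= target p}) / (n_perm + 1)``. Bins with
    fewer than ``min_bin_size`` pool SNPs are widened to neighbors.
    """
    rng = np.random.default_rng(seed)
    target_p = np.atleast_1d(np.asarray(target_p, dtype=float))
    target_maf = np.atleast_1d(np.asarray(target_maf, dtype=float))
    pool_p = np.asarray(pool_p, dtype=float)
    pool_bins = np.minimum((np.asarray(pool_maf) / maf_bin).astype(int),
                           int(0.5 / maf_bin) - 1)
    t_bins = np.minimum((target_maf / maf_bin).astype(int),
                        int(0.5 / maf_bin) - 1)
    out = np.empty(len(target_p))
    nbins = int(0.5 / maf_bin)
    for b in np.unique(t_bins):
        sel_bins = [b]
        pool_idx = np.flatnonzero(np.isin(pool_bins, sel_bins))
        while len(pool_idx) < min_bin_size and not (
                min(sel_bins) <= 0 and max(sel_bins) >= nbins - 1):
            sel_bins = [min(sel_bins) - 1, *sel_bins, max(sel_bins) + 1]
            pool_idx = np.flatnonzero(np.isin(pool_bins, sel_bins))
            logger.warning("MAF bin %d widened to %s for permutation", b, sel_bins)
        if len(pool_idx) == 0:
            raise ValueError("permutation pool is empty")
        pvals = pool_p[pool_idx]
        targets = np.flatnonzero(t_bins == b)
        chunk = max(1, int(4e6 // max(n_perm, 1)))
        for lo in range(0, len(targets), chunk):
            rows = targets[lo:lo + chunk]
            draws = pvals[rng.integers(0, len(pvals), size=(len(rows), n_perm))]
            counts = (draws <= target_p[rows, None]).sum(axis=1)
            out[rows] = (1.0 + counts) / (n_perm + 1.0)
    return out if len(out) > 1 else float(out[0])


# ---------------------------------------------------------------------------
# set-level enrichment
# ---------------------------------------------------------------------------

@dataclass
class SetEnrichment:
    perm_p_set: float
    ks_two_sided_p: float
    ks_one_sided_p: float
    ks_d: float
    n_target: int
    n_draws: int
    target_sig: int
    draw_sig_counts: np.ndarray


def set_enrichment_test(target_p: np.ndarray, target_maf: np.ndarray,
                        pool_p: np.ndarray, pool_maf: np.ndarray,
                        n_draws: int = 100, alpha: float = 0.05,
                        maf_bin: float = 0.05, seed: int = 0) -> SetEnrichment:
    """MAF-matched resampling test of whether a SNP set is enriched for
    fitness associations.

    Each of ``n_draws`` samples draws, without replacement, the same number
    of pool SNPs bin-for-bin as the target set's MAF histogram (borrowing
    from the nearest bin when one runs short, logged).
    ``perm_p_set = (1 + #{draws with >= as many p < alpha}) / (n_draws+1)``.
    The pooled draw p-values are also compared to the target p-values by
    two-sided and one-sided KS tests; the one-sided test asks whether the
    target p-values are stochastically smaller (more significant).
    """
    rng = np.random.default_rng(seed)
    target_p = np.asarray(target_p, dtype=float)
    pool_p = np.asarray(pool_p, dtype=float)
    nbins = int(0.5 / maf_bin)
    t_bins = np.minimum((np.asarray(target_maf) / maf_bin).astype(int), nbins - 1)
    p_bins = np.minimum((np.asarray(pool_maf) / maf_bin).astype(int), nbins - 1)
    need = np.bincount(t_bins, minlength=nbins)
    by_bin = [np.flatnonzero(p_bins == b) for b in range(nbins)]

    target_sig = int(np.sum(target_p < alpha))
    draw_sig = np.empty(n_draws, dtype=np.int64)
    pooled: list[np.ndarray] = []
    for d in range(n_draws):
        chosen: list[np.ndarray] = []
        for b in range(nbins):
            k = need[b]
            if k == 0:
                continue
            cand = by_bin[b]
            if len(cand) < k:
                # nearest-bin borrowing
                logger.warning("pool MAF bin %d short (%d < %d); borrowing",
                               b, len(cand), k)
                order = np.argsort(np.abs(np.arange(nbins) - b))
                cand = np.concatenate([by_bin[bb] for bb in order])[: max(k, len(cand))]
            chosen.append(rng.choice(cand, size=k, replace=False))
        sample = pool_p[np.concatenate(chosen)]
        draw_sig[d] = int(np.sum(sample < alpha))
        pooled.append(sample)
    perm_p = (1.0 + int(np.sum(draw_sig >= target_sig))) / (n_draws + 1.0)
    all_pool = np.concatenate(pooled)
    two = stats.ks_2samp(target_p, all_pool, alternative="two-sided")
    one = stats.ks_2samp(target_p, all_pool, alternative="greater")
    return SetEnrichment(
        perm_p_set=perm_p, ks_two_sided_p=float(two.pvalue),
        ks_one_sided_p=float(one.pvalue), ks_d=float(two.statistic),
        n_target=len(target_p), n_draws=n_draws, target_sig=target_sig,
        draw_sig_counts=draw_sig)


# ---------------------------------------------------------------------------
# gene-based sum-of-chi-squares test
# ---------------------------------------------------------------------------

@dataclass
class GeneTest:
    gene: str
    n_snps: int
    T: float
    eigenvalues: np.ndarray
    p_gene: float
    method: str  # "satterthwaite" | "monte_carlo"
    perm_p_gene: float = float("nan")


def _weighted_chi2_sf_mc(t: float, lam: np.ndarray, n_draws: int = 1_000_000,
                         seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    total = np.zeros(n_draws)
    for l in lam:
        if l > 0:
            total += l * rng.chisquare(1, size=n_draws)
    return (1.0 + float(np.sum(total >= t))) / (n_draws + 1.0)


def gene_based_test(z: np.ndarray, corr: np.ndarray, gene: str = "",
                    mc_threshold: float = 1e-3, seed: int = 0) -> GeneTest:
    """Sum-of-squared-z gene test against a weighted chi-square null.

    ``T = sum z_i^2`` is distributed as ``sum lambda_i chi^2_1`` under the
    null, with lambda the eigenvalues of the SNP correlation matrix. The
    tail is matched by a two-moment (Satterthwaite) scaled chi-square,
    ``T ~ c chi^2_d`` with ``c = sum lambda^2 / sum lambda`` and ``d =
    (sum lambda)^2 / sum lambda^2``; small p-values (below ``mc_threshold``)
    are refined by 10^6-draw Monte Carlo of the weighted sum. Negative
    eigenvalues from a numerically non-PSD matrix are floored at zero.
    """
    z = np.asarray(z, dtype=float)
    corr = np.asarray(corr, dtype=float)
    t = float(np.sum(z ** 2))
    lam = np.linalg.eigvalsh(corr)
    if lam[0] < -1e-6 * max(1.0, lam[-1]):
        logger.warning("gene %s: correlation matrix not PSD; eigenvalues floored",
                       gene)
    lam = np.clip(lam, 0.0, None)[::-1]
    s1, s2 = float(np.sum(lam)), float(np.sum(lam ** 2))
    if s2 == 0:
        raise ValueError("degenerate correlation matrix (all-zero eigenvalues)")
    c = s2 / s1
    d = s1 * s1 / s2
    p = float(stats.chi2.sf(t / c, d))
    method = "satterthwaite"
    if p < mc_threshold:
        p = _weighted_chi2_sf_mc(t, lam, seed=seed)
        method = "monte_carlo"
    return GeneTest(gene=gene, n_snps=len(z), T=t, eigenvalues=lam,
                    p_gene=p, method=method)


def gene_perm_p(gene_p: float, matched_gene_p: np.ndarray) -> float:
    """Per-gene permutation p against size-matched random genes:
    ``(1 + #{matched p <= gene p}) / (n + 1)``."""
    matched = np.asarray(matched_gene_p, dtype=float)
    return (1.0 + int(np.sum(matched <= gene_p))) / (len(matched) + 1.0)


def gene_set_enrichment(target_gene_p: np.ndarray,
                        draw_gene_p: np.ndarray,
                        alpha: float = 0.05) -> float:
    """Set-level gene enrichment: how often a size-matched random gene set
    has at least as many significant genes as the target set.

    ``draw_gene_p`` is (n_draws, n_genes); returns
    ``(1 + #{draws with >= target count}) / (n_draws + 1)``.
    """
    target_sig = int(np.sum(np.asarray(target_gene_p) < alpha))
    draw_sig = np.sum(np.asarray(draw_gene_p) < alpha, axis=1)
    return (1.0 + int(np.sum(draw_sig >= target_sig))) / (len(draw_sig) + 1.0)


def multiple_testing(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni and Benjamini-Hochberg adjustment of a p-value vector."""
    p = np.asarray(p, dtype=float)
    bonf = np.minimum(1.0, p * len(p))
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return bonf, fdr
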
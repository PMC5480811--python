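"""Gene-locus SNP sets, LD matrices, eigenvectors, blocks and matched nulls.

A gene's SNP set is its genic SNPs plus flanking SNPs within 5 kb of either
gene end that are in LD (r^2 above a threshold) with a genic SNP; an
intergenic index SNP contributes its own 5 kb / LD neighborhood. The first
eigenvector of the within-gene r^2 matrix summarizes LD structure for the
mixed model; contiguous blocks are segmented greedily on the same r^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import HaplotypePanel, logger

__all__ = [
    "GeneLocus",
    "ld_r2",
    "ld_r2_matrix",
    "first_ld_eigenvector",
    "define_ld_blocks",
    "extract_locus_snps",
    "match_random_genes",
]


@dataclass
class GeneLocus:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    snp_index: np.ndarray  # indices into the panel, position-ordered
    snp_ids: np.ndarray
    ld_matrix: np.ndarray  # pairwise r^2 over the SNP set
    first_eigvec: np.ndarray
    block_labels: np.ndarray
    index_snp: str | None = None

    @property
    def n_snps(self) -> int:
        return len(self.snp_index)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def _hap_freqs(h1: np.ndarray, h2: np.ndarray) -> tuple[float, float, float]:
    p1 = float(h1.mean())
    p2 = float(h2.mean())
    p12 = float((h1 & h2).mean())
    return p1, p2, p12


def ld_r2(panel_or_h1, snp_i=None, snp_j=None) -> float:
    """Haplotype-based r^2 between two SNPs: D^2 / (p1 q1 p2 q2).

    Accepts either ``(panel, i, j)`` or two 0/1 haplotype vectors.
    Raises for monomorphic SNPs.
    """
    if isinstance(panel_or_h1, HaplotypePanel):
        h1 = panel_or_h1.hap_matrix[:, snp_i]
        h2 = panel_or_h1.hap_matrix[:, snp_j]
    else:
        h1 = np.asarray(panel_or_h1)
        h2 = np.asarray(snp_i)
    p1, p2, p12 = _hap_freqs(h1 == 1, h2 == 1)
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom == 0:
        raise ValueError("r^2 undefined for a monomorphic SNP")
    d = p12 - p1 * p2
    return float(d * d / denom)


def ld_r2_matrix(hap: np.ndarray) -> np.ndarray:
    """Pairwise haplotype r^2 for the columns of a 0/1 matrix (vectorized)."""
    x = hap.astype(float)
    p = x.mean(axis=0)
    var = p * (1 - p)
    if np.any(var == 0):
        raise ValueError("r^2 matrix undefined with monomorphic SNPs")
    c = (x - p).T @ (x - p) / x.shape[0]
    r2 = (c * c) / np.outer(var, var)
    np.fill_diagonal(r2, 1.0)
    return np.clip(r2, 0.0, 1.0)


def first_ld_eigenvector(ld_matrix: np.ndarray) -> np.ndarray:
    """Unit-norm leading eigenvector with a fixed sign convention.

    The sign makes the largest-magnitude loading positive; an eigenvalue tie
    is broken toward the eigenvector whose largest-magnitude loading sits at
    the lowest index.
    """
    m = np.asarray(ld_matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("LD matrix contains non-finite entries")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("LD matrix must be symmetric")
    w, v = np.linalg.eigh(m)
    top = np.flatnonzero(w >= w[-1] - 1e-9 * max(1.0, abs(w[-1])))
    # tie-break: lowest index of the dominant loading
    best = min(top, key=lambda k: int(np.argmax(np.abs(v[:, k]))))
    vec = v[:, best]
    peak = int(np.argmax(np.abs(vec)))
    if vec[peak] < 0:
        vec = -vec
    return vec / np.linalg.norm(vec)


def define_ld_blocks(ld_matrix: np.ndarray, r2_block: float = 0.7) -> np.ndarray:
    """Greedy contiguous LD-block labels over position-ordered SNPs.

    The current block is extended while the next SNP has r^2 >= ``r2_block``
    with any SNP already in the block; otherwise a new block starts.
    Labels are 0-based and contiguous in position.
    """
    n = ld_matrix.shape[0]
    labels = np.zeros(n, dtype=np.int64)
    block_start = 0
    current = 0
    for i in range(1, n):
        if np.any(ld_matrix[i, block_start:i] >= r2_block):
            labels[i] = current
        else:
            current += 1
            block_start = i
            labels[i] = current
    return labels


def extract_locus_snps(panel: HaplotypePanel, gene: str, start: int, end: int,
                       flank_bp: int = 5_000, r2_link: float = 0.7,
                       index_snp: str | None = None,
                       r2_block: float = 0.7) -> GeneLocus:
    """Resolve a gene's SNP set: genic SNPs plus LD-linked flanking SNPs.

    Genic SNPs (inside the 1-based inclusive interval) are always included.
    A flank SNP within ``flank_bp`` beyond either gene end joins iff its r^2
    with at least one genic SNP exceeds ``r2_link``. When ``index_snp``
    names an intergenic SNP, that SNP and its own ``flank_bp`` neighborhood
    SNPs with r^2 above ``r2_link`` to the index are unioned in.
    """
    pos = panel.positions_bp
    genic = np.flatnonzero((pos >= start) & (pos <= end))
    if len(genic) == 0:
        raise ValueError(f"gene {gene!r} has no SNPs in the panel")
    chosen = set(genic.tolist())

    flank = np.flatnonzero(((pos >= start - flank_bp) & (pos < start))
                           | ((pos > end) & (pos <= end + flank_bp)))
    hap = panel.hap_matrix
    for j in flank:
        r2s = (ld_r2(hap[:, j], hap[:, g]) for g in genic
               if 0 < hap[:, g].mean() < 1)
        if 0 < hap[:, j].mean() < 1 and any(r > r2_link for r in r2s):
            chosen.add(int(j))

    if index_snp is not None:
        idx = panel.snp_index(index_snp)
        chosen.add(idx)
        if not (start <= pos[idx] <= end):  # intergenic index SNP rule
            near = np.flatnonzero(np.abs(pos - pos[idx]) <= flank_bp)
            for j in near:
                if j == idx or not 0 < hap[:, j].mean() < 1:
                    continue
                if 0 < hap[:, idx].mean() < 1 and \
                        ld_r2(hap[:, j], hap[:, idx]) > r2_link:
                    chosen.add(int(j))

    order = np.sort(np.fromiter(chosen, dtype=np.int64))
    # r^2 matrix requires polymorphic members; monomorphic ones are dropped
    freqs = hap[:, order].mean(axis=0)
    order = order[(freqs > 0) & (freqs < 1)]
    ld = ld_r2_matrix(hap[:, order])
    return GeneLocus(
        gene=gene, chrom=panel.chrom, start=start, end=end,
        snp_index=order, snp_ids=panel.snp_ids[order], ld_matrix=ld,
        first_eigvec=first_ld_eigenvector(ld),
        block_labels=define_ld_blocks(ld, r2_block), index_snp=index_snp)


def match_random_genes(target_length_bp: int, annotation: pd.DataFrame, n: int,
                       length_tol: float = 0.2, seed: int = 0,
                       exclude: set[str] | None = None) -> pd.DataFrame:
    """Draw ``n`` genes of similar length (within ``±length_tol`` fraction).

    Sampling is without replacement from ``annotation`` (gene/chrom/start/
    end, 1-based inclusive), excluding named genes. If too few candidates
    exist the tolerance is doubled once, then an error is raised.
    """
    rng = np.random.default_rng(seed)
    exclude = exclude or set()
    lengths = annotation["end"] - annotation["start"] + 1
    for tol in (length_tol, 2 * length_tol):
        lo, hi = target_length_bp * (1 - tol), target_length_bp * (1 + tol)
        ok = annotation[(lengths >= lo) & (lengths <= hi)
                        & ~annotation["gene"].isin(exclude)]
        if len(ok) >= n:
            if tol != length_tol:
                logger.warning("length tolerance widened to ±%.0f%% for matching",
                               100 * tol)
            take = rng.choice(len(ok), size=n, replace=False)
            return ok.iloc[np.sort(take)].reset_index(drop=True)
    raise ValueError(
        f"only {len(ok)} candidate genes within doubled tolerance; need {n}")
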
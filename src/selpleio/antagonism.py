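"""Antagonistic-pleiotropy classification of disease index SNPs.

An antagonistic effect is an allele that significantly increases lifetime
reproductive success (LRS) while also increasing disease risk: such alleles
can persist under selection despite their late-life cost. Before
classification the fitness effect is re-signed onto the GWAS effect allele
(allele harmonization); strand-ambiguous palindromic SNPs are excluded.
Proxy expansion collects high-LD neighbors of an index SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DNA_COMPLEMENT, is_palindromic
from .formats_io import HaplotypePanel

__all__ = ["AlignedPair", "AntagonismCall", "harmonize_alleles",
           "classify_antagonism", "expand_proxies"]


@dataclass
class AlignedPair:
    snp_id: str
    effect_allele: str  # the GWAS effect allele both betas now refer to
    other_allele: str
    cad_lnor: float
    cad_p: float
    lrs_beta: float
    lrs_p: float
    palindromic: bool = False


@dataclass
class AntagonismCall:
    snp_id: str
    effect_allele: str
    lrs_beta: float
    lrs_p: float
    cad_lnor: float
    cad_p: float
    both_significant: bool
    label: str  # "antagonistic" | "concordant" | "not_applicable"


def harmonize_alleles(snp_id: str, gwas_effect: str, gwas_other: str,
                      gwas_lnor: float, gwas_p: float,
                      fit_effect: str, fit_other: str,
                      fit_beta: float, fit_p: float,
                      allow_palindromic: bool = False) -> AlignedPair:
    """Re-sign the fitness beta onto the GWAS effect allele.

    Handles allele swaps (beta negated) and strand flips (alleles
    complemented, then matched). A/T and C/G palindromic SNPs cannot be
    strand-resolved and are flagged for exclusion unless
    ``allow_palindromic``. Incompatible allele pairs raise.
    """
    g1, g2 = gwas_effect.upper(), gwas_other.upper()
    f1, f2 = fit_effect.upper(), fit_other.upper()
    pal = is_palindromic(g1, g2)
    if pal and not allow_palindromic:
        return AlignedPair(snp_id, g1, g2, gwas_lnor, gwas_p,
                           float("nan"), float("nan"), palindromic=True)
    if (f1, f2) == (g1, g2):
        beta = fit_beta
    elif (f1, f2) == (g2, g1):
        beta = -fit_beta
    else:
        c1 = DNA_COMPLEMENT.get(f1, "?")
        c2 = DNA_COMPLEMENT.get(f2, "?")
        if (c1, c2) == (g1, g2):
            beta = fit_beta
        elif (c1, c2) == (g2, g1):
            beta = -fit_beta
        else:
            raise ValueError(
                f"incompatible alleles for {snp_id}: GWAS {g1}/{g2} vs "
                f"fitness {f1}/{f2}")
    return AlignedPair(snp_id, g1, g2, gwas_lnor, gwas_p, beta, fit_p,
                       palindromic=pal)


def classify_antagonism(pair: AlignedPair, alpha: float = 0.05,
                        is_index_snp: bool = True) -> AntagonismCall:
    """Label a harmonized SNP antagonistic, concordant, or not applicable.

    The significance gate is asymmetric: the fitness side needs nominal
    ``lrs_p < alpha`` while the disease side requires membership in the
    supplied genome-wide-significant index-SNP list. A both-significant SNP
    is antagonistic when the same allele pushes LRS and disease risk in the
    same direction (both betas positive, or both negative, after
    alignment); otherwise concordant (the allele that helps reproduction
    also lowers risk).
    """
    both = bool(is_index_snp and np.isfinite(pair.lrs_p) and pair.lrs_p < alpha)
    if not both:
        label = "not_applicable"
    elif np.sign(pair.lrs_beta) == np.sign(pair.cad_lnor):
        label = "antagonistic"
    else:
        label = "concordant"
    return AntagonismCall(
        snp_id=pair.snp_id, effect_allele=pair.effect_allele,
        lrs_beta=pair.lrs_beta, lrs_p=pair.lrs_p,
        cad_lnor=pair.cad_lnor, cad_p=pair.cad_p,
        both_significant=both, label=label)


def expand_proxies(panel: HaplotypePanel, index_snp: str,
                   r2_min: float = 0.8, window_bp: int = 1_000_000) -> list[str]:
    """High-LD proxy set of an index SNP: all SNPs within ``window_bp``
    with r^2 >= ``r2_min`` to the index (index included)."""
    from .locus_mapping import ld_r2

    idx = panel.snp_index(index_snp)
    pos = panel.positions_bp
    out = [str(panel.snp_ids[idx])]
    hap_i = panel.hap_matrix[:, idx]
    if not 0 < hap_i.mean() < 1:
        return out
    for j in np.flatnonzero(np.abs(pos - pos[idx]) <= window_bp):
        if j == idx or not 0 < panel.hap_matrix[:, j].mean() < 1:
            continue
        if ld_r2(hap_i, panel.hap_matrix[:, j]) >= r2_min:
            out.append(str(panel.snp_ids[j]))
    return out
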
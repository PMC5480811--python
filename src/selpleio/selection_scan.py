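"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

EHH at marker *m* for a core allele is the probability that two randomly
chosen carrier haplotypes are identical at every marker between the core SNP
and *m*:

    EHH(m) = sum_h C(n_h, 2) / C(n_c, 2)

over the distinct extended haplotypes *h* among the ``n_c`` carriers. iHH is
the trapezoid integral of EHH over genetic distance in both directions from
the core, truncated at the last marker with EHH at or above a cutoff;
``iHS_raw = ln(iHH_A / iHH_D)`` contrasts the ancestral and derived cores.
Raw scores are standardized empirically within derived-allele-frequency bins
and permutation p-values are drawn from the same frequency classes.

Haplotype grouping walks outward refining a prefix partition (linear in
markers); the brute-force pairwise definition is retained only as a test
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import HaplotypePanel, logger

__all__ = [
    "EhhCurve",
    "ehh_curve",
    "integrate_ihh",
    "ihs_scan",
    "standardize_ihs",
    "permute_ihs_p",
    "call_candidate_signals",
]

SCORE_COLUMNS = ["snp_id", "chrom", "pos_bp", "daf", "ihh_a", "ihh_d",
                 "ihs_raw", "reason"]


@dataclass
class EhhCurve:
    """EHH decay in one direction from a core SNP."""

    core_snp: str
    core_allele: str  # "ancestral" | "derived"
    direction: str  # "left" | "right"
    dist_cM: np.ndarray  # genetic distance from the core, starting at 0
    ehh: np.ndarray  # EHH values, ehh[0] == 1
    pos_bp: np.ndarray  # physical positions of the points (core first)
    reached_end: bool  # ran out of chromosome with EHH still >= cutoff


def _partition_walk(hap: np.ndarray, carriers: np.ndarray, marker_order: np.ndarray):
    """Yield (marker, EHH) walking outward, refining the carrier partition.

    Haplotypes in singleton groups are pruned as they can no longer pair.
    """
    n_c = len(carriers)
    pairs_total = n_c * (n_c - 1) / 2.0
    active = carriers.copy()
    gid = np.zeros(len(active), dtype=np.int64)
    for m in marker_order:
        if len(active) < 2:
            yield m, 0.0
            continue
        key = gid * 2 + hap[active, m]
        _, gid, counts = np.unique(key, return_inverse=True, return_counts=True)
        ehh = float(np.sum(counts * (counts - 1)) / 2.0 / pairs_total)
        yield m, ehh
        keep = counts[gid] > 1
        active = active[keep]
        gid = gid[keep]


def ehh_curve(panel: HaplotypePanel, core_snp: int | str, core_allele: str,
              direction: str, cutoff: float = 0.05) -> EhhCurve:
    """EHH decay curve from a core SNP out to one side.

    The curve runs to the first marker where EHH drops below ``cutoff``
    (that marker included) or to the chromosome end. Distances come from the
    panel's genetic map. Raises if fewer than two haplotypes carry the core
    allele.
    """
    core = panel.snp_index(core_snp) if isinstance(core_snp, str) else int(core_snp)
    if core_allele not in ("ancestral", "derived"):
        raise ValueError("core_allele must be 'ancestral' or 'derived'")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    target = 1 if core_allele == "derived" else 0
    carriers = np.flatnonzero(panel.hap_matrix[:, core] == target)
    if len(carriers) < 2:
        raise ValueError(
            f"EHH undefined: {len(carriers)} haplotype(s) carry the "
            f"{core_allele} allele at {panel.snp_ids[core]}")

    if direction == "right":
        order = np.arange(core + 1, panel.n_snps)
    else:
        order = np.arange(core - 1, -1, -1)

    dists = [0.0]
    ehhs = [1.0]
    pos = [int(panel.positions_bp[core])]
    reached_end = True
    for m, e in _partition_walk(panel.hap_matrix, carriers, order):
        dists.append(abs(panel.genetic_pos_cM[m] - panel.genetic_pos_cM[core]))
        ehhs.append(e)
        pos.append(int(panel.positions_bp[m]))
        if e < cutoff:
            reached_end = False
            break
    return EhhCurve(
        core_snp=str(panel.snp_ids[core]), core_allele=core_allele,
        direction=direction, dist_cM=np.asarray(dists), ehh=np.asarray(ehhs),
        pos_bp=np.asarray(pos, dtype=np.int64), reached_end=reached_end)


def _one_side_area(curve: EhhCurve, cutoff: float, max_gap_bp: int) -> float:
    """Truncated trapezoid area for one direction; NaN when undefined."""
    if len(curve.ehh) == 0:
        raise ValueError("empty EHH curve")
    if curve.reached_end:
        return float("nan")  # chromosome end hit with EHH still >= cutoff
    keep = curve.ehh >= cutoff
    # points are orderd core-outward; truncate at last point >= cutoff
    last = np.flatnonzero(keep)
    last = int(last[-1]) if len(last) else 0
    if np.any(np.abs(np.diff(curve.pos_bp[: last + 1])) > max_gap_bp):
        return float("nan")
    d = curve.dist_cM[: last + 1]
    e = curve.ehh[: last + 1]
    if len(d) < 2:
        return 0.0
    return float(np.trapezoid(e, d))


def integrate_ihh(curve_left: EhhCurve, curve_right: EhhCurve,
                  cutoff: float = 0.05, max_gap_bp: int = 200_000) -> float:
    """Integrated EHH (both directions), truncated at the cutoff.

    Returns NaN when either direction reaches the chromosome end before EHH
    falls below ``cutoff`` or when adjacent used markers are further apart
    than ``max_gap_bp``.
    """
    if (curve_left.core_snp != curve_right.core_snp
            or curve_left.core_allele != curve_right.core_allele):
        raise ValueError("left/right curves must share core SNP and allele")
    a = _one_side_area(curve_left, cutoff, max_gap_bp)
    b = _one_side_area(curve_right, cutoff, max_gap_bp)
    return a + b


def _walk_side_slow(panel: HaplotypePanel, j: int, allele: str, direction: str,
                    cutoff: float, max_gap_bp: int) -> float:
    return _one_side_area(ehh_curve(panel, j, allele, direction, cutoff),
                          cutoff, max_gap_bp)


def ihs_scan(panel: HaplotypePanel, cutoff: float = 0.05,
             max_gap_bp: int = 200_000, maf_min: float = 0.05) -> pd.DataFrame:
    """Raw iHS for every SNP with MAF >= ``maf_min`` and defined iHH.

    Per-SNP failures are flagged with a reason code instead of raising:
    ``maf`` (below the frequency floor), ``edge`` (EHH still above the
    cutoff at a chromosome end), ``gap`` (markers further apart than
    ``max_gap_bp``), ``carriers`` (fewer than two carriers of one allele).

    The inner haplotype-partition walk is a compiled kernel; it computes
    the same truncated trapezoid areas as :func:`ehh_curve` +
    :func:`integrate_ihh` (asserted against them in the test suite).
    """
    daf = panel.daf()
    n = panel.n_snps
    ihh_a, ihh_d, codes = _scan_kernel(
        np.ascontiguousarray(panel.hap_matrix),
        np.ascontiguousarray(panel.genetic_pos_cM),
        np.ascontiguousarray(panel.positions_bp),
        float(cutoff), np.int64(max_gap_bp), float(maf_min))
    code_names = {0: "", 1: "maf", 2: "edge", 3: "gap", 4: "carriers"}
    reason = np.array([code_names[int(c)] for c in codes], dtype=object)

    with np.errstate(divide="ignore", invalid="ignore"):
        ihs_raw = np.log(ihh_a / ihh_d)
    bad = np.isfinite(ihh_a) & np.isfinite(ihh_d) & ~np.isfinite(ihs_raw)
    reason[bad] = "zero_ihh"
    ihs_raw[bad] = np.nan
    ihh_a[codes != 0] = np.nan
    ihh_d[codes != 0] = np.nan
    ihs_raw[codes != 0] = np.nan
    return pd.DataFrame({
        "snp_id": panel.snp_ids, "chrom": panel.chrom,
        "pos_bp": panel.positions_bp, "daf": daf,
        "ihh_a": ihh_a, "ihh_d": ihh_d, "ihs_raw": ihs_raw, "reason": reason,
    })


def _build_scan_kernel():
    from numba import njit

    @njit(fastmath=False)
    def _side_area(hap, gpos, pos, core, target, step, cutoff, max_gap_bp):
        """Truncated trapezoid iHH for one core allele and direction.

        Returns (area, code): code 0 = ok, 2 = chromosome end with EHH
        still >= cutoff, 3 = marker gap exceeded.
        """
        n_haps, n_snps = hap.shape
        n_c = 0
        for h in range(n_haps):
            if hap[h, core] == target:
                n_c += 1
        active = np.empty(n_c, dtype=np.int64)
        k = 0
        for h in range(n_haps):
            if hap[h, core] == target:
                active[k] = h
                k += 1
        pairs_total = n_c * (n_c - 1) / 2.0
        gid = np.zeros(n_c, dtype=np.int64)
        n_groups = 1
        n_active = n_c
        prev_ehh = 1.0
        prev_g = 0.0  # genetic distance from the core
        prev_pos = pos[core]
        area = 0.0
        m = core + step
        while 0 <= m < n_snps:
            if n_active < 2:
                return area, 0  # EHH hit 0 (< cutoff); truncate here
            # refine partition by the allele at m
            counts = np.zeros(2 * n_groups, dtype=np.int64)
            keys = np.empty(n_active, dtype=np.int64)
            for i in range(n_active):
                key = gid[i] * 2 + hap[active[i], m]
                keys[i] = key
                counts[key] += 1
            # compact relabel + pair count
            remap = np.full(2 * n_groups, -1, dtype=np.int64)
            pair_sum = 0
            ng = 0
            for key in range(2 * n_groups):
                c = counts[key]
                if c > 0:
                    remap[key] = ng
                    ng += 1
                    pair_sum += c * (c - 1)
            ehh = pair_sum / 2.0 / pairs_total
            if ehh < cutoff:
                return area, 0
            # marker is used: the inter-marker gap rule applies
            if abs(pos[m] - prev_pos) > max_gap_bp:
                return 0.0, 3
            g = abs(gpos[m] - gpos[core])
            area += 0.5 * (prev_ehh + ehh) * (g - prev_g)
            prev_ehh = ehh
            prev_g = g
            prev_pos = pos[m]
            # prune singleton groups; keep compact ids for survivors
            keep_n = 0
            for i in range(n_active):
                if counts[keys[i]] > 1:
                    active[keep_n] = active[i]
                    gid[keep_n] = remap[keys[i]]
                    keep_n += 1
            n_active = keep_n
            n_groups = ng
            m += step
        return area, 2  # ran off the chromosome with EHH >= cutoff

    @njit(fastmath=False)
    def _scan(hap, gpos, pos, cutoff, max_gap_bp, maf_min):
        n_haps, n_snps = hap.shape
        ihh_a = np.full(n_snps, np.nan)
        ihh_d = np.full(n_snps, np.nan)
        codes = np.zeros(n_snps, dtype=np.int8)
        for j in range(n_snps):
            nd = 0
            for h in range(n_haps):
                nd += hap[h, j]
            daf = nd / n_haps
            maf = daf if daf < 0.5 else 1.0 - daf
            if maf < maf_min:
                codes[j] = 1
                continue
            if nd < 2 or n_haps - nd < 2:
                codes[j] = 4
                continue
            code = 0
            a_area = 0.0
            d_area = 0.0
            for t in range(2):
                left, cl = _side_area(hap, gpos, pos, j, t, -1, cutoff, max_gap_bp)
                right, cr = _side_area(hap, gpos, pos, j, t, 1, cutoff, max_gap_bp)
                c = max(cl, cr)
                if c > code:
                    code = c
                if t == 0:
                    a_area = left + right
                else:
                    d_area = left + right
            if code != 0:
                codes[j] = code
                continue
            ihh_a[j] = a_area
            ihh_d[j] = d_area
        return ihh_a, ihh_d, codes

    return _scan


_scan_kernel = _build_scan_kernel()


def standardize_ihs(scores: pd.DataFrame, bin_width: float = 0.025) -> pd.DataFrame:
    """Standardize raw iHS empirically within derived-allele-frequency bins.

    Adds ``daf_bin``, ``ihs_std`` (mean 0, sample SD 1 within each bin) and
    ``nominal_p`` (two-sided standard-normal tail). Bins holding fewer than
    two defined scores, or with zero spread, are flagged undefined.
    """
    out = scores.copy()
    out["daf_bin"] = np.minimum((out["daf"] / bin_width).astype(int),
                                int(1.0 / bin_width) - 1)
    out["ihs_std"] = np.nan
    defined = out["ihs_raw"].notna()
    for b, idx in out.index[defined].groupby(out.loc[defined, "daf_bin"]).items():
        vals = out.loc[idx, "ihs_raw"].to_numpy()
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            out.loc[idx, "reason"] = "bin"
            logger.warning("DAF bin %s has %d usable score(s); flagged undefined",
                           b, len(vals))
            continue
        out.loc[idx, "ihs_std"] = (vals - vals.mean()) / np.std(vals, ddof=1)
    out["nominal_p"] = 2.0 * stats.norm.sf(np.abs(out["ihs_std"]))
    return out


def permute_ihs_p(scores: pd.DataFrame, n_perm: int = 10_000,
                  seed: int = 0, min_class_size: int = 10) -> pd.DataFrame:
    """Permutation p-values from resampling within DAF classes.

    For each scored SNP, ``n_perm`` standardized scores are drawn uniformly
    with replacement from its derived-allele-frequency class (the scored
    genome-wide pool); ``permuted_p = (1 + #{|draw| >= |target|}) /
    (n_perm + 1)``. Classes smaller than ``min_class_size`` are widened to
    their immediate neighbor bins.
    """
    rng = np.random.default_rng(seed)
    out = scores.copy()
    out["permuted_p"] = np.nan
    defined = out["ihs_std"].notna()
    bins = out.loc[defined, "daf_bin"]
    abs_std = np.abs(out["ihs_std"].to_numpy())
    for b in sorted(bins.unique()):
        members = out.index[defined & (out["daf_bin"] == b)]
        pool_bins = [b]
        pool = members
        while len(pool) < min_class_size:
            pool_bins = [min(pool_bins) - 1, *pool_bins, max(pool_bins) + 1]
            pool = out.index[defined & out["daf_bin"].isin(pool_bins)]
            if min(pool_bins) < 0 and max(pool_bins) > bins.max():
                break
        if len(pool_bins) > 1:
            logger.warning("DAF class %d widened to bins %s (had %d SNPs)",
                           b, pool_bins, len(members))
        pool_pos = out.index.get_indexer(pool)
        pool_vals = abs_std[pool_pos]
        member_pos = out.index.get_indexer(members)
        targets = abs_std[member_pos]
        # each target draws from its class excluding itself
        self_idx = np.searchsorted(pool_pos, member_pos)
        counts = np.empty(len(members), dtype=np.int64)
        chunk = max(1, int(4e6 // max(n_perm, 1)))
        for lo in range(0, len(members), chunk):
            hi = min(lo + chunk, len(members))
            idx = rng.integers(0, len(pool_vals) - 1, size=(hi - lo, n_perm))
            idx = idx + (idx >= self_idx[lo:hi, None])
            draws = pool_vals[idx]
            counts[lo:hi] = (draws >= targets[lo:hi, None]).sum(axis=1)
        out.loc[members, "permuted_p"] = (1.0 + counts) / (n_perm + 1.0)
    return out


def call_candidate_signals(scores: pd.DataFrame, gene_loci,
                           ihs_min: float = 2.0, p_max: float = 0.05,
                           cluster_k: int = 2,
                           cluster_window_bp: int = 50_000,
                           population: str = "") -> pd.DataFrame:
    """Candidate selection signals per gene (peaks of elevated |iHS|).

    A SNP is a candidate when |iHS| > ``ihs_min``, its permutation p is
    below ``p_max``, and at least ``cluster_k`` *other* SNPs within
    ``cluster_window_bp`` also have |iHS| > ``ihs_min`` (the cluster rule).
    Candidates are grouped into signals by window adjacency; the apex is the
    member with the largest |iHS| and sets the magnitude class
    (``2-3``, ``3-4``, ``>4``).

    ``gene_loci`` maps gene name -> iterable of member snp_ids (a
    ``GeneLocus`` list from locus mapping also works).
    """
    if not isinstance(gene_loci, dict):
        gene_loci = {loc.gene: loc for loc in gene_loci}
    gene_loci = {g: (list(v.snp_ids) if hasattr(v, "snp_ids") else list(v))
                 for g, v in gene_loci.items()}
    pos_all = scores["pos_bp"].to_numpy()
    abs_all = np.abs(scores["ihs_std"].to_numpy())
    elevated_pos = pos_all[np.nan_to_num(abs_all) > ihs_min]

    records = []
    for gene, snp_ids in gene_loci.items():
        sub = scores[scores["snp_id"].isin(set(snp_ids))]
        sub = sub[sub["ihs_std"].notna()]
        if sub.empty:
            continue
        abs_ihs = np.abs(sub["ihs_std"].to_numpy())
        pos = sub["pos_bp"].to_numpy()
        perm = sub["permuted_p"].to_numpy()
        # cluster support counts genome-wide elevated SNPs, excluding self
        support = np.array([
            np.sum(np.abs(elevated_pos - p) <= cluster_window_bp) for p in pos])
        self_elevated = abs_ihs > ihs_min
        support = support - self_elevated.astype(int)
        is_cand = self_elevated & (perm < p_max) & (support >= cluster_k)
        if not is_cand.any():
            continue
        cand_order = np.argsort(pos[is_cand])
        cpos = pos[is_cand][cand_order]
        cabs = abs_ihs[is_cand][cand_order]
        cperm = perm[is_cand][cand_order]
        cids = sub["snp_id"].to_numpy()[is_cand][cand_order]
        breaks = np.flatnonzero(np.diff(cpos) > cluster_window_bp)
        groups = np.split(np.arange(len(cpos)), breaks + 1)
        for g in groups:
            apex = g[np.argmax(cabs[g])]
            apex_val = float(cabs[apex])
            cls = "2-3" if apex_val <= 3 else ("3-4" if apex_val <= 4 else ">4")
            records.append({
                "gene": gene, "population": population,
                "n_members": len(g),
                "member_snps": ",".join(cids[g]),
                "apex_snp": cids[apex], "apex_abs_ihs": apex_val,
                "apex_pos_bp": int(cpos[apex]),
                "permuted_p": float(cperm[apex]),
                "magnitude_class": cls,
            })
    return pd.DataFrame(records, columns=[
        "gene", "population", "n_members", "member_snps", "apex_snp",
        "apex_abs_ihs", "apex_pos_bp", "permuted_p", "magnitude_class"])
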
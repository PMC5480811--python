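"""End-to-end orchestration: simulate -> scan -> associate -> eqtl ->
fitness -> antagonism -> report, with a reproducibility manifest.

Each stage is a plain function over in-memory objects and result tables;
``run_pipeline`` wires them together from a :class:`RunConfig`, persists
every intermediate table, and records seeds and output hashes in a JSON
manifest. Stage seeds are expanded from the single global seed by a fixed
counter scheme (``seed * 1000 + stage_index``, mod 2^31), so any stage can
be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .antagonism import classify_antagonism, harmonize_alleles
from .eqtl_scan import compare_selected_vs_random, fit_eqtl, permute_eqtl
from .fitness_enrichment import (COVARIATE_COLUMNS, adjust_lrs, compute_grm,
                                 gene_based_test, gene_perm_p,
                                 gene_set_enrichment, lmm_assoc,
                                 multiple_testing, permute_snp_p,
                                 set_enrichment_test)
from .formats_io import (HaplotypePanel, RunConfig, apply_qc_filters, logger,
                         read_expression, read_gene_bed, read_gwas_summary,
                         read_phased_vcf, read_phenotypes, write_results)
from .locus_mapping import GeneLocus, extract_locus_snps, match_random_genes
from .risk_selection import (fit_selection_risk_model, gene_matched_null,
                             permute_association, rank_genes)
from .selection_scan import (call_candidate_signals, ihs_scan, permute_ihs_p,
                             standardize_ihs)
from .synthetic_data import write_fixture_bundle

__all__ = ["RunManifest", "run_pipeline", "stage_seed"]

STAGES = ["simulate", "scan", "associate", "eqtl", "fitness", "antagonism",
          "report"]


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1000 + STAGES.index(stage)) % (2 ** 31)


@dataclass
class RunManifest:
    config: dict
    version: str
    global_seed: int
    stages: list[dict] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def record(self, name: str, seed: int | None, outputs: list[Path]) -> None:
        self.stages.append({
            "stage": name,
            "seed": seed,
            "outputs": {p.name: _sha256(p) for p in outputs},
        })

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def scan_panel(panel: HaplotypePanel, config: RunConfig, seed: int) -> pd.DataFrame:
    scores = ihs_scan(panel, cutoff=config.ehh_cutoff,
                      max_gap_bp=config.max_gap_bp, maf_min=config.ihs_maf_min)
    scores = standardize_ihs(scores, bin_width=config.daf_bin_width)
    return permute_ihs_p(scores, n_perm=config.n_perm_ihs, seed=seed)


def build_loci(panel: HaplotypePanel, genes: pd.DataFrame,
               config: RunConfig) -> dict[str, GeneLocus]:
    loci = {}
    for _, row in genes.iterrows():
        try:
            loci[row.gene] = extract_locus_snps(
                panel, row.gene, int(row.start), int(row.end),
                flank_bp=config.flank_bp, r2_link=config.r2_link,
                r2_block=config.r2_block)
        except ValueError as err:
            logger.warning("locus %s skipped: %s", row.gene, err)
    return loci


def random_interval_annotation(panel: HaplotypePanel, length_bp: int,
                               n_candidates: int, seed: int) -> pd.DataFrame:
    """Random same-chromosome intervals used as the null-gene annotation on
    simulated data (a stand-in for a genome-wide gene annotation)."""
    rng = np.random.default_rng(seed)
    span_lo = int(panel.positions_bp[0])
    span_hi = int(panel.positions_bp[-1]) - length_bp
    if span_hi <= span_lo:
        raise ValueError("panel span shorter than requested interval length")
    starts = rng.integers(span_lo, span_hi, size=n_candidates)
    return pd.DataFrame({
        "gene": [f"null_{i}" for i in range(n_candidates)],
        "chrom": panel.chrom,
        "start": starts,
        "end": starts + length_bp - 1,
    })


def _gene_model_inputs(locus: GeneLocus, scores: pd.DataFrame,
                       gwas: pd.DataFrame):
    sc = scores.set_index("snp_id")
    gw = gwas.set_index("snp_id")
    ids = [s for s in locus.snp_ids if s in sc.index and s in gw.index]
    if len(ids) < 3:
        return None
    mask = np.isin(locus.snp_ids, ids)
    return (gw.loc[ids, "ln_or"].to_numpy(),
            sc.loc[ids, "ihs_std"].to_numpy(),
            locus.first_eigvec[mask])


def associate_genes(panel: HaplotypePanel, scores: pd.DataFrame,
                    gwas: pd.DataFrame, loci: dict[str, GeneLocus],
                    config: RunConfig, seed: int,
                    population: str = "") -> pd.DataFrame:
    """Fit the selection-risk mixed model per gene with both permutation
    nulls (iHS shuffling; length-matched random genes)."""
    rows = []
    for k, (gene, locus) in enumerate(sorted(loci.items())):
        inputs = _gene_model_inputs(locus, scores, gwas)
        if inputs is None:
            logger.warning("gene %s: fewer than 3 usable SNPs; skipped", gene)
            continue
        ln_or, ihs, v = inputs
        try:
            beta, nominal_p, fit = fit_selection_risk_model(ln_or, ihs, v)
        except ValueError as err:
            logger.warning("gene %s unfittable: %s", gene, err)
            continue
        _, perm_p = permute_association(ln_or, ihs, v,
                                        n_perm=config.n_perm_assoc,
                                        seed=seed + 13 * k)
        # length-matched null genes drawn from random intervals
        perm_p_genes = np.nan
        if np.isfinite(nominal_p):
            try:
                annot = random_interval_annotation(
                    panel, locus.length_bp,
                    n_candidates=max(4 * config.n_null_genes, 40),
                    seed=seed + 977 * k)
                matched = match_random_genes(locus.length_bp, annot,
                                             n=config.n_null_genes,
                                             length_tol=config.length_tol,
                                             seed=seed + 977 * k + 1)
                null_inputs = []
                for _, nr in matched.iterrows():
                    try:
                        nloc = extract_locus_snps(
                            panel, nr.gene, int(nr.start), int(nr.end),
                            flank_bp=config.flank_bp, r2_link=config.r2_link)
                    except ValueError:
                        continue
                    ni = _gene_model_inputs(nloc, scores, gwas)
                    if ni is not None:
                        null_inputs.append(ni)
                perm_p_genes = gene_matched_null(nominal_p, null_inputs)
            except ValueError as err:
                logger.warning("gene %s: matched-null unavailable (%s)", gene, err)
        rows.append({
            "gene": gene, "population": population,
            "n_snps": int(np.sum(np.isfinite(np.asarray(ihs, dtype=float)))),
            "beta_scaled": beta, "nominal_p": nominal_p,
            "perm_p_shuffle": perm_p, "perm_p_genes": perm_p_genes,
            "significant": bool(perm_p < 0.05) if np.isfinite(perm_p) else False,
        })
    return pd.DataFrame(rows)


def eqtl_stage(panel: HaplotypePanel, expr, sex: np.ndarray,
               signals: pd.DataFrame, loci: dict[str, GeneLocus],
               config: RunConfig, seed: int):
    """Permuted eQTL p for every SNP of every probed gene, then the
    selected-vs-random KS comparison (None when too few signals)."""
    gene_probe = {g: p for p, g in expr.gene_links.items()}
    dosage = panel.dosage()
    expr_vals = expr.values[panel.sample_ids]
    eqtl_rows = []
    eqtl_p: dict[str, float] = {}
    snp_blocks: dict[str, tuple[str, int]] = {}
    for gene, locus in sorted(loci.items()):
        probe = gene_probe.get(gene)
        if probe is None:
            continue
        y = expr_vals.loc[probe].to_numpy()
        for j, sid in zip(locus.snp_index, locus.snp_ids):
            snp_blocks[str(sid)] = (gene, int(locus.block_labels[
                int(np.flatnonzero(locus.snp_index == j)[0])]))
            try:
                beta, nominal = fit_eqtl(dosage[:, j], sex, y)
            except ValueError:
                continue
            perm = permute_eqtl(dosage[:, j], sex, y,
                                n_perm=config.n_perm_eqtl,
                                seed=seed + (int(j) % 99991))
            eqtl_p[str(sid)] = perm
            eqtl_rows.append({"snp_id": sid, "probe_id": probe, "gene": gene,
                              "beta": beta, "nominal_p": nominal,
                              "permuted_p": perm})
    table = pd.DataFrame(eqtl_rows)
    apex = [s for s in signals["apex_snp"] if s in eqtl_p]
    comparison = None
    if len(apex) >= 5:
        try:
            comparison = compare_selected_vs_random(eqtl_p, apex, snp_blocks,
                                                    seed=seed + 1)
        except ValueError as err:
            logger.warning("eQTL comparison skipped: %s", err)
    else:
        logger.info("eQTL comparison skipped: %d apex SNPs with results",
                    len(apex))
    return table, comparison


def fitness_stage(panel: HaplotypePanel, phenotypes: pd.DataFrame,
                  genes: pd.DataFrame, loci: dict[str, GeneLocus],
                  config: RunConfig, seed: int) -> dict:
    """Adjusted-LRS mixed-model associations plus the enrichment battery."""
    pheno = adjust_lrs(phenotypes, n_groups=config.n_birth_groups)
    pheno = pheno.set_index("sample_id").loc[panel.sample_ids].reset_index()
    intervals = [(int(r.start), int(r.end)) for _, r in genes.iterrows()]
    grm = compute_grm(panel, prune_r2=config.prune_r2,
                      exclude_intervals=intervals,
                      excl_window_bp=config.grm_excl_window_bp,
                      r2_excl=config.r2_excl, min_snps=30)
    assoc = lmm_assoc(pheno["lrs_adjusted"].to_numpy(),
                      pheno[COVARIATE_COLUMNS], grm, panel.dosage(),
                      snp_ids=panel.snp_ids)
    assoc["pos_bp"] = panel.positions_bp
    gene_snp_ids = sorted({str(s) for loc in loci.values() for s in loc.snp_ids})
    in_set = assoc["snp_id"].isin(gene_snp_ids)
    target, pool = assoc[in_set], assoc[~in_set]
    assoc["permuted_p"] = np.nan
    if len(pool) >= 100:
        assoc.loc[in_set, "permuted_p"] = permute_snp_p(
            target["nominal_p"].to_numpy(), target["maf"].to_numpy(),
            pool["nominal_p"].to_numpy(), pool["maf"].to_numpy(),
            n_perm=config.n_perm_snp, maf_bin=config.maf_bin_width,
            seed=seed)
    bonf, fdr = multiple_testing(assoc["nominal_p"].to_numpy())
    assoc["p_bonferroni"], assoc["p_fdr_bh"] = bonf, fdr

    enrichment = None
    if len(pool) >= 10 * max(len(target), 1) // 10 and len(pool) >= 100:
        enrichment = set_enrichment_test(
            target["nominal_p"].to_numpy(), target["maf"].to_numpy(),
            pool["nominal_p"].to_numpy(), pool["maf"].to_numpy(),
            n_draws=config.n_set_draws, maf_bin=config.maf_bin_width,
            seed=seed + 1)

    # gene-based sum-of-chi-squares tests with size-matched permutation
    dosage = panel.dosage()
    z_all = (assoc["beta"] / assoc["se"]).to_numpy()
    by_id = dict(zip(assoc["snp_id"], z_all))

    def interval_test(name: str, start: int, end: int):
        mask = (panel.positions_bp >= start) & (panel.positions_bp <= end)
        idx = np.flatnonzero(mask)
        if len(idx) < 2:
            return None
        z = np.array([by_id[str(panel.snp_ids[j])] for j in idx])
        corr = np.corrcoef(dosage[:, idx], rowvar=False)
        return gene_based_test(z[np.isfinite(z)], corr, gene=name,
                               seed=seed + 2)

    gene_tests = []
    null_gene_p: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed + 3)
    for _, row in genes.iterrows():
        gt = interval_test(row.gene, int(row.start), int(row.end))
        if gt is None:
            continue
        length = int(row.end - row.start + 1)
        matched_p = []
        annot = random_interval_annotation(panel, length,
                                           n_candidates=4 * config.n_gene_perm,
                                           seed=int(rng.integers(2 ** 31)))
        for _, nr in annot.iterrows():
            if len(matched_p) >= config.n_gene_perm:
                break
            nt = interval_test(nr.gene, int(nr.start), int(nr.end))
            if nt is not None:
                matched_p.append(nt.p_gene)
        if matched_p:
            gt.perm_p_gene = gene_perm_p(gt.p_gene, np.asarray(matched_p))
            null_gene_p[row.gene] = np.asarray(matched_p)
        gene_tests.append(gt)

    set_perm_p = np.nan
    if gene_tests and null_gene_p:
        n_draws = min(config.n_gene_set_draws,
                      min(len(v) for v in null_gene_p.values()))
        draws = np.column_stack([
            rng.choice(null_gene_p[g.gene], size=n_draws, replace=True)
            for g in gene_tests if g.gene in null_gene_p])
        set_perm_p = gene_set_enrichment(
            np.array([g.p_gene for g in gene_tests]), draws)

    gene_table = pd.DataFrame([{
        "gene": g.gene, "n_snps": g.n_snps, "T": g.T, "p_gene": g.p_gene,
        "method": g.method, "perm_p_gene": g.perm_p_gene,
    } for g in gene_tests])
    return {"snp_assoc": assoc, "gene_tests": gene_table,
            "enrichment": enrichment, "gene_set_perm_p": set_perm_p,
            "grm": grm, "phenotypes": pheno}


def antagonism_stage(gwas: pd.DataFrame, snp_assoc: pd.DataFrame,
                     index_snps: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Cross-reference disease index SNPs with fitness associations."""
    gw = gwas.set_index("snp_id")
    fit = snp_assoc.set_index("snp_id")
    rows = []
    for sid in index_snps:
        if sid not in gw.index or sid not in fit.index:
            continue
        g = gw.loc[sid]
        f = fit.loc[sid]
        try:
            pair = harmonize_alleles(sid, g.effect_allele, g.other_allele,
                                     g.ln_or, g.p, g.effect_allele,
                                     g.other_allele, f.beta, f.nominal_p)
        except ValueError as err:
            logger.warning("%s", err)
            continue
        if pair.palindromic:
            logger.info("palindromic index SNP %s excluded", sid)
            continue
        call = classify_antagonism(pair, alpha=alpha, is_index_snp=True)
        rows.append(dataclasses.asdict(call))
    return pd.DataFrame(rows, columns=[
        "snp_id", "effect_allele", "lrs_beta", "lrs_p", "cad_lnor", "cad_p",
        "both_significant", "label"])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, work_dir: str | Path) -> RunManifest:
    """Execute every stage on a fixture bundle (generated when the config
    carries no input paths); persists tables and returns the manifest."""
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config),
                           version=_pkg_version(), global_seed=config.seed,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    paths = dict(config.paths)
    if not paths:
        in_dir = work_dir / "input"
        write_fixture_bundle(in_dir, seed=stage_seed(config.seed, "simulate"))
        paths = {k: str(in_dir / v) for k, v in {
            "vcf": "panel.vcf", "genes": "genes.bed", "gwas": "gwas.tsv",
            "expression": "expression.tsv", "probe_genes": "probe_genes.tsv",
            "phenotypes": "phenotypes.tsv"}.items()}
        manifest.record("simulate", stage_seed(config.seed, "simulate"),
                        sorted(in_dir.glob("*")))
    else:
        manifest.record("simulate", None, [])

    population = config.populations[0] if config.populations else ""
    panel = read_phased_vcf(paths["vcf"], population_label=population)
    panel, _ = apply_qc_filters(panel, config.call_rate_min,
                                config.hwe_p_min, config.maf_min)
    genes = read_gene_bed(paths["genes"])
    gwas = read_gwas_summary(paths["gwas"])

    seed_scan = stage_seed(config.seed, "scan")
    scores = scan_panel(panel, config, seed_scan)
    loci = build_loci(panel, genes, config)
    signals = call_candidate_signals(
        scores, loci, ihs_min=config.ihs_candidate_min,
        p_max=config.candidate_p_max, cluster_k=config.cluster_k,
        cluster_window_bp=config.cluster_window_bp, population=population)
    out = write_results({"scores": scores, "signals": signals}, work_dir)
    manifest.record("scan", seed_scan, out)

    seed_assoc = stage_seed(config.seed, "associate")
    assoc = associate_genes(panel, scores, gwas, loci, config, seed_assoc,
                            population=population)
    out = write_results({"assoc": assoc}, work_dir)
    manifest.record("associate", seed_assoc, out)

    seed_eqtl = stage_seed(config.seed, "eqtl")
    expr = read_expression(paths["expression"], paths["probe_genes"])
    pheno_raw = read_phenotypes(paths["phenotypes"])
    sex = (pheno_raw.set_index("sample_id").loc[panel.sample_ids, "sex"]
           .to_numpy())
    eqtl_table, ks = eqtl_stage(panel, expr, sex, signals, loci, config,
                                seed_eqtl)
    out = write_results({"eqtl": eqtl_table}, work_dir)
    manifest.record("eqtl", seed_eqtl, out)

    seed_fit = stage_seed(config.seed, "fitness")
    fit = fitness_stage(panel, pheno_raw, genes, loci, config, seed_fit)
    out = write_results({"snp_assoc": fit["snp_assoc"],
                         "gene_tests": fit["gene_tests"]}, work_dir)
    manifest.record("fitness", seed_fit, out)

    index_snps = (gwas.loc[gwas.groupby(
        gwas["snp_id"].map(_gene_of(genes, gwas)))["p"].idxmin(), "snp_id"]
        .tolist() if len(gwas) else [])
    calls = antagonism_stage(gwas, fit["snp_assoc"], index_snps)
    out = write_results({"antagonism": calls}, work_dir)
    manifest.record("antagonism", stage_seed(config.seed, "antagonism"), out)

    ranking = rank_genes(assoc) if len(assoc) else pd.DataFrame(
        columns=["gene", "n_significant", "headline"])
    matrix_a = signals.pivot_table(index="gene", columns="population",
                                   values="apex_abs_ihs", aggfunc="max")
    matrix_b = assoc.pivot_table(index="gene", columns="population",
                                 values="beta_scaled") if len(assoc) else pd.DataFrame()
    summary = pd.DataFrame([{
        "n_snps": panel.n_snps, "n_samples": panel.n_samples,
        "n_signals": len(signals),
        "ks_eqtl_p": np.nan if ks is None else ks.ks_p,
        "set_perm_p": np.nan if fit["enrichment"] is None
        else fit["enrichment"].perm_p_set,
        "gene_set_perm_p": fit["gene_set_perm_p"],
    }])
    out = write_results({"ranking": ranking,
                         "matrix_apex_ihs": matrix_a.reset_index(),
                         "matrix_beta": (matrix_b.reset_index()
                                         if len(matrix_b) else matrix_b),
                         "summary": summary}, work_dir)
    manifest.record("report", None, out)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(work_dir / "manifest.json")
    return manifest


def _gene_of(genes: pd.DataFrame, gwas: pd.DataFrame):
    def lookup(snp_id: str):
        pos = gwas.set_index("snp_id").loc[snp_id, "pos_bp"]
        for _, row in genes.iterrows():
            if row.start <= pos <= row.end:
                return row.gene
        return "intergenic"
    return lookup


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("selpleio")
    except PackageNotFoundError:
        return "0.0.0"
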
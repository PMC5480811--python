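"""Readers, writers and in-memory containers for every external artifact.

Conventions
-----------
* Haplotypes are coded 0 = ancestral, 1 = derived, using the VCF ``INFO/AA``
  field (or a sidecar table) to orient alleles.
* BED input is 0-based half-open on disk; all in-memory intervals are 1-based
  inclusive (the VCF convention).
* Tabular artifacts are tab-separated text with documented headers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("selpleio")

__all__ = [
    "HaplotypePanel",
    "QcReport",
    "RunConfig",
    "ExpressionMatrix",
    "read_phased_vcf",
    "write_phased_vcf",
    "apply_qc_filters",
    "hwe_chi2_p",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_gene_bed",
    "write_gene_bed",
    "read_phenotypes",
    "write_phenotypes",
    "read_expression",
    "write_expression",
    "write_results",
    "load_config",
    "setup_run_log",
]

GWAS_COLUMNS = ["snp_id", "chrom", "pos_bp", "effect_allele", "other_allele", "ln_or", "se", "p"]
PHENOTYPE_COLUMNS = [
    "sample_id", "sex", "birth_year", "lrs_raw",
    "education", "smoking", "born_in_country", "estrogen_use",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased haplotype panel with ancestral/derived (0/1) allele coding.

    ``hap_matrix`` has one row per haplotype (two consecutive rows per
    sample, in ``sample_ids`` order) and one column per SNP.
    """

    snp_ids: np.ndarray
    chrom: str
    positions_bp: np.ndarray
    genetic_pos_cM: np.ndarray
    alleles: np.ndarray  # (n_snps, 2): (ancestral, derived)
    hap_matrix: np.ndarray  # (n_haps, n_snps) in {0, 1}
    sample_ids: list[str]
    population: str = ""
    founder_flags: np.ndarray | None = None
    call_rate: np.ndarray | None = None  # per-SNP, from real-data readers

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.genetic_pos_cM = np.asarray(self.genetic_pos_cM, dtype=float)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.hap_matrix = np.ascontiguousarray(self.hap_matrix, dtype=np.int8)
        if self.founder_flags is None:
            self.founder_flags = np.ones(len(self.sample_ids), dtype=bool)
        self.founder_flags = np.asarray(self.founder_flags, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        n_haps, n_snps = self.hap_matrix.shape
        if n_haps % 2 != 0 or n_haps != 2 * len(self.sample_ids):
            raise ValueError(
                f"hap_matrix has {n_haps} rows for {len(self.sample_ids)} samples; "
                "expected two haplotypes per sample"
            )
        for name, arr in [("snp_ids", self.snp_ids), ("positions_bp", self.positions_bp),
                          ("genetic_pos_cM", self.genetic_pos_cM)]:
            if len(arr) != n_snps:
                raise ValueError(f"{name} length {len(arr)} != {n_snps} SNPs")
        if n_snps > 1:
            if not np.all(np.diff(self.positions_bp) > 0):
                raise ValueError("positions_bp must be strictly increasing")
            if not np.all(np.diff(self.genetic_pos_cM) >= -1e-12):
                raise ValueError("genetic_pos_cM must be non-decreasing")
        vals = np.unique(self.hap_matrix)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("hap_matrix entries must be 0 (ancestral) or 1 (derived)")

    # -- basic shape -------------------------------------------------------
    @property
    def n_snps(self) -> int:
        return self.hap_matrix.shape[1]

    @property
    def n_haps(self) -> int:
        return self.hap_matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    # -- derived quantities ------------------------------------------------
    def daf(self) -> np.ndarray:
        """Derived allele frequency per SNP."""
        return self.hap_matrix.mean(axis=0)

    def maf(self) -> np.ndarray:
        d = self.daf()
        return np.minimum(d, 1.0 - d)

    def dosage(self) -> np.ndarray:
        """Per-sample derived-allele dosage matrix (n_samples x n_snps)."""
        return (self.hap_matrix[0::2].astype(np.int16)
                + self.hap_matrix[1::2].astype(np.int16))

    def founder_dosage(self) -> np.ndarray:
        return self.dosage()[self.founder_flags]

    # -- subsetting --------------------------------------------------------
    def take_snps(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return dataclasses.replace(
            self,
            snp_ids=self.snp_ids[index],
            positions_bp=self.positions_bp[index],
            genetic_pos_cM=self.genetic_pos_cM[index],
            alleles=self.alleles[index],
            hap_matrix=self.hap_matrix[:, index],
            call_rate=None if self.call_rate is None else self.call_rate[index],
        )

    def take_samples(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        hap_rows = np.empty(2 * len(index), dtype=np.int64)
        hap_rows[0::2] = 2 * index
        hap_rows[1::2] = 2 * index + 1
        return dataclasses.replace(
            self,
            hap_matrix=self.hap_matrix[hap_rows],
            sample_ids=[self.sample_ids[i] for i in index],
            founder_flags=self.founder_flags[index],
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if len(hits) == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(hits[0])


@dataclass
class QcReport:
    n_input: int
    n_removed_call_rate: int = 0
    n_removed_hwe: int = 0
    n_removed_maf: int = 0

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.n_removed_call_rate
                - self.n_removed_hwe - self.n_removed_maf)


@dataclass
class ExpressionMatrix:
    """Pre-normalized (log2-scale) expression values, probes x samples."""

    values: pd.DataFrame  # index = probe_ids, columns = sample_ids
    gene_links: pd.Series  # probe_id -> gene name

    def __post_init__(self) -> None:
        missing = set(self.values.index) - set(self.gene_links.index)
        if missing:
            raise ValueError(f"probes without gene link: {sorted(missing)[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RunConfig:
    """Thresholds, seeds and paths for a pipeline run."""

    seed: int = 0
    populations: list[str] = field(default_factory=lambda: ["POP1"])
    # QC
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    # selection scan
    ihs_maf_min: float = 0.05
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    daf_bin_width: float = 0.025
    n_perm_ihs: int = 10_000
    ihs_candidate_min: float = 2.0
    candidate_p_max: float = 0.05
    cluster_k: int = 2
    cluster_window_bp: int = 50_000
    # locus mapping
    flank_bp: int = 5_000
    r2_link: float = 0.7
    r2_block: float = 0.7
    length_tol: float = 0.2
    # association
    n_perm_assoc: int = 10_000
    n_null_genes: int = 100
    # eQTL
    n_perm_eqtl: int = 10_000
    # fitness
    n_birth_groups: int = 6
    prune_r2: float = 0.2
    r2_excl: float = 0.8
    #: half-width of the exclusion zone around tested loci when building the
    #: relatedness kernel (~1 cM at the simulator's compressed map)
    grm_excl_window_bp: int = 50_000
    n_perm_snp: int = 10_000
    maf_bin_width: float = 0.05
    n_set_draws: int = 100
    n_gene_perm: int = 100
    n_gene_set_draws: int = 300
    # antagonism
    proxy_r2_min: float = 0.8
    proxy_window_bp: int = 1_000_000
    # paths (optional; used by the CLI pipeline)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_perm_ihs", "n_perm_assoc", "n_perm_eqtl", "n_perm_snp",
                     "n_set_draws", "n_gene_perm", "n_gene_set_draws", "n_null_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**raw)


def setup_run_log(path: str | Path | None = None, level: int = logging.INFO) -> logging.Logger:
    """Attach a plain-text run-log handler; seeds and filter counts go here."""
    logger.setLevel(level)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(path)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    return logger


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path,
    population_label: str = "",
    ancestral_table: Mapping[str, str] | None = None,
    genetic_map_cM_per_Mb: float = 1.0,
    founder_ids: Sequence[str] | None = None,
) -> HaplotypePanel:
    """Read a phased single-chromosome VCF into ancestral/derived coding.

    The ancestral allele is taken from ``INFO/AA``; ``ancestral_table``
    (snp_id -> ancestral base) is the fallback for records lacking it.
    Sites with an unknown ancestral state, or where it matches neither REF
    nor ALT, are dropped (counted in the log). Multiallelic and non-SNP
    records are dropped. Any unphased genotype is a hard error.

    Missing genotypes are tolerated only as far as the call-rate QC filter:
    the per-site call rate is recorded on the panel and missing haplotypes
    are filled with the site's major allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    call_rates: list[float] = []
    chrom = None
    n_dropped_aa = 0
    n_dropped_nonsnp = 0

    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped_nonsnp += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("panel readers expect a single-chromosome VCF")
        aa = var.INFO.get("AA")
        if aa is None and ancestral_table is not None:
            aa = ancestral_table.get(var.ID)
        aa = None if aa is None else str(aa).upper()
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if aa not in (ref, alt):
            n_dropped_aa += 1
            continue
        # gt_types/genotypes: list of [a0, a1, phased]
        geno = np.asarray(var.genotypes, dtype=np.int64)
        if np.any((geno[:, 2] == 0) & (geno[:, 0] >= 0)):
            bad = np.flatnonzero(geno[:, 2] == 0)[0]
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS} (sample {samples[bad]})"
            )
        hap = geno[:, :2].reshape(-1).astype(np.int8)  # ALT dosage per haplotype
        missing = hap < 0
        call_rates.append(1.0 - missing.mean())
        if missing.any():
            fill = 1 if hap[~missing].mean() > 0.5 else 0
            hap = hap.copy()
            hap[missing] = fill
        if aa == alt:  # derived allele is REF
            hap = (1 - hap).astype(np.int8)
            anc, der = alt, ref
        else:
            anc, der = ref, alt
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        alleles.append((anc, der))
        columns.append(hap)

    if n_dropped_aa:
        logger.warning("dropped %d sites with unusable ancestral state", n_dropped_aa)
    if n_dropped_nonsnp:
        logger.info("dropped %d multiallelic/non-SNP records", n_dropped_nonsnp)
    if not columns:
        raise ValueError(f"no usable biallelic SNPs in {path}")

    positions_bp = np.asarray(positions, dtype=np.int64)
    founders = None
    if founder_ids is not None:
        founders = np.array([s in set(founder_ids) for s in samples])
    return HaplotypePanel(
        snp_ids=np.asarray(snp_ids, dtype=object),
        chrom=chrom or "",
        positions_bp=positions_bp,
        genetic_pos_cM=positions_bp * genetic_map_cM_per_Mb / 1e6,
        alleles=np.asarray(alleles, dtype=object),
        hap_matrix=np.column_stack(columns),
        sample_ids=samples,
        population=population_label,
        founder_flags=founders,
        call_rate=np.asarray(call_rates),
    )


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a phased VCF 4.2 with ancestral state in INFO/AA."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j in range(panel.n_snps):
            anc, der = panel.alleles[j]
            col = panel.hap_matrix[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(panel.n_samples))
            fh.write(f"{panel.chrom}\t{panel.positions_bp[j]}\t{panel.snp_ids[j]}"
                     f"\t{anc}\t{der}\t.\tPASS\tAA={anc}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-df chi-square Hardy-Weinberg test from genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    keep = exp > 0
    chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
    return float(stats.chi2.sf(chi2, df=1))


def apply_qc_filters(
    panel: HaplotypePanel,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
    maf_min: float = 0.01,
) -> tuple[HaplotypePanel, QcReport]:
    """Standard marker QC: call rate, founder HWE, MAF — in that order.

    HWE is tested on founder genotypes only, by the 1-df chi-square.
    Raises if nothing survives.
    """
    report = QcReport(n_input=panel.n_snps)
    keep = np.ones(panel.n_snps, dtype=bool)

    if panel.call_rate is not None:
        fail = panel.call_rate < call_rate_min
        report.n_removed_call_rate = int(fail.sum())
        keep &= ~fail

    dos = panel.founder_dosage()
    n_bb = (dos == 2).sum(axis=0)  # derived homozygote
    n_ab = (dos == 1).sum(axis=0)
    n_aa = (dos == 0).sum(axis=0)
    hwe_p = np.array([hwe_chi2_p(a, h, b) for a, h, b in zip(n_aa, n_ab, n_bb)])
    fail_hwe = keep & (hwe_p < hwe_p_min)
    report.n_removed_hwe = int(fail_hwe.sum())
    keep &= ~fail_hwe

    fail_maf = keep & (panel.maf() < maf_min)
    report.n_removed_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    if not keep.any():
        raise ValueError("QC removed every SNP")
    logger.info("QC: %d -> %d SNPs (call_rate %d, HWE %d, MAF %d removed)",
                report.n_input, report.n_retained, report.n_removed_call_rate,
                report.n_removed_hwe, report.n_removed_maf)
    return panel.take_snps(keep), report


# ---------------------------------------------------------------------------
# tabular artifacts
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def read_gwas_summary(path: str | Path) -> pd.DataFrame:
    """Per-SNP disease summary statistics (effect sizes as ln odds ratios)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, GWAS_COLUMNS, "GWAS summary")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicated snp_id in GWAS summary: {dup}")
    if not ((df["p"] > 0) & (df["p"] <= 1)).all():
        raise ValueError("GWAS p values must lie in (0, 1]")
    if not (df["se"] > 0).all():
        raise ValueError("GWAS se must be positive")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError("effect_allele must differ from other_allele")
    return df.reset_index(drop=True)


def write_gwas_summary(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, GWAS_COLUMNS, "GWAS summary")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """BED4 gene annotation -> DataFrame with 1-based inclusive intervals."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "start0", "end0", "gene"],
                     dtype={"chrom": str})
    if (df["end0"] <= df["start0"]).any():
        raise ValueError("BED intervals must have end > start")
    out = pd.DataFrame({
        "gene": df["gene"],
        "chrom": df["chrom"],
        "start": df["start0"] + 1,  # 0-based half-open -> 1-based inclusive
        "end": df["end0"],
    })
    if out["gene"].duplicated().any():
        raise ValueError("duplicated gene names in BED")
    return out


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    _require_columns(genes, ["gene", "chrom", "start", "end"], "gene table")
    with open(path, "w") as fh:
        for _, row in genes.iterrows():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PHENOTYPE_COLUMNS, "phenotype table")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id in phenotype table")
    if (df["lrs_raw"] < 0).any():
        raise ValueError("lrs_raw must be non-negative")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, PHENOTYPE_COLUMNS, "phenotype table")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_expression(path: str | Path, gene_links_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    links = pd.read_csv(gene_links_path, sep="\t", index_col=0)["gene"]
    return ExpressionMatrix(values=values, gene_links=links)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     gene_links_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.10g")
    expr.gene_links.rename("gene").to_frame().rename_axis("probe_id").to_csv(
        gene_links_path, sep="\t")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result table as <name>.tsv under out_dir; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths.append(p)
    return paths
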
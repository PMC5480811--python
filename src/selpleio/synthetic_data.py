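"""Synthetic fixtures with the statistical structure of the real study data.

The real inputs — phased haplotype panels from worldwide populations, a
disease GWAS meta-analysis, lymphoblastoid expression, and a cohort with
lifetime reproductive success (LRS) — are access-restricted or bulky, so
every downstream stage is exercised on generated data with planted, known
signals:

* a forward Wright-Fisher simulator produces LD-structured phased haplotypes,
  optionally with an incomplete hard sweep at a chosen site;
* GWAS summary statistics with per-SNP true log odds ratios, optionally
  coupled to sweep proximity (the scenario the risk-vs-selection regression
  is designed to detect);
* expression with planted cis-eQTLs and a sex covariate;
* an LRS phenotype with fixed covariate effects, a relatedness-structured
  polygenic term, a secular birth-year trend, and planted SNP effects whose
  sign can be made concordant with disease risk (antagonistic pleiotropy).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import (
    ExpressionMatrix,
    HaplotypePanel,
    write_expression,
    write_gene_bed,
    write_gwas_summary,
    write_phased_vcf,
    write_phenotypes,
)

__all__ = [
    "SimSpec",
    "EffectSpec",
    "simulate_neutral_panel",
    "inject_sweep",
    "simulate_unlinked_panel",
    "simulate_gwas_summary",
    "simulate_expression",
    "simulate_fitness",
    "write_fixture_bundle",
]


@dataclass
class SimSpec:
    """Wright-Fisher forward-simulation parameters.

    The genetic map is linear: ``cM = bp * recomb_rate_cM_per_Mb / 1e6``.
    """

    n_samples: int = 100
    n_snps: int = 3000
    chrom_length_bp: int = 2_000_000
    #: desk-scale compression: an ~80 cM region represented in 2 Mb, so EHH
    #: decays below its cutoff within the simulated span (near-clonal
    #: families in a small population put an EHH floor at long range unless
    #: meioses carry enough crossovers) while neighboring SNPs keep strong LD
    recomb_rate_cM_per_Mb: float = 40.0
    wf_population_size: int = 200
    wf_generations: int = 150
    #: founders are copies drawn from this many template haplotypes, giving
    #: block-like LD at generation 0 that recombination then erodes
    n_founder_haplotypes: int = 8
    sweeps: list[tuple[int, float, float]] = field(default_factory=list)
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        for pos, s, stop in self.sweeps:
            if s < 0:
                raise ValueError("selection coefficient s must be >= 0")
            if not 0 < stop < 1:
                raise ValueError("stop_frequency must lie in (0, 1)")
        if self.n_samples > self.wf_population_size:
            raise ValueError("n_samples cannot exceed wf_population_size")


@dataclass
class EffectSpec:
    """Planted ground truth for the downstream analyses."""

    # GWAS
    gwas_effects: dict[str, float] = field(default_factory=dict)  # snp_id -> true ln(OR)
    gwas_noise_sd: float | None = None  # None -> per-SNP sampling SE
    coupling: float = 0.0  # |true ln OR| boost per unit of sweep-proximity kernel
    coupling_decay_bp: float = 100_000.0
    sweep_positions: list[int] = field(default_factory=list)
    n_cases: int = 60_000
    n_controls: int = 120_000
    # eQTL: (snp_id, probe_id, gene, beta, sex_beta, noise_sd)
    eqtls: list[tuple[str, str, str, float, float, float]] = field(default_factory=list)
    # LRS
    lrs_snp_betas: dict[str, float] = field(default_factory=dict)
    lrs_covariate_betas: dict[str, float] = field(default_factory=dict)
    lrs_intercept: float = 2.5
    lrs_h2: float = 0.0
    lrs_residual_sd: float = 1.0
    lrs_link: str = "gaussian"  # "gaussian" (rounded) or "poisson"
    birth_year_range: tuple[int, int] = (1900, 1960)
    secular_trend: float = 0.0  # latent-LRS change across the birth-year range

    def __post_init__(self) -> None:
        if not 0.0 <= self.lrs_h2 < 1.0:
            raise ValueError("lrs_h2 must lie in [0, 1)")
        if self.lrs_link not in ("gaussian", "poisson"):
            raise ValueError("lrs_link must be 'gaussian' or 'poisson'")

    def validate_against(self, panel: HaplotypePanel) -> None:
        known = set(panel.snp_ids)
        for sid in (*self.gwas_effects, *self.lrs_snp_betas,
                    *(e[0] for e in self.eqtls)):
            if sid not in known:
                raise ValueError(f"effect references SNP {sid!r} absent from panel")


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------

def _recombinant_gametes(pool_a: np.ndarray, pool_b: np.ndarray,
                         gmap_morgans: np.ndarray, total_morgans: float,
                         rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per (pool_a[i], pool_b[i]) parent pair.

    Crossover counts are Poisson(genetic length in Morgans); crossover points
    are uniform on the genetic map. Segment parity decides the source parent.
    """
    n, n_snps = pool_a.shape
    out = np.empty_like(pool_a)
    k = rng.poisson(total_morgans, size=n)
    start = rng.integers(0, 2, size=n)
    no_x = k == 0
    out[no_x] = np.where(start[no_x, None] == 0, pool_a[no_x], pool_b[no_x])
    for i in np.flatnonzero(~no_x):
        points = np.sort(rng.uniform(0.0, total_morgans, size=k[i]))
        parity = (start[i] + np.searchsorted(points, gmap_morgans)) % 2
        out[i] = np.where(parity == 0, pool_a[i], pool_b[i])
    return out


def _wf_generation_neutral(pool: np.ndarray, gmap_m: np.ndarray, total_m: float,
                           rng: np.random.Generator) -> np.ndarray:
    n_haps = pool.shape[0]
    pa = pool[rng.integers(0, n_haps, size=n_haps)]
    pb = pool[rng.integers(0, n_haps, size=n_haps)]
    return _recombinant_gametes(pa, pb, gmap_m, total_m, rng)


def simulate_neutral_panel(spec: SimSpec) -> HaplotypePanel:
    """Forward Wright-Fisher simulation of a neutral phased panel.

    2N founder haplotypes carry mutations at random positions with initial
    derived counts drawn from the standard neutral site-frequency spectrum
    (probability proportional to 1/k). Each generation every offspring
    haplotype is a recombinant copy of two uniformly chosen parent
    haplotypes. After ``wf_generations``, ``n_samples`` diploids are sampled
    and sites fixed or lost are dropped. Sweeps listed in ``spec.sweeps``
    are injected afterwards, in order.
    """
    rng = np.random.default_rng(spec.seed)
    two_n = 2 * spec.wf_population_size
    positions = np.sort(rng.choice(
        np.arange(1, spec.chrom_length_bp + 1), size=spec.n_snps, replace=False))
    gmap_cM = positions * spec.recomb_rate_cM_per_Mb / 1e6
    gmap_m = gmap_cM / 100.0
    total_m = spec.chrom_length_bp * spec.recomb_rate_cM_per_Mb / 1e6 / 100.0

    # template haplotypes carry mutations with derived counts from the
    # neutral SFS (P(count = k) ∝ 1/k); founders are copies of templates
    n_f = min(spec.n_founder_haplotypes, two_n)
    ks = np.arange(1, n_f)
    sfs = (1.0 / ks) / np.sum(1.0 / ks)
    counts = rng.choice(ks, size=spec.n_snps, p=sfs)
    templates = np.zeros((n_f, spec.n_snps), dtype=np.int8)
    for j, c in enumerate(counts):
        templates[rng.choice(n_f, size=c, replace=False), j] = 1
    pool = templates[rng.integers(0, n_f, size=two_n)]

    for _ in range(spec.wf_generations):
        pool = _wf_generation_neutral(pool, gmap_m, total_m, rng)

    freq = pool.mean(axis=0)
    seg = (freq > 0) & (freq < 1)
    if not seg.any():
        raise ValueError(
            "all simulated sites fixed or lost; increase n_snps or reduce wf_generations")

    hap_rows = rng.choice(two_n, size=2 * spec.n_samples, replace=False)
    panel = HaplotypePanel(
        snp_ids=np.array([f"rs{p}" for p in positions[seg]], dtype=object),
        chrom=spec.chrom,
        positions_bp=positions[seg],
        genetic_pos_cM=gmap_cM[seg],
        alleles=np.array([("A", "G")] * int(seg.sum()), dtype=object),
        hap_matrix=pool[np.sort(hap_rows)][:, seg],
        sample_ids=[f"S{i:04d}" for i in range(spec.n_samples)],
        population=f"SIM{spec.seed}",
    )
    # re-drop sites monomorphic within the sample
    f = panel.daf()
    panel = panel.take_snps((f > 0) & (f < 1))
    for k, (pos, s, stop) in enumerate(spec.sweeps):
        # sweeps start from low-frequency standing variation so the rise
        # leaves a detectable haplotype signature
        panel = inject_sweep(panel, pos, s, stop,
                             seed=spec.seed + 7919 * (k + 1),
                             max_start_freq=0.25)
    return panel


def inject_sweep(panel: HaplotypePanel, position: int, s: float,
                 stop_frequency: float, seed: int, max_restarts: int = 200,
                 max_generations: int = 5000,
                 max_start_freq: float | None = None) -> HaplotypePanel:
    """Continue the Wright-Fisher process with selection at one site.

    The panel's haplotypes are treated as the founding population (the sweep
    starts soft, from standing variation at the segregating site nearest to
    ``position``). Diploid fitnesses are 1, 1+s, 1+2s by derived-allele count
    at the focal site. Evolution stops the first generation the focal derived
    frequency reaches ``stop_frequency``; that final generation is drawn
    conditioned on the focal count being exactly ``ceil(stop * 2N)``, so the
    final frequency lies in ``[stop, stop + 1/(2N))``. If the allele is lost,
    the process restarts from the input panel (up to ``max_restarts``).
    """
    rng = np.random.default_rng(seed)
    daf = panel.daf()
    eligible = (daf > 0) & (daf < 1)
    if max_start_freq is not None:
        low = eligible & (daf <= max_start_freq)
        eligible = low if low.any() else eligible
    if not eligible.any():
        raise ValueError("no segregating site at or near the requested position")
    cand = np.flatnonzero(eligible)
    focal = int(cand[np.argmin(np.abs(panel.positions_bp[cand] - position))])
    two_n = panel.n_haps
    k_star = int(np.ceil(stop_frequency * two_n))
    gmap_m = panel.genetic_pos_cM / 100.0
    total_m = float(gmap_m[-1] - gmap_m[0]) if panel.n_snps > 1 else 0.0

    for restart in range(max_restarts):
        pool = panel.hap_matrix.copy()
        for _ in range(max_generations):
            count = int(pool[:, focal].sum())
            if count == 0:
                break  # lost -> restart
            if count >= k_star:
                break
            pool = _wf_selection_generation(pool, focal, s, gmap_m, total_m, rng,
                                            exact_k=None, k_star=k_star)
        count = int(pool[:, focal].sum())
        if k_star <= count < two_n:
            freq = pool.mean(axis=0)
            seg = (freq > 0) & (freq < 1)
            perm = rng.permutation(two_n)
            return dataclasses.replace(
                panel, hap_matrix=pool[perm][:, seg],
                snp_ids=panel.snp_ids[seg], positions_bp=panel.positions_bp[seg],
                genetic_pos_cM=panel.genetic_pos_cM[seg], alleles=panel.alleles[seg],
                call_rate=None,
            )
    raise RuntimeError(
        f"selected allele lost before reaching {stop_frequency} in "
        f"{max_restarts} restarts")


def _wf_selection_generation(pool: np.ndarray, focal: int, s: float,
                             gmap_m: np.ndarray, total_m: float,
                             rng: np.random.Generator,
                             exact_k: int | None, k_star: int) -> np.ndarray:
    """One selected WF generation; caps the focal derived count at ``k_star``.

    Parents are diploids (random haplotype pairing each generation) chosen
    with probability proportional to fitness; each offspring haplotype is one
    recombinant gamete. If the unconditional draw would overshoot ``k_star``,
    gametes are re-drawn stratified so the focal count is exactly ``k_star``.
    """
    two_n = pool.shape[0]
    n_dip = two_n // 2
    perm = rng.permutation(two_n)
    ha, hb = pool[perm[:n_dip]], pool[perm[n_dip:]]
    w = 1.0 + s * (ha[:, focal].astype(float) + hb[:, focal])
    pr = w / w.sum()

    def draw(n: int) -> np.ndarray:
        idx = rng.choice(n_dip, size=n, p=pr)
        return _recombinant_gametes(ha[idx], hb[idx], gmap_m, total_m, rng)

    off = draw(two_n)
    k = int(off[:, focal].sum())
    if k <= k_star:
        return off
    # stratified top-up: keep k_star derived-carrying and 2N-k_star others
    derived = [g for g in off if g[focal] == 1][:k_star]
    ancestral = [g for g in off if g[focal] == 0]
    while len(ancestral) < two_n - k_star:
        extra = draw(two_n)
        ancestral.extend(g for g in extra if g[focal] == 0)
    out = np.array(derived + ancestral[: two_n - k_star], dtype=np.int8)
    return out[rng.permutation(two_n)]


def simulate_unlinked_panel(n_samples: int, n_snps: int, seed: int,
                            maf_range: tuple[float, float] = (0.05, 0.5),
                            spacing_bp: int = 5_000, chrom: str = "1",
                            recomb_rate_cM_per_Mb: float = 1.0) -> HaplotypePanel:
    """Panel of independent sites in Hardy-Weinberg proportions.

    No LD is generated; intended for relatedness-kernel and mixed-model
    fixtures where sample size matters more than haplotype structure.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=n_snps)
    hap = (rng.random((2 * n_samples, n_snps)) < freqs).astype(np.int8)
    f = hap.mean(axis=0)
    keep = (f > 0) & (f < 1)
    positions = (np.arange(n_snps, dtype=np.int64) + 1) * spacing_bp
    return HaplotypePanel(
        snp_ids=np.array([f"rs{p}" for p in positions[keep]], dtype=object),
        chrom=chrom,
        positions_bp=positions[keep],
        genetic_pos_cM=positions[keep] * recomb_rate_cM_per_Mb / 1e6,
        alleles=np.array([("A", "G")] * int(keep.sum()), dtype=object),
        hap_matrix=hap[:, keep],
        sample_ids=[f"U{i:04d}" for i in range(n_samples)],
        population="UNLINKED",
    )


# ---------------------------------------------------------------------------
# downstream artifacts
# ---------------------------------------------------------------------------

def simulate_gwas_summary(panel: HaplotypePanel, spec: EffectSpec,
                          seed: int = 0) -> pd.DataFrame:
    """Per-SNP case/control summary statistics with planted effects.

    True effects are the planted per-SNP ln(OR) values plus, when
    ``coupling > 0``, a magnitude boost ``coupling * exp(-d / decay)`` for
    distance ``d`` to the nearest listed sweep position. Standard errors are
    those of a Wald log-OR estimate at the panel allele frequency for the
    nominal case/control sizes; observed effects add Normal noise of the
    configured SD (defaulting to that SE).
    """
    spec.validate_against(panel)
    rng = np.random.default_rng(seed)
    daf = panel.daf()
    true = np.array([spec.gwas_effects.get(sid, 0.0) for sid in panel.snp_ids])
    if spec.coupling > 0 and spec.sweep_positions:
        d = np.min(np.abs(panel.positions_bp[:, None]
                          - np.asarray(spec.sweep_positions)[None, :]), axis=1)
        boost = spec.coupling * np.exp(-d / spec.coupling_decay_bp)
        true = np.sign(np.where(true == 0, 1.0, true)) * (np.abs(true) + boost)
    p_eff = np.clip(daf, 0.01, 0.99)
    se = np.sqrt(1.0 / (2 * spec.n_cases * p_eff * (1 - p_eff))
                 + 1.0 / (2 * spec.n_controls * p_eff * (1 - p_eff)))
    noise_sd = se if spec.gwas_noise_sd is None else np.full_like(se, spec.gwas_noise_sd)
    obs = true + rng.normal(0.0, 1.0, size=len(true)) * noise_sd
    z = obs / se
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "snp_id": panel.snp_ids,
        "chrom": panel.chrom,
        "pos_bp": panel.positions_bp,
        "effect_allele": [a[1] for a in panel.alleles],  # derived allele
        "other_allele": [a[0] for a in panel.alleles],
        "ln_or": obs,
        "se": se,
        "p": pvals,
    })


def simulate_expression(panel: HaplotypePanel, spec: EffectSpec, seed: int,
                        sex: np.ndarray | None = None,
                        n_null_probes: int = 0) -> tuple[ExpressionMatrix, np.ndarray]:
    """Expression matrix with planted cis-eQTLs.

    Each planted probe is ``beta * dosage + sex_beta * sex + Normal noise``;
    optional null probes are pure noise linked to a placeholder gene.
    Returns the matrix and the per-sample sex vector used (0/1).
    """
    spec.validate_against(panel)
    rng = np.random.default_rng(seed)
    if sex is None:
        sex = rng.integers(0, 2, size=panel.n_samples)
    sex = np.asarray(sex)
    dosage = panel.dosage()
    rows, probe_ids, links = [], [], {}
    for snp_id, probe_id, gene, beta, sex_beta, noise_sd in spec.eqtls:
        x = dosage[:, panel.snp_index(snp_id)]
        rows.append(beta * x + sex_beta * sex + rng.normal(0, noise_sd, panel.n_samples))
        probe_ids.append(probe_id)
        links[probe_id] = gene
    for k in range(n_null_probes):
        pid = f"null_probe_{k}"
        rows.append(rng.normal(0, 1.0, panel.n_samples))
        probe_ids.append(pid)
        links[pid] = f"null_gene_{k}"
    values = pd.DataFrame(np.array(rows), index=probe_ids, columns=panel.sample_ids)
    return ExpressionMatrix(values=values, gene_links=pd.Series(links)), sex


def simulate_fitness(panel: HaplotypePanel, spec: EffectSpec, seed: int,
                     grm: np.ndarray | None = None) -> pd.DataFrame:
    """Lifetime-reproductive-success phenotypes with planted structure.

    The latent trait is intercept + covariate effects + planted SNP effects
    + polygenic term + secular birth-year trend + residual. The polygenic
    term has covariance ``sigma_g^2 * K`` with ``sigma_g^2`` chosen so the
    planted narrow-sense heritability (relative to the residual) equals
    ``lrs_h2``; K defaults to the realized relationship matrix of the panel
    itself (the same kernel construction the analysis uses). ``lrs_raw`` is
    a rounded, floored-at-zero Gaussian by default, or Poisson with a log
    link.
    """
    spec.validate_against(panel)
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    dosage = panel.dosage()

    cov = pd.DataFrame({
        "sample_id": panel.sample_ids,
        "sex": np.ones(n, dtype=int),  # cohort of women by default
        "birth_year": rng.integers(spec.birth_year_range[0],
                                   spec.birth_year_range[1] + 1, size=n),
        "education": rng.integers(0, 2, size=n),
        "smoking": rng.integers(0, 2, size=n),
        "born_in_country": rng.integers(0, 2, size=n),
        "estrogen_use": rng.integers(0, 2, size=n),
    })
    latent = np.full(n, spec.lrs_intercept, dtype=float)
    for name, beta in spec.lrs_covariate_betas.items():
        latent += beta * cov[name].to_numpy(dtype=float)
    for snp_id, beta in spec.lrs_snp_betas.items():
        latent += beta * dosage[:, panel.snp_index(snp_id)]
    span = max(spec.birth_year_range[1] - spec.birth_year_range[0], 1)
    latent += spec.secular_trend * (cov["birth_year"] - spec.birth_year_range[0]) / span

    if spec.lrs_h2 > 0:
        if grm is None:
            from .fitness_enrichment import compute_grm
            grm = compute_grm(panel, prune_r2=1.1, min_snps=1).kernel
        sigma_g2 = spec.lrs_h2 / (1.0 - spec.lrs_h2) * spec.lrs_residual_sd ** 2
        # eigenvalue square root; K is PSD up to rounding
        w, u = np.linalg.eigh(grm)
        w = np.clip(w, 0.0, None)
        g = u @ (np.sqrt(w * sigma_g2) * rng.normal(size=n))
        latent += g
    latent += rng.normal(0.0, spec.lrs_residual_sd, size=n)

    if spec.lrs_link == "gaussian":
        lrs_raw = np.maximum(0, np.rint(latent)).astype(int)
    else:
        rate = np.exp(np.clip(latent, None, 5.0))
        lrs_raw = rng.poisson(rate)
    out = cov.copy()
    out.insert(3, "lrs_raw", lrs_raw)
    return out


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(out_dir: str | Path, sim_spec: SimSpec | None = None,
                         effect_spec: EffectSpec | None = None,
                         genes: pd.DataFrame | None = None,
                         seed: int = 0) -> dict:
    """Emit a coherent on-disk fixture: VCF, BED, GWAS/expression/phenotype
    TSVs and a ``truth.json`` with the planted parameters.

    Defaults plant one sweep, risk-selection coupling around it, one strong
    cis-eQTL at the sweep apex, and two LRS SNP effects concordant with
    risk. Returns the truth dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if sim_spec is None:
        sim_spec = SimSpec(n_samples=80, n_snps=3000, chrom_length_bp=2_000_000,
                           wf_population_size=200,
                           sweeps=[(950_000, 0.05, 0.6)], seed=seed)
    panel = simulate_neutral_panel(sim_spec)

    if genes is None:
        genes = pd.DataFrame({
            "gene": ["GENE_SWEPT", "GENE_LEFT", "GENE_RIGHT"],
            "chrom": [sim_spec.chrom] * 3,
            "start": [900_000, 550_000, 1_300_000],
            "end": [1_000_000, 650_000, 1_400_000],
        })
    if effect_spec is None:
        apex = panel.snp_ids[int(np.argmin(np.abs(panel.positions_bp - 950_000)))]
        far = panel.snp_ids[int(np.argmin(np.abs(panel.positions_bp - 600_000)))]
        effect_spec = EffectSpec(
            coupling=0.08, sweep_positions=[950_000],
            eqtls=[(apex, "probe_swept", "GENE_SWEPT", 1.0, 0.3, 0.5)],
            lrs_snp_betas={apex: 0.25, far: 0.2},
            lrs_h2=0.2, lrs_residual_sd=1.0, secular_trend=-0.5,
        )
    gwas = simulate_gwas_summary(panel, effect_spec, seed=seed + 1)
    expr, sex = simulate_expression(panel, effect_spec, seed=seed + 2, n_null_probes=4)
    pheno = simulate_fitness(panel, effect_spec, seed=seed + 3)

    write_phased_vcf(panel, out_dir / "panel.vcf")
    write_gene_bed(genes, out_dir / "genes.bed")
    write_gwas_summary(gwas, out_dir / "gwas.tsv")
    write_expression(expr, out_dir / "expression.tsv", out_dir / "probe_genes.tsv")
    write_phenotypes(pheno, out_dir / "phenotypes.tsv")

    truth = {
        "seed": seed,
        "sim_spec": {k: v for k, v in dataclasses.asdict(sim_spec).items()},
        "effect_spec": {
            k: (v if not isinstance(v, tuple) else list(v))
            for k, v in dataclasses.asdict(effect_spec).items()
        },
        "n_snps": int(panel.n_snps),
        "n_samples": int(panel.n_samples),
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=list)
    return truth
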
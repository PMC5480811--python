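import numpy as np
import pytest

from selpleio.formats_io import HaplotypePanel


def make_panel(hap, positions=None, cM_per_Mb=1.0, chrom="1",
               population="TEST", alleles=None):
    """Panel from a raw 0/1 haplotype matrix (rows = haplotypes)."""
    hap = np.asarray(hap, dtype=np.int8)
    n_haps, n_snps = hap.shape
    assert n_haps % 2 == 0
    if positions is None:
        positions = (np.arange(n_snps) + 1) * 1000
    positions = np.asarray(positions, dtype=np.int64)
    if alleles is None:
        alleles = np.array([("A", "G")] * n_snps, dtype=object)
    return HaplotypePanel(
        snp_ids=np.array([f"rs{p}" for p in positions], dtype=object),
        chrom=chrom,
        positions_bp=positions,
        genetic_pos_cM=positions * cM_per_Mb / 1e6,
        alleles=alleles,
        hap_matrix=hap,
        sample_ids=[f"S{i}" for i in range(n_haps // 2)],
        population=population,
    )


def random_panel(rng, n_haps=20, n_snps=50, cM_per_Mb=1000.0):
    """Random segregating panel (high map density so EHH decays fast)."""
    while True:
        hap = (rng.random((n_haps, n_snps)) < rng.uniform(0.1, 0.9, n_snps))
        hap = hap.astype(np.int8)
        f = hap.mean(axis=0)
        if ((f > 0) & (f < 1)).all():
            return make_panel(hap, cM_per_Mb=cM_per_Mb)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
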
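"""Study constants: populations, candidate-gene panel size, thresholds.

The analysis targets coronary-artery-disease (CAD) candidate genes assembled
from genome-wide-significant GWAS loci, scanned for recent positive selection
in 12 worldwide populations (11 HapMap3 panels plus a Finnish extension).
"""

# Population codes, grouped by ancestry.
POPULATIONS_AFRICAN = ["ASW", "MKK", "YRI", "LWK"]
POPULATIONS_EAST_ASIAN = ["CHB", "CHD", "JPT"]
POPULATIONS_EUROPEAN = ["CEU", "TSI", "FIN"]
POPULATIONS_OTHER = ["GIH", "MEX"]
POPULATIONS = (
    POPULATIONS_AFRICAN + POPULATIONS_EAST_ASIAN + POPULATIONS_EUROPEAN + POPULATIONS_OTHER
)

# The CAD candidate-gene panel: 56 genes anchored on lead index SNPs plus 20
# further genes from the same meta-analysis loci.
N_CANDIDATE_GENES = 76

# Genes named in the headline ranking (those with at least four significant
# selection-risk associations across populations, plus worked-example loci).
NAMED_CANDIDATE_GENES = [
    "ABCG8", "ABO", "ADAMST7", "ANKS1A", "BCAS3", "CDKN2B-AS1", "CNNM2",
    "COG5", "COL4A2", "CXCL12", "FLT1", "HDAC9", "KCNK5", "KIAA1462", "KSR2",
    "LDLR", "LIPA", "LPA", "LPL", "MIA3", "MRAS", "NT5C2", "PCSK9", "PDGFD",
    "PEMT", "PHACTR1", "PLG", "PPAP2B", "RAI1", "SLC22A5", "SMAD3", "SMG6",
    "SWAP70", "TEX41",
]

#: Family-wise error rate used throughout.
ALPHA = 0.05

#: Bonferroni-corrected per-gene significance threshold across the candidate panel.
BONFERRONI_ALPHA = ALPHA / N_CANDIDATE_GENES


def gene_population_grid_size() -> int:
    """Number of gene-by-population analysis cells (one regression each)."""
    return N_CANDIDATE_GENES * len(POPULATIONS)


DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) allele pairs."""
    return DNA_COMPLEMENT.get(a1.upper()) == a2.upper()
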
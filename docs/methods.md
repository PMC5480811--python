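# Methods

`selpleio` implements a polygenic-selection analysis of disease-associated
loci: a haplotype-based selection scan, a per-gene mixed-model association
between disease genetic risk and selection signals, a cis-eQTL comparison of
selected versus random SNPs, a fitness-association battery on lifetime
reproductive success (LRS), and an antagonistic-pleiotropy classifier. The
original cohort-scale inputs (worldwide reference haplotype panels, a
case/control meta-analysis, lymphoblastoid expression, a longitudinal cohort
with completed reproduction) are access-restricted or bulky, so the package
ships a first-class synthetic-data module and validates every stage against
planted truth.

## Selection scan (EHH / iHS)

For a core SNP and core allele, extended haplotype homozygosity at marker
*m* is the probability that two random carrier haplotypes are identical at
every marker between the core and *m*:

    EHH(m) = sum_h C(n_h, 2) / C(n_c, 2)

over distinct extended haplotypes *h* among the `n_c` carriers. iHH is the
trapezoid integral of EHH over genetic distance, both directions from the
core, truncated at the last marker with EHH at or above a cutoff (default
0.05, the field's usual choice; no interpolation at the cutoff crossing). The unstandardized score is `iHS_raw = ln(iHH_A / iHH_D)`.
A SNP's score is undefined ("edge") when either direction reaches the
chromosome end with EHH still at or above the cutoff, when adjacent used
markers are more than `max_gap_bp` apart (default 200 kb), when MAF < 5%,
or when one allele has fewer than two carriers. Raw scores are standardized
to mean 0 / sample SD 1 within derived-allele-frequency bins of width 0.025,
and permutation p-values compare each SNP's |iHS| against draws (with
replacement, excluding the SNP itself) from its DAF class.

Haplotype grouping walks outward from the core refining a prefix partition
(linear in markers, singleton groups pruned); a numba-compiled kernel does
the genome scan, and the test suite asserts exact agreement both with the
pure-numpy curve implementation and with a brute-force pair-enumeration
oracle.

A candidate selection signal requires |iHS| > 2, permutation p < 0.05, and
at least 2 other |iHS| > 2 SNPs within 50 kb (the cluster rule; both knobs
configurable — the verbal "cluster" criterion in the source literature is
not quantified, so this is a declared convention). Signals are grouped by
window adjacency; the apex (max |iHS|) sets the magnitude class
(2–3, 3–4, >4).

## Risk-versus-selection mixed model

Per gene and population, per-SNP |ln(OR)| is regressed on |iHS| (both
standardized to unit variance, so the slope is a scaled coefficient) under

    y = b0 + b1 x + u v + e,   u ~ N(0, sigma_u^2),  e ~ N(0, sigma_e^2 I)

where `v` is the unit-norm first eigenvector of the gene's r² LD matrix.
"First eigenvector as a random effect" is formalized as a random
coefficient on the eigenvector loading — a rank-1 covariance
`sigma_u^2 v v^T` — because that is the construction in which a single
continuous vector is a random effect and both degenerate limits are
testable: `sigma_u^2 = 0` reduces exactly to OLS, and `sigma_u^2 -> inf`
to OLS with `v` as a fixed covariate. The variance ratio is estimated by
REML with a closed-form profile (all quantities reduce to scalar
projections on `v`). Two permutation nulls attach to each fit: shuffling
iHS across SNPs (comparing |slope| magnitudes, 10,000 shuffles by default)
and refitting on 100 length-matched random genes (±20% bp length). Genes
are ranked by the number of populations with shuffle-permutation p < 0.05;
four or more flags the headline panel.

## cis-eQTL comparison

Expression is regressed on derived-allele dosage with sex as covariate
(OLS, two-sided t-test); permutation p-values shuffle expression across
samples. The selection contrast takes the permuted eQTL p of each
gene-population combination's apex SNP (stratum A) versus an equal number
of SNPs drawn one-per-combination from LD blocks containing no
significant-selection SNP (stratum B), compared by a two-sample
Kolmogorov–Smirnov test (exact for strata of ≤25, asymptotic otherwise;
one-sided mode tests A stochastically smaller). "Different LD blocks" is
interpreted as blocks disjoint from any block holding a candidate-signal
SNP; blocks are greedy contiguous segments extended while the next SNP has
r² ≥ 0.7 with any block member. Stratum B is not allele-frequency matched
(flag available). Expression is assumed pre-normalized (log2 scale);
normalization pipelines are out of scope and part of the input contract.

## Fitness battery

LRS is adjusted for secular demographic change by splitting samples into six
equal-count birth-year groups (quantile cuts; cut points are not published,
so equal-count is the declared convention) and dividing by the group mean,
making each group's adjusted mean exactly 1. Association uses

    y = W a + x b + g + e,  g ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

with covariates education, smoking, birthplace and estrogen use, and K the
realized relationship matrix `K_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i)
/ (2 p_i (1-p_i))` over LD-pruned SNPs (greedy pruning to pairwise
r² ≤ 0.2) kept clear of the tested loci (interval ± window exclusion plus
r² ≥ 0.8 proxy exclusion) to avoid proximal contamination. K is
eigendecomposed once; `delta = sigma_e^2 / sigma_g^2` is profiled by
restricted likelihood on a 21-point log grid over [1e-5, 1e5] refined by
bounded golden-section, under the covariate-only model (the standard
spectral-LMM strategy, which keeps the scan linear in SNPs); each SNP is
then tested by GLS at that delta with a two-sided Wald p. REML is used
rather than ML — it removes the fixed-effect bias in the variance
components and both limits are testable.

Per-SNP permutation p-values resample nominal p-values within MAF bins of
width 0.05 (bin width unquantified in the source; widened to neighbors when
a bin holds under 100 SNPs). Set-level enrichment draws MAF-bin-matched SNP
samples without replacement (100 draws), counts draws with at least as many
p < 0.05 as the target set, and compares pooled draw p-values to target
p-values by two- and one-sided KS. The gene-based test is the
sum-of-squared-z statistic `T = sum z_i^2`, null-distributed as
`sum lambda_i chi2_1` with lambda the eigenvalues of the gene's *signed*
genotype correlation matrix (z statistics are correlated by r, not r²);
the tail is a two-moment (Satterthwaite) scaled chi-square, refined by a
10^6-draw Monte-Carlo when p < 1e-3 (chosen over a saddlepoint
approximation for testability: agreement is enforced against an
independent Monte-Carlo oracle).
Bonferroni and Benjamini–Hochberg adjustments use the full test count.

## Antagonism classification

The fitness beta is re-signed onto the GWAS effect allele (swap and strand
flips resolved; A/T and C/G palindromic SNPs excluded by default — safer at
desk scale, overridable). The significance gate is asymmetric: nominal LRS
p < 0.05 plus membership in the genome-wide-significant index-SNP list. A
both-significant SNP is *antagonistic* when the same allele raises both LRS
and disease risk (same-sign betas after alignment), otherwise *concordant*.
Proxy expansion collects SNPs within ±1 Mb at r² ≥ 0.8.

## Synthetic data: what it emulates, and what it does not

The haplotype generator is a forward Wright–Fisher simulation: founders are
copies drawn from a small template-haplotype pool (default 8 templates
carrying mutations with derived counts from the neutral 1/k spectrum); each
generation every offspring haplotype is a recombinant gamete
(Poisson-distributed crossovers, uniform on a linear genetic map). Defaults:
N = 200 diploids, 150 generations, 100 sampled diploids, 3000 initial sites
on a 2 Mb chromosome at 40 cM/Mb.

Two deliberate departures from a literal small-population neutral model are
design choices, not oversights. First, founders drawn from a small template
pool create block-like LD at generation 0 that recombination then erodes —
with mutually independent founders a desk-scale population has essentially
no LD. Second, the genetic map is compressed (tens of cM per Mb): in a small
population, near-clonal families put a long-range floor on EHH, and with a
short map that floor sits above the integration cutoff, leaving most scores
undefined; the compressed map represents a much larger genomic region at
desk scale so that EHH decays within the span while neighboring SNPs keep
strong LD. Sweeps are injected from low-frequency standing variation
(start ≤ 0.25 by default) with diploid fitnesses 1, 1+s, 1+2s and stop the
first generation the focal frequency reaches the target; the final
generation is drawn conditioned on the focal count equaling
`ceil(stop * 2N)`, so the stop contract holds exactly.

GWAS summary statistics plant per-SNP true ln(OR) values, optionally
coupled to sweep proximity by an exponential-decay kernel (default scale
100 kb); standard errors are Wald log-OR errors at nominal case/control
sizes (60,000 / 120,000). Expression probes are linear in dosage with a sex
term and Gaussian noise. The LRS phenotype is a latent Gaussian (intercept
2.5 children, covariate and SNP effects, secular birth-year trend,
polygenic term with covariance `sigma_g^2 K` using the same kernel
construction as the analysis, residual), rounded and floored at zero;
a Poisson log-link alternative is available but the default is rounded
Gaussian because the analysis model is linear. An auxiliary generator of
unlinked Hardy–Weinberg sites serves relatedness-scale fixtures (n = 1000)
where LD structure is irrelevant.

What passing tests therefore do **not** show: robustness to genotyping
error and missingness, to case/control ascertainment in the risk estimates,
to expression normalization artifacts, to non-Gaussian LRS (overdispersion,
zero inflation), or to demographic structure (migration, admixture,
bottlenecks) — none of which the generator emulates.

## Problem sizes and numerical choices

The validation battery runs at desk scale, chosen so the full suite
completes in minutes: standardization moments on ≥20,000 simulated SNPs
pooled over ~10 chromosomes; sweep power over 50 replicates (10 base panels
× 5 sweeps); permutation-null calibration with 500+ draws per family at
1000 (or 199 for the model-refit family) permutations; parameter recovery
over 25–100 seeds; set-enrichment power over 20 simulations. Permutation
p-values always carry the add-one pseudocount `(1 + k) / (n + 1)` and are
never zero. Eigenvalue ties in the LD eigenvector are broken toward the
lowest-index dominant loading and the sign fixed by making the
largest-magnitude loading positive. Degenerate inputs (zero-variance
regressors, monomorphic SNPs, bins with fewer than two scores) are flagged
undefined rather than raising, except where a hard contract is stated.

## Known limitations

- The desk-scale Wright–Fisher panel has young allele ages relative to real
  reference panels; standardized iHS magnitudes match only in distribution
  (by construction), not in raw scale.
- Roughly a third of simulated SNPs get undefined iHS near chromosome ends
  (the edge rule); real genome-wide scans lose far fewer.
- The pipeline's length-matched "random genes" on simulated data are random
  same-length intervals of the single simulated chromosome, not a genome
  annotation.
- Population labels are carried but the shipped pipeline demonstrates one
  simulated population per run; multi-population ranking is exercised at
  the library level.
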
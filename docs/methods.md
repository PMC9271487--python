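# Methods

This note documents the statistical procedures ovismap implements, the
defaults it ships, and what its simulation-based tests do and do not
demonstrate.

## Reference panel and catalogue

Genotypes are read and written in binary PLINK 1.x (SNP-major .bed,
magic bytes `6C 1B 01`), with the published 2-bit code (00 = 0 copies
of allele2, 01 = missing, 10 = 1, 11 = 2; four samples per byte,
least-significant bits first). Individual-major files are rejected
rather than silently transposed. Coordinates are 1-based throughout
and every window is inclusive on both ends.

The reference table keeps one row per surviving variant after three
filters applied in a fixed order per variant: sex-chromosome exclusion
(a configurable label set defaulting to {X, Y, XY, MT, 27}, since .bim
dialects disagree and the ovine assembly uses numeric codes), duplicate
collapse (same rs_id, or same chromosome+position+unordered allele
pair; the first occurrence in file order wins, which keeps the result
order-stable), then monomorphic removal (allele2 frequency 0 or 1 among
non-missing calls). Alleles are stored in bytewise lexicographic order
(a1 < a2, multi-character alleles permitted) and af2 is complemented
whenever the .bim order had to be swapped, so af2 always tracks the
stored a2. This single stored orientation is what makes effects from
different studies directly comparable, which colocalization requires.

LD between two variants is the Pearson correlation of dosage vectors
over pairwise-complete samples (missing calls excluded pairwise, n_used
reported so callers can filter); the matrix routine used by clumping
and the θ weights mean-imputes missing calls per variant, which is
identical on fully-called data and avoids per-pair recomputation.

## Harmonization

Each completed record is (i) looked up by rs_id (optional fallback:
chromosome+position+allele set, off by default since identifier
authority is a policy choice); (ii) coordinate-corrected to the
catalogue (default) or dropped; (iii) allele-aligned: direct match with
ea = a2 is kept, ea = a1 sign-flips (β → −β, z → −z, eaf → 1 − eaf),
a match only after Watson–Crick complementation strand-flips first,
anything else is dropped. Palindromic A/T and C/G pairs are dropped by
default; the optional `freq-resolve` policy aligns them by comparing
eaf with af2 but only where |af2 − 0.5| > 0.1, because frequency
resolution near 0.5 is guesswork. A p of exactly 0 on input is clamped
to 1e−300 so log10 arithmetic stays finite.

Each input record gets exactly one disposition label (the counts sum to
the input size). A record needing several actions is counted once with
precedence drop > strand_flipped > sign_flipped > position_corrected >
ok. Harmonization never changes |β|, SE, p or n, and it is an
involution on its output: flipping every kept record's orientation and
re-harmonizing reproduces the same table (up to one float ulp in
1 − (1 − eaf)); the disposition counts of the second pass swap
ok ↔ sign_flipped, as they must.

## Quality control

The three stages are independent, deterministic, and read-only:

1. **Allele-frequency concordance** — flag |eaf − af2| > 0.2; pass if
   ≤ 5 % of comparable records are flagged. The tolerance is lenient
   on purpose: study cohorts legitimately differ from the reference
   population, and this stage exists to catch wrong-column and
   wrong-orientation errors, not drift.
2. **Effect-size distribution** — λ_GC = median(z²)/0.45494 must lie
   in [0.5, 2.0] and no β/SE may be non-finite or |β| > 100. The wide
   λ window makes this a structural-error detector (z reported as χ²,
   one-sided p, log-scale β), not an inflation test.
3. **p–z consistency** — flag records with
   |log10 p − log10 2Φ(−|β/SE|)| > 0.1, strict inequality at the
   boundary. 0.1 in log10 tolerates float rounding and printed
   truncation while catching any systematically wrong p column.

All thresholds are arguments and are printed into the report header.
A study "passes QC" iff all three stages pass; the registry refuses
non-passing studies unless explicitly overridden. The HTML report is a
single self-contained file (inline CSS, base64 figures).

## Downstream analysis

**Clumping** is the standard greedy reduction: repeatedly take the
smallest-p unassigned SNP with p < 1e−7 (ties by chromosome then
position) as an index and absorb unassigned SNPs within ±1 Mb with
r² ≥ 0.1; SNPs absent from the panel are absorbed by distance, and a
distance-only mode exists for use without a panel. The p threshold is
the conventional genome-wide line for these array densities; window
and r² are ordinary clumping defaults and are exposed as flags.

**SMR-θ** is the weighted Pearson correlation of two studies' signed
z-vectors over the shared SNPs of a region. The default weights
w_i = 1/Σ_j r²_ij (the reciprocal of each SNP's LD "multiplicity")
down-weight redundant blocks so one long haplotype does not dominate;
uniform weights are available and are what the oracle tests check
against. |θ| > 0.7 (strict) classifies pleiotropic concordant/
discordant. θ requires ≥ 3 shared SNPs and positive variance of both
z-vectors; no significance test for θ is reported — only θ and n_snps,
since a defensible null distribution would require LD-aware
resampling that is out of scope.

**Kinship PCs.** The genomic relationship matrix is X·Xᵀ/m over
per-variant standardized dosages ((g − 2·af2)/√(2·af2·(1 − af2)),
mean-imputed missing calls, monomorphic variants skipped and counted);
PCs are top eigenvectors scaled by √eigenvalue.

**Breeding values** are the exact linear score Σ b_i·g_ik with g
counting the stated effective allele (dosage flipped 2 − g when that
allele is the panel's allele1; missing calls imputed at 2·af2 and
counted). Validation fits OLS of phenotype on [1, BV, covariates] with
Student-t inference, and the top-quartile contrast compares animals
with BV strictly above the 75th percentile against the whole cohort
(overlapping groups, exactly as a breeder would report it) on the
covariate-corrected phenotype — OLS residuals plus the fitted
intercept, so percentages are computed on the trait's own scale. The
Welch test is used for the group comparison; a cleaner top-vs-rest
contrast is available behind a flag.

## Synthetic data

The generator emulates a genotyped reference population and the
GWAS studies derived from it. Haplotypes come from a stationary
latent-Gaussian AR(1) per LD block, thresholded at the (1 − maf)
quantile; genotypes are sums of two independent haplotypes, so
Hardy–Weinberg holds by construction and LD decays geometrically
within blocks and vanishes between them. Phenotypes are additive over
standardized causal dosages plus Gaussian noise (so a standardized
effect b against unit noise gives h² = b²/(b² + 1)); the per-SNP scan
is textbook simple linear regression with a normal approximation for
p. All randomness flows through `numpy.random.default_rng` (PCG64),
so fixture hashes are reproducible across platforms.

What this does **not** emulate: demography and pedigree structure,
allele-frequency drift between reference and study cohorts, genotyping
error, imputation uncertainty, or real LD's long-range irregularity.
Passing tests therefore demonstrate algorithmic correctness and
calibration under a clean additive model, not robustness to the
artefacts of real array data.

The canonical fixture suite is a 200 × 2,000-variant panel (twenty
rho = 0.9 blocks) with exactly 5 duplicated, 3 monomorphic and 4
sex-chromosome rows planted so catalogue attrition is known; two traits
share one causal variant (standardized effect 0.8, unit noise) so a
pleiotropic locus exists; one copy of the first study has its ten
strongest p-values overwritten to violate stage-3 QC.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to make their statistics
stable on a laptop: 100-replicate colocalization calibration at
n = 500 individuals and h² = 0.3 per trait over two 30-SNP blocks;
breeding-value validation at n = 200 with four markers and a
500-replicate null for the type-I rate; 200 random ≤ 20-SNP instances
for the clumping oracle; 200 randomized studies for the harmonization
algebra. The acceptance script's reported top-quartile gain uses a
baseline trait mean of 3 units (an early-growth body-weight scale) so
the percentage is computed against a realistic denominator.

Tie-breaks are deterministic everywhere (proxy search: descending r²,
then distance, then position; clumping: p, then chromosome, then
position), correlations are clipped to [−1, 1] against rounding, and
p-values are floored at 1e−300. Degenerate inputs (constant dosages,
constant BV, < 3 shared SNPs, zero-variance z) raise typed errors
rather than returning NaN.

## Known limitations

No liftover between assemblies; no meta-analysis; no conditional/joint
multi-SNP analysis or Bayesian colocalization; hard-call genotypes
only (no PLINK 2 .pgen, no dosage data); the registry is single-writer
and local. The per-filter attrition of a real array catalogue depends
on the input data and is logged, never asserted.
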
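# ovismap

A desk-scale platform for livestock GWAS summary statistics: it
harmonizes heterogeneous per-SNP association tables against a genotyped
reference panel, quality-controls them in three defined stages, stores
them in a local queryable registry, and runs the downstream analyses a
sheep (or any livestock) geneticist needs — linkage-disequilibrium
proxy search, clumping into independent loci, SMR-θ colocalization
between traits, and breeding-value scoring for marker-assisted
selection.

It is aimed at groups who collect published GWAS results (effect sizes,
standard errors, p-values — never individual genotypes) from many
sources and need them on one coordinate system and one allele
orientation before any cross-study analysis is meaningful.

## The model in brief

**Harmonization.** A summary-statistics row carries at minimum an SNP
identifier, effective and reference alleles, the effect estimate β, and
one of {SE, p, z}. These are interchangeable without loss:

    z = β / SE,  p = 2·Φ(−|z|),  |z| = Φ⁻¹(1 − p/2).

Every record is aligned to a *reference table* built from a genotyped
panel (stored as binary PLINK .bed/.bim/.fam), which fixes per variant
the coordinate, the allele pair in lexicographic order (a1 < a2), and
the frequency of a2. Records whose effective allele is a1 are
sign-flipped (β → −β, z → −z, eaf → 1 − eaf); alleles matching only
after Watson–Crick complementation are strand-flipped; strand-ambiguous
A/T and C/G pairs are dropped by default.

**Three-stage QC.** (1) study allele frequencies vs the catalogue's;
(2) the effect-size distribution, summarized by the genomic inflation
factor λ_GC = median(z²)/0.455; (3) per-record consistency of the
reported p with 2·Φ(−|β/SE|).

**SMR-θ colocalization.** For two traits and one locus, θ is the
weighted Pearson correlation of the two signed z-vectors over the
shared SNPs (weights 1/Σ_j r²_ij down-weight redundant LD). |θ| > 0.7
calls the locus pleiotropic; the sign gives effect-direction
concordance. A small |θ| instead suggests distinct causal variants in
linkage.

**Breeding values.** BV_k = Σ_i b_i·g_ik over the index SNPs of clumped
loci, with g counting effective-allele copies; validated by OLS of
phenotype ~ BV + covariates (sex, parity, top kinship PCs) and by the
corrected-phenotype contrast of the top BV quartile against the cohort.

## Worked example

`examples/` holds one narrative script per capability. Running
`python examples/04_breeding_values.py` (simulated 200-animal panel,
one causal locus) prints:

```
1 independent locus/loci at p < 1e-7:
  index rs50 (chr1:345000, p = 3.28e-22, 13 member SNPs)

scored 200 animals; BV range [0.000, 2.090] trait units
phenotype ~ BV + sex + parity + PC1 + PC2: slope = 0.341 (se 0.052), p = 5.08e-10
top BV quartile vs cohort: +0.346 trait units (+11.47 %), Welch p = 0.000487
```

Clumping found the planted locus (index SNP rs50) and absorbed its LD
block; the breeding value built from that single marker is strongly
associated with the phenotype, and animals in the top BV quartile sit
11 % above the covariate-corrected cohort mean — the quantity a breeder
would use to judge the marker panel. Likewise
`python examples/03_colocalization.py` prints
`theta = -0.964 ... pleiotropic_discordant` for two traits driven by
the same variant with opposite signs, and `theta = -0.577 ...
not_colocalized` for traits with distinct causal variants.

The same pipeline is scriptable from the shell via the `ovis` CLI
(`ovis panel build-ref`, `ovis sumstats harmonize`, `ovis qc run`,
`ovis db register/snp/region`, `ovis clump`, `ovis coloc`,
`ovis bv score/test`, `ovis simulate fixtures`).

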
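"""Synthetic genotype panels and GWAS summary statistics.

Every other module is testable without external data: this module
emulates the role of the genotyped reference population and of the
summary-statistics studies loaded into the platform.

Genotypes are built from a latent-Gaussian AR(1) model: per haplotype
and per LD block, a stationary AR(1) series with lag-one correlation
``rho`` is thresholded at the (1 − maf) normal quantile, so each site
carries the alternative allele with probability ``maf`` and adjacent
sites are correlated, with LD decaying geometrically with distance.
A genotype is the sum of two independent haplotypes (Hardy–Weinberg by
construction).  This gives desk-fast, parameterizable LD; it is not a
demographic model (no pedigree, drift or genotyping error).

Phenotypes are additive over standardized causal dosages plus Gaussian
noise; the per-SNP association scan is the textbook simple linear
regression with a normal approximation for the p-value, matching how
the studies the platform stores are produced.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded from the config, so outputs are reproducible across runs and
platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel, VariantMeta, write_plink

__all__ = ["BlockSpec", "SimulationConfig", "simulate_panel", "simulate_gwas", "make_fixture_suite"]

# ordered, strand-unambiguous allele pairs cycled over simulated variants
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: ``n_snps`` sites with latent AR(1) correlation
    ``rho`` and per-site MAF drawn uniformly from ``maf_range``."""

    n_snps: int
    rho: float
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        if not abs(self.rho) < 1.0:
            raise ValueError("|rho| must be < 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


@dataclass
class SimulationConfig:
    n_individuals: int
    blocks: list[BlockSpec]
    causal: list[tuple[int, float]] = field(default_factory=list)  # (variant index, effect in SD units)
    residual_sd: float = 1.0
    seed: int = 0
    chrom: str = "1"
    pos_start: int = 100_000
    pos_step: int = 5_000
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not self.blocks:
            raise ValueError("at least one block required")
        m = sum(b.n_snps for b in self.blocks)
        for idx, _ in self.causal:
            if not 0 <= idx < m:
                raise ValueError(f"causal index {idx} outside 0..{m - 1}")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_variants(self) -> int:
        return sum(b.n_snps for b in self.blocks)


def _haplotypes(rng: np.random.Generator, n_hap: int, block: BlockSpec) -> np.ndarray:
    """n_hap × n_snps 0/1 alleles from a thresholded AR(1) latent."""
    z = np.empty((n_hap, block.n_snps))
    z[:, 0] = rng.standard_normal(n_hap)
    if block.n_snps > 1:
        innov = rng.standard_normal((n_hap, block.n_snps - 1)) * np.sqrt(1.0 - block.rho**2)
        for j in range(1, block.n_snps):
            z[:, j] = block.rho * z[:, j - 1] + innov[:, j - 1]
    mafs = rng.uniform(*block.maf_range, size=block.n_snps)
    cut = stats.norm.isf(mafs)  # P(z > cut) = maf
    return (z > cut).astype(np.int8)


def simulate_panel(cfg: SimulationConfig) -> GenotypePanel:
    """LD-structured diploid panel, deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    geno_blocks = []
    for block in cfg.blocks:
        g = _haplotypes(rng, n, block) + _haplotypes(rng, n, block)
        geno_blocks.append(g.astype(np.int8))
    dosages = np.concatenate(geno_blocks, axis=1)

    if cfg.missing_rate > 0.0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)

    variants = [
        VariantMeta(
            rs_id=f"rs{i + 1}",
            chrom=cfg.chrom,
            pos=cfg.pos_start + i * cfg.pos_step,
            allele1=_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0],
            allele2=_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1],
        )
        for i in range(cfg.n_variants)
    ]
    samples = [f"ind{i + 1}" for i in range(n)]
    return GenotypePanel(samples=samples, variants=variants, dosages=dosages)


def simulate_gwas(
    panel: GenotypePanel,
    cfg: SimulationConfig,
    variant_subset: list[int] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Phenotype + per-SNP association scan over ``panel``.

    y = sum_c b_c · standardized(g_c) + N(0, residual_sd²); each SNP is
    then tested by simple linear regression of y on its dosage (slope,
    SE, z = slope/SE, p = 2·Φ(−|z|)).  Monomorphic SNPs get NaN
    statistics.  Returns the raw summary-statistics table (columns
    rsid/chr/bp/effect_allele/other_allele/beta/se/pval/eaf/n, the
    package's default parse dialect) and the phenotype vector.
    The scan RNG is ``cfg.seed + 1`` so a panel and its GWAS draw
    independent streams.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    d = panel.dosages.astype(np.float64)
    d = np.where(d == MISSING, np.nan, d)
    col_mean = np.nanmean(d, axis=0)
    d_filled = np.where(np.isnan(d), col_mean, d)
    n = panel.n_samples

    y = rng.normal(0.0, cfg.residual_sd, size=n) if cfg.residual_sd > 0 else np.zeros(n)
    for idx, b in cfg.causal:
        g = d_filled[:, idx]
        sd = g.std()
        if sd == 0:
            raise ValueError(f"causal variant index {idx} is monomorphic")
        y = y + b * (g - g.mean()) / sd

    cols = range(panel.n_variants) if variant_subset is None else variant_subset
    rows = []
    for j in cols:
        v = panel.variants[j]
        g = d_filled[:, j]
        gc = g - g.mean()
        ssx = float(gc @ gc)
        if ssx == 0.0:
            beta = se = z = p = np.nan
        else:
            beta = float(gc @ (y - y.mean())) / ssx
            resid = (y - y.mean()) - beta * gc
            sigma2 = float(resid @ resid) / (n - 2)
            se = float(np.sqrt(sigma2 / ssx))
            if se == 0.0:
                z, p = np.inf, 0.0
            else:
                z = beta / se
                p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "rsid": v.rs_id,
                "chr": v.chrom,
                "bp": v.pos,
                "effect_allele": v.allele2,
                "other_allele": v.allele1,
                "beta": beta,
                "se": se,
                "pval": p,
                "eaf": g.mean() / 2.0,
                "n": n,
            }
        )
    return pd.DataFrame(rows), y


#: column_map turning the simulate_gwas dialect into the canonical schema
GWAS_COLUMN_MAP = {
    "rs_id": "rsid",
    "chrom": "chr",
    "pos": "bp",
    "ea": "effect_allele",
    "ra": "other_allele",
    "p": "pval",
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(
    out_dir: str | Path,
    seed: int,
    n_individuals: int = 200,
    n_clean_variants: int = 1988,
    n_duplicates: int = 5,
    n_monomorphic: int = 3,
    n_sex_chrom: int = 4,
) -> dict:
    """Write the canonical test fixture set and its manifest.

    Produces, under ``out_dir``:

    * ``panel.{bed,bim,fam}`` — a 200 × 2,000-variant panel whose last
      rows plant 5 duplicated variants, 3 monomorphic variants and 4
      sex-chromosome (chrom "27") rows, so the catalogue filters have
      known attrition;
    * ``gwas_a.tsv`` / ``gwas_b.tsv`` — two traits sharing one causal
      variant (a pleiotropic locus) scanned over the clean variants;
    * ``gwas_bad_p.tsv`` — gwas_a with p-values of its strongest hits
      overwritten, violating p–z consistency;
    * ``pheno.tsv`` / ``covar.tsv`` — phenotype and covariate tables
      keyed by sample_id;
    * ``manifest.json`` — sha256 of each file plus the RNG description.

    Deterministic: the same seed yields identical file hashes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_blocks = 20
    per_block = n_clean_variants // n_blocks
    rest = n_clean_variants - per_block * (n_blocks - 1)
    blocks = [BlockSpec(n_snps=per_block, rho=0.9) for _ in range(n_blocks - 1)]
    blocks.append(BlockSpec(n_snps=rest, rho=0.9))
    causal_idx = per_block // 2  # mid first block
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        blocks=blocks,
        causal=[(causal_idx, 0.8)],
        residual_sd=1.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    clean = simulate_panel(cfg)

    variants = list(clean.variants)
    dosages = [clean.dosages]
    # planted duplicates: re-use the first n_duplicates clean columns verbatim
    dup_src = list(range(n_duplicates))
    variants += [variants[j] for j in dup_src]
    dosages.append(clean.dosages[:, dup_src])
    # monomorphic: all-zero dosage autosomal rows
    mono = np.zeros((n_individuals, n_monomorphic), dtype=np.int8)
    # placed beyond every clean position so no (chrom, pos) collision
    base_pos = cfg.pos_start + (cfg.n_variants + 10) * cfg.pos_step
    variants += [
        VariantMeta(f"rsM{i + 1}", cfg.chrom, base_pos + (i + 1) * cfg.pos_step, "A", "G")
        for i in range(n_monomorphic)
    ]
    dosages.append(mono)
    # sex-chromosome rows: polymorphic but on chrom 27
    sex = rng.integers(0, 3, size=(n_individuals, n_sex_chrom)).astype(np.int8)
    variants += [
        VariantMeta(f"rsX{i + 1}", "27", 1_000 + i * cfg.pos_step, "C", "T")
        for i in range(n_sex_chrom)
    ]
    dosages.append(sex)

    panel = GenotypePanel(
        samples=clean.samples,
        variants=variants,
        dosages=np.concatenate(dosages, axis=1),
    )
    write_plink(panel, out_dir / "panel")

    # two traits, one shared causal variant
    gwas_a, y_a = simulate_gwas(clean, cfg)
    cfg_b = SimulationConfig(
        n_individuals=n_individuals,
        blocks=blocks,
        causal=[(causal_idx, 0.7)],
        residual_sd=1.0,
        seed=cfg.seed + 1000,
    )
    gwas_b, _ = simulate_gwas(clean, cfg_b)
    gwas_a.to_csv(out_dir / "gwas_a.tsv", sep="\t", index=False)
    gwas_b.to_csv(out_dir / "gwas_b.tsv", sep="\t", index=False)

    bad = gwas_a.copy()
    strongest = bad["pval"].nsmallest(10).index
    bad.loc[strongest, "pval"] = 0.5
    bad.to_csv(out_dir / "gwas_bad_p.tsv", sep="\t", index=False)

    pheno_rng = np.random.default_rng(cfg.seed + 2000)
    sex_cov = pheno_rng.integers(0, 2, size=n_individuals)
    parity = pheno_rng.integers(1, 4, size=n_individuals)
    pheno = 3.0 + 0.4 * y_a + 0.2 * sex_cov + pheno_rng.normal(0, 0.3, n_individuals)
    pd.DataFrame({"sample_id": panel.samples, "phenotype": pheno}).to_csv(
        out_dir / "pheno.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"sample_id": panel.samples, "sex": sex_cov, "parity": parity}
    ).to_csv(out_dir / "covar.tsv", sep="\t", index=False)

    files = sorted(
        p.name
        for p in out_dir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "rng": "numpy.random.default_rng (PCG64)",
        "n_individuals": n_individuals,
        "n_variants_total": panel.n_variants,
        "planted": {
            "duplicates": n_duplicates,
            "monomorphic": n_monomorphic,
            "sex_chrom": n_sex_chrom,
        },
        "causal_rs": clean.variants[causal_idx].rs_id,
        "files": {name: _sha256(out_dir / name) for name in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
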
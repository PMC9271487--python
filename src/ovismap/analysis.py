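"""Downstream analysis of harmonized summary statistics.

Implements the platform's analysis toolkit:

* greedy LD **clumping** of significant SNPs into independent loci;
* **SMR-theta colocalization**: a weighted correlation of two traits'
  signed z-scores over the shared SNPs of a locus.  |theta| near 1
  indicates a shared (pleiotropic) signal; the sign tells whether the
  effect directions agree.  |theta| > 0.7 is the conventional call;
* the **genomic relationship matrix** and its leading principal
  components, used as population-structure covariates;
* **breeding values** BV_k = sum_i b_i * g_ik over selected markers,
  their association with a phenotype (p ~ BV + covariates, OLS), and
  the top-quartile contrast used to judge a marker panel's value for
  marker-assisted selection;
* regional, Manhattan and z-z diagnostic plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    AlleleMismatchError,
    DegenerateBVError,
    DegeneratePatternError,
    DegeneratePredictorError,
    InsufficientOverlapError,
    MissingMarkerError,
)
from .ld import ld_matrix
from .panel import MISSING, GenotypePanel
from .sumstats import HarmonizedStudy

__all__ = [
    "Locus",
    "clump",
    "ThetaResult",
    "smr_theta",
    "theta_matrix",
    "kinship_pcs",
    "BVResult",
    "breeding_values",
    "RegressionResult",
    "bv_association",
    "ContrastResult",
    "top_quartile_contrast",
    "regional_plot",
    "manhattan",
    "zz_plot",
]


# ---------------------------------------------------------------- clumping


@dataclass(frozen=True)
class Locus:
    index_rs: str
    index_p: float
    chrom: str
    pos: int
    members: tuple[str, ...]  # includes the index SNP


def clump(
    study: HarmonizedStudy,
    panel: GenotypePanel | None,
    p_threshold: float = 1e-7,
    r2_threshold: float = 0.1,
    window_bp: int = 1_000_000,
    distance_only: bool = False,
    absorb_missing_by_distance: bool = True,
) -> list[Locus]:
    """Greedy reduction of significant SNPs into independent loci.

    Repeatedly takes the smallest-p unassigned SNP with
    p < ``p_threshold`` as an index (ties broken by chrom then pos) and
    absorbs every unassigned study SNP on the same chromosome within
    ±``window_bp`` whose r² with the index (from ``panel``) reaches
    ``r2_threshold``.  With ``distance_only`` (or a None panel) the
    window alone groups SNPs; SNPs absent from the panel are absorbed
    by distance when ``absorb_missing_by_distance`` is set.

    Loci are returned by ascending index p-value; no two index SNPs can
    be within the window with r² ≥ threshold.
    """
    df = study.records
    if len(df) == 0:
        return []
    order = df[["rs_id", "chrom", "pos", "p"]].copy()
    order["pos"] = order["pos"].astype(int)
    order = order.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    panel_ids = {v.rs_id for v in panel.variants} if panel is not None else set()
    assigned: set[str] = set()
    loci: list[Locus] = []

    sig = order[order["p"] < p_threshold]
    for idx_row in sig.itertuples(index=False):
        if idx_row.rs_id in assigned:
            continue
        members = [idx_row.rs_id]
        assigned.add(idx_row.rs_id)

        near = order[
            (order["chrom"] == idx_row.chrom)
            & ((order["pos"] - idx_row.pos).abs() <= window_bp)
            & (~order["rs_id"].isin(assigned))
        ]
        use_ld = not distance_only and panel is not None and idx_row.rs_id in panel_ids
        if use_ld and len(near):
            cand = [rs for rs in near["rs_id"] if rs in panel_ids]
            if cand:
                rr = ld_matrix(panel, [idx_row.rs_id] + cand)[0, 1:]
                for rs, r in zip(cand, rr):
                    if r * r >= r2_threshold:
                        members.append(rs)
                        assigned.add(rs)
            if absorb_missing_by_distance:
                for rs in near["rs_id"]:
                    if rs not in panel_ids and rs not in assigned:
                        members.append(rs)
                        assigned.add(rs)
        else:
            for rs in near["rs_id"]:
                members.append(rs)
                assigned.add(rs)

        loci.append(
            Locus(
                index_rs=idx_row.rs_id,
                index_p=float(idx_row.p),
                chrom=str(idx_row.chrom),
                pos=int(idx_row.pos),
                members=tuple(members),
            )
        )
    return loci


# ---------------------------------------------------------- colocalization


@dataclass(frozen=True)
class ThetaResult:
    theta: float
    n_snps: int
    weight_scheme: str
    snps: tuple[str, ...]
    classification: str  # pleiotropic_concordant | pleiotropic_discordant | not_colocalized


def _classify(theta: float, threshold: float) -> str:
    if theta > threshold:
        return "pleiotropic_concordant"
    if theta < -threshold:
        return "pleiotropic_discordant"
    return "not_colocalized"


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = float(w @ x), float(w @ y)
    cxy = float(w @ ((x - mx) * (y - my)))
    cx = float(w @ ((x - mx) ** 2))
    cy = float(w @ ((y - my) ** 2))
    if cx <= 0.0 or cy <= 0.0:
        raise DegeneratePatternError("zero variance of a z-score vector")
    return float(np.clip(cxy / np.sqrt(cx * cy), -1.0, 1.0))


def _region_shared(
    study_a: HarmonizedStudy,
    study_b: HarmonizedStudy,
    chrom: str,
    start: int,
    end: int,
) -> pd.DataFrame:
    sel_a = study_a.records.query("chrom == @chrom and @start <= pos <= @end")
    sel_b = study_b.records.query("chrom == @chrom and @start <= pos <= @end")
    merged = sel_a[["rs_id", "pos", "z"]].merge(
        sel_b[["rs_id", "z"]], on="rs_id", suffixes=("_a", "_b")
    )
    return merged.sort_values("pos", kind="mergesort").reset_index(drop=True)


def smr_theta(
    study_a: HarmonizedStudy,
    study_b: HarmonizedStudy,
    chrom: str,
    start: int,
    end: int,
    panel: GenotypePanel | None = None,
    weight_scheme: str = "ld_effective",
    threshold: float = 0.7,
) -> ThetaResult:
    """Colocalization statistic theta for a locus shared by two traits.

    theta is the weighted Pearson correlation of the two studies'
    z-vectors over the SNPs present in both within [start, end] on
    ``chrom`` (inclusive, both studies harmonized to the same effective
    allele).  Weights: "uniform" (w = 1) or "ld_effective"
    (w_i = 1 / sum_j r²_ij over the shared SNPs, down-weighting
    redundant LD; requires ``panel``).  |theta| > ``threshold``
    classifies the locus as pleiotropic, with the sign giving effect-
    direction concordance.
    """
    shared = _region_shared(study_a, study_b, str(chrom), start, end)
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"{len(shared)} shared SNPs in {chrom}:{start}-{end}; need >= 3"
        )
    snps = shared["rs_id"].tolist()
    za = shared["z_a"].to_numpy(dtype=float)
    zb = shared["z_b"].to_numpy(dtype=float)

    if weight_scheme == "uniform":
        w = np.ones(len(snps))
    elif weight_scheme == "ld_effective":
        if panel is None:
            raise ValueError("ld_effective weights require a genotype panel")
        r = ld_matrix(panel, snps)
        w = 1.0 / np.maximum((r * r).sum(axis=1), 1e-12)
    else:
        raise ValueError(f"unknown weight scheme: {weight_scheme}")

    theta = _weighted_pearson(za, zb, w)
    return ThetaResult(
        theta=theta,
        n_snps=len(snps),
        weight_scheme=weight_scheme,
        snps=tuple(snps),
        classification=_classify(theta, threshold),
    )


def theta_matrix(
    studies: list[HarmonizedStudy],
    chrom: str,
    start: int,
    end: int,
    panel: GenotypePanel | None = None,
    weight_scheme: str = "ld_effective",
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Pairwise theta over all study pairs in a region.

    Returns a symmetric DataFrame (diagonal 1) indexed by study_key and
    a list of (key_i, key_j, reason) for pairs that could not be
    computed (reported as NaN cells).
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    keys = [s.study_key for s in studies]
    mat = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    failures: list[tuple[str, str, str]] = []
    for i in range(len(studies)):
        for j in range(i + 1, len(studies)):
            try:
                res = smr_theta(
                    studies[i], studies[j], chrom, start, end,
                    panel=panel, weight_scheme=weight_scheme, threshold=threshold,
                )
                mat.iloc[i, j] = mat.iloc[j, i] = res.theta
            except (InsufficientOverlapError, DegeneratePatternError) as e:
                mat.iloc[i, j] = mat.iloc[j, i] = np.nan
                failures.append((keys[i], keys[j], str(e)))
    return mat, failures


def theta_heatmap(mat: pd.DataFrame, out: str | Path) -> Path:
    """Diverging-palette heatmap of a theta matrix (blue +, red −)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.6 * len(mat) + 2, 0.6 * len(mat) + 2))
    im = ax.imshow(mat.to_numpy(dtype=float), cmap="RdBu", vmin=-1, vmax=1)
    ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat)), mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="theta")
    out = Path(out)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out


# ------------------------------------------------------------- kinship PCs


def kinship_pcs(
    panel: GenotypePanel, k: int = 2
) -> tuple[np.ndarray, np.ndarray, int]:
    """Genomic relationship matrix and its top-k principal components.

    Dosages are standardized per variant (subtract 2·af2, divide by
    sqrt(2·af2·(1−af2)) under Hardy–Weinberg), missing calls imputed at
    the mean; GRM = X·Xᵀ/m.  PCs are the top-k eigenvectors scaled by
    sqrt(eigenvalue).  Returns (pcs [n×k], grm [n×n], n_skipped
    monomorphic variants).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = panel.n_samples
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")

    cols = []
    skipped = 0
    d = panel.dosages.astype(np.float64)
    for j in range(panel.n_variants):
        col = d[:, j].copy()
        miss = col == MISSING
        called = col[~miss]
        if called.size == 0:
            skipped += 1
            continue
        af2 = called.sum() / (2.0 * called.size)
        if af2 <= 0.0 or af2 >= 1.0:
            skipped += 1
            continue
        col[miss] = 2.0 * af2
        cols.append((col - 2.0 * af2) / np.sqrt(2.0 * af2 * (1.0 - af2)))
    if len(cols) < k:
        raise ValueError(f"only {len(cols)} polymorphic variants; need >= k={k}")

    x = np.column_stack(cols)
    grm = (x @ x.T) / x.shape[1]
    vals, vecs = np.linalg.eigh(grm)
    top = np.argsort(vals)[::-1][:k]
    pcs = vecs[:, top] * np.sqrt(np.maximum(vals[top], 0.0))
    return pcs, grm, skipped


# --------------------------------------------------------- breeding values


@dataclass(frozen=True)
class BVResult:
    bv: np.ndarray  # per individual, trait units
    b: np.ndarray  # per marker, oriented to the stated effective allele
    g: np.ndarray  # n_samples × n_markers effective-allele dosages
    markers: tuple[str, ...]
    n_imputed: int  # missing calls replaced by 2·af2


def breeding_values(effects: pd.DataFrame, panel: GenotypePanel) -> BVResult:
    """Score individuals: BV_k = sum_i b_i * g_ik.

    ``effects`` needs columns rs_id, effective_allele, beta; g counts
    copies of each marker's stated effective allele in the panel (the
    dosage is flipped to 2−g when that allele is the panel's allele1).
    Missing genotypes are imputed as 2·af2 of the variant and counted.
    """
    for col in ("rs_id", "effective_allele", "beta"):
        if col not in effects.columns:
            raise ValueError(f"effects table lacks column '{col}'")

    panel_idx = {v.rs_id: v for v in panel.variants}
    missing = [rs for rs in effects["rs_id"] if rs not in panel_idx]
    if missing:
        raise MissingMarkerError(f"markers absent from panel: {', '.join(missing)}")

    g_cols = []
    n_imputed = 0
    for row in effects.itertuples(index=False):
        v = panel_idx[row.rs_id]
        dose = panel.dosage_vector(row.rs_id).astype(np.float64)
        ea = str(row.effective_allele).upper()
        if ea == v.allele2:
            pass
        elif ea == v.allele1:
            dose = np.where(dose == MISSING, MISSING, 2.0 - dose)
        else:
            raise AlleleMismatchError(
                f"{row.rs_id}: effective allele {ea} matches neither "
                f"{v.allele1} nor {v.allele2}"
            )
        miss = dose == MISSING
        if miss.any():
            called = dose[~miss]
            af = called.mean() / 2.0 if called.size else 0.0
            dose[miss] = 2.0 * af
            n_imputed += int(miss.sum())
        g_cols.append(dose)

    g = np.column_stack(g_cols)
    b = effects["beta"].to_numpy(dtype=float)
    return BVResult(
        bv=g @ b,
        b=b,
        g=g,
        markers=tuple(effects["rs_id"]),
        n_imputed=n_imputed,
    )


# ------------------------------------------------------------- regression


@dataclass(frozen=True)
class RegressionResult:
    slope_bv: float
    se: float
    t: float
    p: float
    n: int
    covariate_effects: dict[str, float]


def bv_association(
    phenotype: np.ndarray,
    bv: BVResult | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> RegressionResult:
    """OLS fit of phenotype ~ intercept + BV + covariates.

    Reports the BV slope with its SE, t and two-sided p (Student t with
    n − k degrees of freedom).  Raises on a constant BV or a
    rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(phenotype, dtype=float)
    x_bv = bv.bv if isinstance(bv, BVResult) else np.asarray(bv, dtype=float)
    if len(y) != len(x_bv):
        raise ValueError("phenotype and BV lengths differ")
    if np.std(x_bv) == 0.0:
        raise DegeneratePredictorError("breeding values are constant")

    design = pd.DataFrame({"BV": x_bv})
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True).astype(float)
        if len(cov) != len(y):
            raise ValueError("covariate rows do not match phenotype length")
        design = pd.concat([design, cov], axis=1)
    exog = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        bad = [
            c
            for c in design.columns
            if np.linalg.matrix_rank(exog.drop(columns=[c]).to_numpy())
            == np.linalg.matrix_rank(exog.to_numpy())
        ]
        raise DegeneratePredictorError(f"rank-deficient design; collinear: {bad}")
    if len(y) <= exog.shape[1]:
        raise ValueError("need n > number of predictors + 1")

    fit = sm.OLS(y, exog).fit()
    return RegressionResult(
        slope_bv=float(fit.params["BV"]),
        se=float(fit.bse["BV"]),
        t=float(fit.tvalues["BV"]),
        p=float(fit.pvalues["BV"]),
        n=len(y),
        covariate_effects={
            c: float(fit.params[c]) for c in design.columns if c != "BV"
        },
    )


# --------------------------------------------------- top-quartile contrast


@dataclass(frozen=True)
class ContrastResult:
    mean_difference: float
    percent_difference: float
    t: float
    p: float
    n_top: int
    n_cohort: int


def _correct_phenotype(y: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """Residualize on covariates, adding back the fitted intercept so
    the corrected values stay on the phenotype's own scale."""
    if covariates is None or not len(covariates.columns):
        return y.copy()
    exog = sm.add_constant(covariates.reset_index(drop=True).astype(float), has_constant="add")
    fit = sm.OLS(y, exog).fit()
    return np.asarray(fit.resid) + float(fit.params["const"])


def top_quartile_contrast(
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    bv: BVResult | np.ndarray,
    top_vs_rest: bool = False,
) -> ContrastResult:
    """Phenotype gain of the top-BV-quartile animals.

    The phenotype is corrected for the covariates (OLS residuals plus
    the fitted intercept); the top group is animals whose BV is
    strictly above the 75th percentile.  Reports the top-group mean
    minus the cohort mean, the same as a percentage of the cohort mean,
    and the Welch t-test p for the comparison (against the whole cohort
    by default, or the complement with ``top_vs_rest``).
    """
    y = np.asarray(phenotype, dtype=float)
    x_bv = bv.bv if isinstance(bv, BVResult) else np.asarray(bv, dtype=float)
    if len(y) < 8:
        raise ValueError("need at least 8 animals")
    q75 = float(np.percentile(x_bv, 75))
    top = x_bv > q75
    if not top.any():
        raise DegenerateBVError("no animal strictly above the 75th BV percentile")

    corrected = _correct_phenotype(y, covariates)
    baseline = corrected[~top] if top_vs_rest else corrected
    diff = float(corrected[top].mean() - baseline.mean())
    base_mean = float(baseline.mean())
    pct = 100.0 * diff / base_mean if base_mean != 0.0 else float("nan")
    t, p = stats.ttest_ind(corrected[top], baseline, equal_var=False)
    return ContrastResult(
        mean_difference=diff,
        percent_difference=pct,
        t=float(t),
        p=float(p),
        n_top=int(top.sum()),
        n_cohort=len(y),
    )


# ------------------------------------------------------------------ plots


def _agg_pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def regional_plot(
    study: HarmonizedStudy, chrom: str, start: int, end: int, out: str | Path
) -> Path:
    """Regional association graph: −log10 p against position."""
    sel = study.records.query("chrom == @chrom and @start <= pos <= @end")
    if len(sel) == 0:
        raise ValueError(f"no records in {chrom}:{start}-{end}")
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.scatter(sel["pos"] / 1e6, -np.log10(np.maximum(sel["p"], 1e-300)), s=10)
    ax.set_xlabel(f"chr{chrom} position (Mb)")
    ax.set_ylabel("-log10 p")
    ax.set_title(study.study_key)
    out = Path(out)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out


def manhattan(study: HarmonizedStudy, out: str | Path) -> Path:
    """Genome-wide Manhattan plot, chromosomes laid end to end."""
    df = study.records
    if len(df) == 0:
        raise ValueError("empty study")
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, grp in df.groupby("chrom", sort=True):
        x = grp["pos"].to_numpy(dtype=float) + offset
        ax.scatter(x, -np.log10(np.maximum(grp["p"], 1e-300)), s=6)
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += float(grp["pos"].max()) + 1e6
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    out = Path(out)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out


def zz_plot(
    study_a: HarmonizedStudy,
    study_b: HarmonizedStudy,
    chrom: str,
    start: int,
    end: int,
    out: str | Path,
    theta: float | None = None,
) -> tuple[Path, int]:
    """Joint z-z scatter for the shared SNPs of a region.

    Returns the figure path and the number of points plotted.
    """
    shared = _region_shared(study_a, study_b, str(chrom), start, end)
    if len(shared) == 0:
        raise ValueError(f"no shared SNPs in {chrom}:{start}-{end}")
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.scatter(shared["z_a"], shared["z_b"], s=12)
    ax.set_xlabel(f"z ({study_a.study_key})")
    ax.set_ylabel(f"z ({study_b.study_key})")
    if theta is not None:
        ax.text(0.02, 0.95, f"theta = {theta:.2f}", transform=ax.transAxes)
    out = Path(out)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out, len(shared)
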
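"""Three-stage quality control of a harmonized study.

Stage 1 compares the study's effective-allele frequencies against the
catalogue frequencies; stage 2 inspects the effect-size distribution
(including the genomic inflation factor lambda_GC); stage 3 verifies
that each reported p-value corresponds to its z-statistic
(z = beta / se, p = 2*Phi(-|z|)).  The three checks are independent and
deterministic; a study passes QC iff all three pass.  Results can be
rendered into a single self-contained HTML report.
"""

from __future__ import annotations

import base64
import datetime
import io
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import CheckNotApplicableError, EmptyReportError
from .reference import ReferenceTable
from .sumstats import HarmonizationLog, HarmonizedStudy

__all__ = [
    "QCCheckResult",
    "check_af_concordance",
    "check_effect_distribution",
    "check_pz_consistency",
    "run_all_checks",
    "render_report",
    "CHI2_1_MEDIAN",
]

#: Median of the chi-squared distribution with 1 degree of freedom;
#: lambda_GC = median(z^2) / CHI2_1_MEDIAN.
CHI2_1_MEDIAN: float = float(stats.chi2.median(df=1))  # 0.454936...


@dataclass
class QCCheckResult:
    check_name: str  # af_concordance | effect_distribution | pz_consistency
    passed: bool
    n_flagged: int
    flagged_ids: list[str]
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_flagged == len(self.flagged_ids)


def check_af_concordance(
    study: HarmonizedStudy,
    ref: ReferenceTable,
    tol: float = 0.2,
    max_flagged_fraction: float = 0.05,
) -> QCCheckResult:
    """Stage 1: study allele frequencies vs the catalogue's.

    Flags records with |eaf - af2| > tol (records without an eaf are
    skipped and counted in the metrics).  Passes iff the flagged
    fraction of comparable records is <= ``max_flagged_fraction``.
    """
    df = study.records
    eaf = df["eaf"].to_numpy(dtype=float)
    have = ~np.isnan(eaf)
    if not have.any():
        raise CheckNotApplicableError("no records carry an effective-allele frequency")

    af2 = np.array([ref[rs].af2 if rs in ref else np.nan for rs in df["rs_id"]])
    usable = have & ~np.isnan(af2)
    diff = np.abs(eaf - af2)
    flagged = usable & (diff > tol)
    ids = df.loc[flagged, "rs_id"].tolist()

    n_usable = int(usable.sum())
    frac = len(ids) / n_usable if n_usable else 0.0
    if n_usable >= 2 and np.std(eaf[usable]) > 0 and np.std(af2[usable]) > 0:
        af_corr = float(np.corrcoef(eaf[usable], af2[usable])[0, 1])
    else:
        af_corr = float("nan")
    return QCCheckResult(
        check_name="af_concordance",
        passed=frac <= max_flagged_fraction,
        n_flagged=len(ids),
        flagged_ids=ids,
        metrics={
            "af_correlation": af_corr,
            "fraction_flagged": frac,
            "n_compared": float(n_usable),
            "n_without_eaf": float(int((~have).sum())),
            "tol": tol,
        },
    )


def check_effect_distribution(
    study: HarmonizedStudy,
    abs_beta_max: float = 100.0,
    lambda_range: tuple[float, float] = (0.5, 2.0),
) -> QCCheckResult:
    """Stage 2: effect-size distribution and genomic inflation.

    lambda_GC = median(z^2) / 0.45494 (the chi^2_1 median).  Flags
    records with non-finite beta/se or |beta| > ``abs_beta_max``;
    passes iff lambda_GC lies in ``lambda_range`` and nothing is
    flagged as non-finite.
    """
    df = study.records
    if len(df) == 0:
        raise CheckNotApplicableError("empty study")
    beta = df["beta"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    z = df["z"].to_numpy(dtype=float)

    nonfinite = ~np.isfinite(beta) | ~np.isfinite(se)
    huge = np.isfinite(beta) & (np.abs(beta) > abs_beta_max)
    flagged = nonfinite | huge
    ids = df.loc[flagged, "rs_id"].tolist()

    zf = z[np.isfinite(z)]
    lam = float(np.median(zf**2) / CHI2_1_MEDIAN) if zf.size else float("nan")
    lo, hi = lambda_range
    passed = bool(np.isfinite(lam) and lo <= lam <= hi and not flagged.any())
    return QCCheckResult(
        check_name="effect_distribution",
        passed=passed,
        n_flagged=len(ids),
        flagged_ids=ids,
        metrics={
            "lambda_gc": lam,
            "beta_mean": float(np.nanmean(beta)),
            "beta_median": float(np.nanmedian(beta)),
            "beta_sd": float(np.nanstd(beta)),
            "abs_beta_max": abs_beta_max,
        },
    )


def check_pz_consistency(study: HarmonizedStudy, tol_log10: float = 0.1) -> QCCheckResult:
    """Stage 3: does the reported p-value match beta/se?

    For each record p_exp = 2*Phi(-|beta/se|); a record is flagged when
    |log10(p) - log10(p_exp)| > tol_log10 (strict inequality, so a
    record exactly at the tolerance is not flagged).
    """
    df = study.records
    if len(df) == 0:
        return QCCheckResult("pz_consistency", True, 0, [], {"max_abs_log10_ratio": 0.0})
    beta = df["beta"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    p = df["p"].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_exp = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300)
        delta = np.abs(np.log10(np.maximum(p, 1e-300)) - np.log10(p_exp))
    delta = np.where(np.isfinite(delta), delta, np.inf)
    flagged = delta > tol_log10
    ids = df.loc[flagged, "rs_id"].tolist()
    return QCCheckResult(
        check_name="pz_consistency",
        passed=len(ids) == 0,
        n_flagged=len(ids),
        flagged_ids=ids,
        metrics={
            "max_abs_log10_ratio": float(delta.max()) if len(delta) else 0.0,
            "tol_log10": tol_log10,
        },
    )


def run_all_checks(
    study: HarmonizedStudy,
    ref: ReferenceTable,
    af_tol: float = 0.2,
    pz_tol_log10: float = 0.1,
    abs_beta_max: float = 100.0,
    lambda_range: tuple[float, float] = (0.5, 2.0),
) -> list[QCCheckResult]:
    """Run the three stages in order; a CheckNotApplicable stage is
    reported as a failed-to-run result rather than raised."""
    results: list[QCCheckResult] = []
    try:
        results.append(check_af_concordance(study, ref, tol=af_tol))
    except CheckNotApplicableError:
        results.append(
            QCCheckResult("af_concordance", False, 0, [], {"not_applicable": 1.0})
        )
    results.append(
        check_effect_distribution(study, abs_beta_max=abs_beta_max, lambda_range=lambda_range)
    )
    results.append(check_pz_consistency(study, tol_log10=pz_tol_log10))
    return results


def overall_pass(results: list[QCCheckResult]) -> bool:
    return all(r.passed for r in results)


_PAGE = string.Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>QC report: $study</title>
<style>
 body { font-family: sans-serif; margin: 2em; max-width: 70em; }
 .pass { background: #2e7d32; color: white; padding: .3em .8em; border-radius: 4px; }
 .fail { background: #c62828; color: white; padding: .3em .8em; border-radius: 4px; }
 table { border-collapse: collapse; margin: 1em 0; }
 td, th { border: 1px solid #aaa; padding: .25em .6em; text-align: left; }
 img { max-width: 28em; border: 1px solid #ddd; }
</style></head><body>
<h1>Summary-statistics QC report</h1>
<p>Study <b>$study</b> &mdash; $n records &mdash; generated $date</p>
<p>Thresholds: $thresholds</p>
<h2>Overall: <span class="$overall_class">$overall</span></h2>
$sections
<h2>Harmonization dispositions</h2>
$harmo_table
</body></html>
"""
)

_SECTION = string.Template(
    """<h2>$title <span class="$cls">$verdict</span></h2>
<table><tr><th>metric</th><th>value</th></tr>$metric_rows</table>
$flagged
$figure
"""
)

_TITLES = {
    "af_concordance": "Stage 1 &mdash; allele-frequency concordance",
    "effect_distribution": "Stage 2 &mdash; effect-size distribution",
    "pz_consistency": "Stage 3 &mdash; p-value / z-statistic consistency",
}


def _embed_figure(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img src="data:image/png;base64,{data}" alt="figure">'


def _af_figure(study: HarmonizedStudy, ref: ReferenceTable):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = study.records
    eaf = df["eaf"].to_numpy(dtype=float)
    af2 = np.array([ref[rs].af2 if rs in ref else np.nan for rs in df["rs_id"]])
    ok = ~np.isnan(eaf) & ~np.isnan(af2)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], color="grey", lw=1)
    ax.scatter(af2[ok], eaf[ok], s=6, alpha=0.5)
    ax.set_xlabel("catalogue af2")
    ax.set_ylabel("study eaf")
    ax.set_title("allele-frequency concordance")
    return fig


def _pz_figure(study: HarmonizedStudy):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = study.records
    z = df["z"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        obs = -np.log10(np.maximum(df["p"].to_numpy(dtype=float), 1e-300))
        exp = -np.log10(np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300))
    fig, ax = plt.subplots(figsize=(4, 4))
    lim = max(1.0, float(np.nanmax(exp)) if len(exp) else 1.0)
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.scatter(exp, obs, s=6, alpha=0.5)
    ax.set_xlabel("-log10 p expected from z")
    ax.set_ylabel("-log10 p reported")
    ax.set_title("p vs z consistency")
    return fig


def render_report(
    results: list[QCCheckResult],
    harmonization_log: HarmonizationLog,
    out: str | Path,
    study: HarmonizedStudy | None = None,
    ref: ReferenceTable | None = None,
    max_flagged_listed: int = 50,
) -> Path:
    """Write a single-file HTML QC report (inline CSS and figures).

    One section per check with a PASS/FAIL banner, the metric table and
    the flagged records (capped at ``max_flagged_listed``), followed by
    the harmonization disposition table.  Raises
    :class:`EmptyReportError` on an empty results list.
    """
    if not results:
        raise EmptyReportError("no QC check results to report")
    out = Path(out)

    sections = []
    for res in results:
        rows = "".join(
            f"<tr><td>{k}</td><td>{v:.6g}</td></tr>" for k, v in res.metrics.items()
        )
        if res.flagged_ids:
            shown = res.flagged_ids[:max_flagged_listed]
            more = len(res.flagged_ids) - len(shown)
            items = "".join(f"<li>{rs}</li>" for rs in shown)
            suffix = f"<p>... and {more} more</p>" if more else ""
            flagged = f"<p>{res.n_flagged} flagged record(s):</p><ul>{items}</ul>{suffix}"
        else:
            flagged = "<p>No records flagged.</p>"
        figure = ""
        if study is not None:
            if res.check_name == "af_concordance" and ref is not None:
                figure = _embed_figure(_af_figure(study, ref))
            elif res.check_name == "pz_consistency":
                figure = _embed_figure(_pz_figure(study))
        sections.append(
            _SECTION.substitute(
                title=_TITLES.get(res.check_name, res.check_name),
                cls="pass" if res.passed else "fail",
                verdict="PASS" if res.passed else "FAIL",
                metric_rows=rows,
                flagged=flagged,
                figure=figure,
            )
        )

    harmo_rows = "".join(
        f"<tr><td>{k}</td><td>{v}</td></tr>" for k, v in harmonization_log.counts.items()
    )
    harmo_table = (
        f"<table><tr><th>disposition</th><th>count</th></tr>{harmo_rows}"
        f"<tr><th>input records</th><td>{harmonization_log.n_input}</td></tr>"
        f"<tr><th>kept</th><td>{harmonization_log.n_kept}</td></tr></table>"
    )

    thresholds = "; ".join(
        f"{r.check_name}: "
        + ", ".join(f"{k}={v:.4g}" for k, v in r.metrics.items() if k in ("tol", "tol_log10", "abs_beta_max"))
        for r in results
    )
    ok = overall_pass(results)
    html = _PAGE.substitute(
        study=study.study_key if study is not None else "study",
        n=len(study.records) if study is not None else "?",
        date=datetime.date.today().isoformat(),
        thresholds=thresholds or "defaults",
        overall_class="pass" if ok else "fail",
        overall="PASS" if ok else "FAIL",
        sections="".join(sections),
        harmo_table=harmo_table,
    )
    out.write_text(html)
    return out
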
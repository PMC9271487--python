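"""Linkage disequilibrium from the reference panel.

LD between two variants is the Pearson correlation r of their dosage
vectors over pairwise-complete samples (both calls non-missing); r² is
its square.  This is the quantity the catalogue serves for proxy-SNP
search, clumping and the LD-effective colocalization weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateVariantError, UnknownVariantError
from .panel import MISSING, GenotypePanel
from .reference import ReferenceTable

__all__ = ["LDResult", "ld", "find_proxies", "ld_matrix"]


@dataclass(frozen=True)
class LDResult:
    rs_a: str
    rs_b: str
    r: float
    r2: float
    n_used: int


def _pair_r(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = (x != MISSING) & (y != MISSING)
    n_used = int(ok.sum())
    if n_used < 2:
        raise DegenerateVariantError("fewer than 2 pairwise-complete samples")
    xf = x[ok].astype(np.float64)
    yf = y[ok].astype(np.float64)
    xc = xf - xf.mean()
    yc = yf - yf.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateVariantError("zero dosage variance over complete samples")
    r = float((xc * yc).sum() / (sx * sy))
    return min(1.0, max(-1.0, r)), n_used


def ld(panel: GenotypePanel, rs_a: str, rs_b: str) -> LDResult:
    """Pairwise LD between two variants of ``panel``."""
    try:
        xa = panel.dosage_vector(rs_a)
        xb = panel.dosage_vector(rs_b)
    except KeyError as e:
        raise UnknownVariantError(str(e)) from e
    r, n_used = _pair_r(xa, xb)
    return LDResult(rs_a=rs_a, rs_b=rs_b, r=r, r2=r * r, n_used=n_used)


def ld_matrix(panel: GenotypePanel, rs_ids: list[str]) -> np.ndarray:
    """Signed r matrix for a set of variants (complete-case per pair).

    Missing dosages are mean-imputed per variant before the matrix
    product; for the small fully-called regions this package works with
    it matches pairwise :func:`ld` exactly, and degrades gracefully
    (never raises) for monomorphic columns, whose rows are set to 0 off
    the diagonal.
    """
    cols = []
    for rs in rs_ids:
        try:
            d = panel.dosage_vector(rs).astype(np.float64)
        except KeyError as e:
            raise UnknownVariantError(str(e)) from e
        miss = d == MISSING
        if miss.any():
            mean = d[~miss].mean() if (~miss).any() else 0.0
            d = np.where(miss, mean, d)
        cols.append(d)
    x = np.column_stack(cols)
    x = x - x.mean(axis=0)
    norms = np.sqrt((x * x).sum(axis=0))
    safe = np.where(norms == 0.0, 1.0, norms)
    xn = x / safe
    r = xn.T @ xn
    zero = norms == 0.0
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def find_proxies(
    panel: GenotypePanel,
    ref: ReferenceTable,
    rs_query: str,
    r2_min: float = 0.8,
    window_bp: int = 1_000_000,
) -> list[tuple[str, float, float]]:
    """Variants in LD with a query SNP (proxy-SNP search).

    Returns ``(rs_id, r, r2)`` tuples for catalogue variants on the same
    chromosome within ±``window_bp`` (inclusive) of the query whose r²
    with it is ≥ ``r2_min``, the query itself excluded, sorted by
    descending r² with ties broken by ascending distance then position.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    q = ref.get(rs_query)
    if q is None:
        raise UnknownVariantError(rs_query)
    if rs_query not in {v.rs_id for v in panel.variants}:
        raise UnknownVariantError(rs_query)

    hits: list[tuple[str, float, float, int, int]] = []
    for row in ref.rows:
        if row.rs_id == rs_query or row.chrom != q.chrom:
            continue
        dist = abs(row.pos - q.pos)
        if dist > window_bp:
            continue
        try:
            res = ld(panel, rs_query, row.rs_id)
        except (DegenerateVariantError, UnknownVariantError):
            continue
        if res.r2 >= r2_min:
            hits.append((row.rs_id, res.r, res.r2, dist, row.pos))
    hits.sort(key=lambda h: (-h[2], h[3], h[4]))
    return [(rs, r, r2) for rs, r, r2, _, _ in hits]
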
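"""Summary-statistics parsing, completion and harmonization.

GWAS summary statistics arrive as heterogeneous delimited text tables.
The minimum information per row is an SNP identifier, the effective and
reference alleles, the effect estimate, and any one of {standard error,
p-value, z-statistic}: the three are interchangeable without loss
because z = beta/se and p = 2·Φ(−|z|).

Records are held as a pandas DataFrame with the fixed schema
``rs_id, chrom, pos, ea, ra, beta, se, z, p, eaf, n``.  Harmonization
aligns every record to the reference table: identifier and position
unification, then allele alignment so the stored effective allele is
always the catalogue's a2 (the lexicographically larger allele), making
effect signs comparable across studies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateSEError,
    IncompleteRecordError,
    InvalidPError,
    MissingColumnError,
)
from .reference import ReferenceTable

__all__ = [
    "SCHEMA",
    "ParseLog",
    "parse_sumstats",
    "complete_statistics",
    "HarmonizePolicy",
    "HarmonizationLog",
    "HarmonizedStudy",
    "harmonize",
]

#: Canonical column order of a (harmonized) study table.
SCHEMA = ["rs_id", "chrom", "pos", "ea", "ra", "beta", "se", "z", "p", "eaf", "n"]

_NUMERIC = ["pos", "beta", "se", "z", "p", "eaf", "n"]
_REQUIRED = ["rs_id", "ea", "ra", "beta"]

# unicode minus / en-dash / em-dash seen in exported tables ("5E–07")
_DASHES = re.compile("[−–—]")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_P_FLOOR = 1e-300


def _normalize_number(cell: object) -> float:
    if cell is None:
        return np.nan
    s = str(cell).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NULL", "."}:
        return np.nan
    return float(_DASHES.sub("-", s))


@dataclass
class ParseLog:
    n_lines: int = 0
    n_parsed: int = 0
    n_dropped: int = 0
    errors: list[str] = field(default_factory=list)


def parse_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, ParseLog]:
    """Read a raw summary-statistics table into the canonical schema.

    Parameters
    ----------
    path
        Delimited text file (gzip transparently supported by pandas).
    column_map
        Maps canonical names (``rs_id``, ``ea``, ``ra``, ``beta``,
        ``se``, ``z``, ``p``, ``eaf``, ``n``, ``chrom``, ``pos``) to the
        file's header names.  Identity for omitted keys.
    sep
        Field delimiter; autodetected (tab/comma/whitespace) if None.

    Rows whose numeric cells cannot be parsed (after normalizing unicode
    dashes to ASCII minus) are dropped and counted in the returned
    :class:`ParseLog`.  A missing required column raises
    :class:`MissingColumnError` naming it.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str, comment=None)
    raw.columns = [c.strip() for c in raw.columns]

    rename = {}
    for canon in SCHEMA:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
    df = raw.rename(columns=rename)

    for col in _REQUIRED:
        if col not in df.columns:
            raise MissingColumnError(f"required column '{col}' not found in {path}")
    if not any(c in df.columns for c in ("se", "p", "z")):
        raise MissingColumnError(
            f"{path}: need at least one of 'se', 'p', 'z' alongside 'beta'"
        )

    for col in SCHEMA:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SCHEMA].copy()

    log = ParseLog(n_lines=len(df))
    bad = np.zeros(len(df), dtype=bool)
    for col in _NUMERIC:
        parsed = np.full(len(df), np.nan)
        for i, cell in enumerate(df[col].tolist()):
            try:
                parsed[i] = _normalize_number(cell)
            except ValueError:
                bad[i] = True
                log.errors.append(f"row {i}: unparseable {col}={cell!r}")
        df[col] = parsed

    df["rs_id"] = df["rs_id"].astype(str).str.strip()
    df["chrom"] = df["chrom"].astype(str).str.strip().replace({"nan": ""})
    for col in ("ea", "ra"):
        df[col] = df[col].astype(str).str.strip().str.upper()

    df = df.loc[~bad].reset_index(drop=True)
    log.n_dropped = int(bad.sum())
    log.n_parsed = len(df)
    return df, log


def complete_statistics(records: pd.DataFrame) -> pd.DataFrame:
    """Fill in se, z and p so all three are present and consistent.

    Per record: with beta and se, z = beta/se and p = 2·Φ(−|z|); with
    beta and z, se = beta/z; with beta and p alone,
    |z| = Φ⁻¹(1 − p/2) with the sign of beta, then se = beta/z.
    A p of exactly 0 on input is clamped to 1e−300 (keeps log10
    arithmetic finite); that propagates into a finite z.

    Raises :class:`DegenerateSEError`, :class:`InvalidPError` or
    :class:`IncompleteRecordError` naming the first offending record.
    """
    df = records.copy()
    beta = df["beta"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    z = df["z"].to_numpy(dtype=float)
    p = df["p"].to_numpy(dtype=float)
    ids = df["rs_id"].to_numpy()

    if np.isnan(beta).any():
        raise IncompleteRecordError(f"{ids[int(np.isnan(beta).argmax())]}: beta missing")

    have_se, have_z, have_p = ~np.isnan(se), ~np.isnan(z), ~np.isnan(p)
    none = ~(have_se | have_z | have_p)
    if none.any():
        raise IncompleteRecordError(
            f"{ids[int(none.argmax())]}: none of se/z/p present"
        )
    if (have_se & (se <= 0)).any():
        k = int((have_se & (se <= 0)).argmax())
        raise DegenerateSEError(f"{ids[k]}: se={se[k]} must be positive")
    bad_p = have_p & ((p < 0) | (p > 1))
    if bad_p.any():
        k = int(bad_p.argmax())
        raise InvalidPError(f"{ids[k]}: p={p[k]} outside [0, 1]")
    p = np.where(have_p & (p == 0.0), _P_FLOOR, p)

    use_z = ~have_se & have_z
    if (use_z & (z == 0) & (beta != 0)).any():
        k = int((use_z & (z == 0) & (beta != 0)).argmax())
        raise DegenerateSEError(f"{ids[k]}: z=0 with nonzero beta, se underivable")
    use_p = ~have_se & ~have_z & have_p
    if (use_p & (beta == 0)).any():
        k = int((use_p & (beta == 0)).argmax())
        raise DegenerateSEError(f"{ids[k]}: beta=0 with only p given, se underivable")
    if (use_p & (p == 1.0)).any():
        k = int((use_p & (p == 1.0)).argmax())
        raise DegenerateSEError(f"{ids[k]}: p=1 with only p given, z=0, se underivable")
    if (use_z & (z == 0) & (beta == 0)).any():
        k = int((use_z & (z == 0) & (beta == 0)).argmax())
        raise IncompleteRecordError(f"{ids[k]}: beta=0 and z=0, se underivable")

    z_out = np.where(have_se, beta / np.where(have_se, se, 1.0), z)
    z_from_p = stats.norm.isf(np.where(use_p, p, 0.5) / 2.0) * np.where(beta >= 0, 1.0, -1.0)
    z_out = np.where(use_p, z_from_p, z_out)
    se_out = np.where(have_se, se, beta / np.where(z_out == 0, np.nan, z_out))
    p_out = 2.0 * stats.norm.sf(np.abs(z_out))
    p_out = np.maximum(p_out, _P_FLOOR)

    if (np.isfinite(se_out) & (se_out <= 0)).any():
        k = int((np.isfinite(se_out) & (se_out <= 0)).argmax())
        raise DegenerateSEError(f"{ids[k]}: derived se={se_out[k]} not positive")

    df["z"] = z_out
    df["se"] = se_out
    df["p"] = p_out
    return df


DISPOSITIONS = [
    "ok",
    "sign_flipped",
    "strand_flipped",
    "position_corrected",
    "dropped_allele_mismatch",
    "dropped_unknown_id",
    "dropped_palindromic",
]


@dataclass(frozen=True)
class HarmonizePolicy:
    """Knobs for identifier, position and allele unification.

    position
        "ref-position" (default): catalogue coordinates overwrite a
        disagreeing record, counted position_corrected; "drop": such
        records are dropped (counted dropped_allele_mismatch would be
        wrong, so they count position_corrected in the dropped list).
    palindromic
        "drop" (default): strand-ambiguous A/T and C/G variants are
        dropped; "freq-resolve": aligned by comparing eaf with the
        catalogue af2, but only where |af2 − 0.5| > freq_margin.
    locus_fallback
        When True, a record whose rs_id is unknown is looked up by
        (chrom, pos, allele set) and adopts the catalogue rs_id.
    """

    position: str = "ref-position"
    palindromic: str = "drop"
    freq_margin: float = 0.1
    locus_fallback: bool = False


@dataclass
class HarmonizationLog:
    """One disposition per input record; counts sum to the input size.

    A record needing several actions (e.g. a position fix and a sign
    flip) is counted once under the most informative label, with
    precedence drop > strand_flipped > sign_flipped >
    position_corrected > ok.
    """

    counts: dict[str, int] = field(default_factory=lambda: {d: 0 for d in DISPOSITIONS})
    dispositions: list[tuple[str, str]] = field(default_factory=list)  # (rs_id, label)
    n_input: int = 0
    n_kept: int = 0

    def record(self, rs_id: str, label: str) -> None:
        self.counts[label] += 1
        self.dispositions.append((rs_id, label))


@dataclass
class HarmonizedStudy:
    """A study whose records are aligned to the catalogue orientation."""

    study_key: str
    records: pd.DataFrame  # SCHEMA columns; ea == catalogue a2 everywhere
    log: HarmonizationLog

    def write_parquet(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_parquet(path, index=False)
        return path

    @classmethod
    def read_parquet(cls, path: str | Path, study_key: str | None = None) -> "HarmonizedStudy":
        df = pd.read_parquet(path)
        key = study_key or Path(path).stem
        return cls(study_key=key, records=df, log=HarmonizationLog(n_input=len(df), n_kept=len(df)))


def _is_palindromic(ea: str, ra: str) -> bool:
    comp = _complement(ea)
    return comp is not None and comp == ra


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def harmonize(
    records: pd.DataFrame,
    ref: ReferenceTable,
    policy: HarmonizePolicy = HarmonizePolicy(),
    study_key: str = "study",
) -> HarmonizedStudy:
    """Align completed records to the reference table.

    Per record: (i) the rs_id is looked up in the catalogue (optionally
    falling back to chrom+pos+allele-set); unknown ids are dropped.
    (ii) A disagreeing coordinate is overwritten with the catalogue's
    (or the record dropped, per policy).  (iii) Alleles are aligned to
    the catalogue pair: a direct match with ea = a2 is kept as-is; with
    ea = a1 the effect is sign-flipped (beta → −beta, z → −z,
    eaf → 1 − eaf, alleles swapped); a match only after Watson–Crick
    complementation is strand-flipped first; anything else is dropped.
    Strand-ambiguous palindromic pairs are handled per policy.

    Harmonization never changes |beta|, se, p or n.
    """
    log = HarmonizationLog(n_input=len(records))
    out_rows: list[dict] = []

    for row in records.to_dict("records"):
        rs, ea, ra = row["rs_id"], row["ea"], row["ra"]
        rv = ref.get(rs)
        if rv is None and policy.locus_fallback and row["chrom"] and not np.isnan(row["pos"] or np.nan):
            for cand in ref.at_locus(str(row["chrom"]), int(row["pos"])):
                if {ea, ra} == {cand.a1, cand.a2}:
                    rv = cand
                    row["rs_id"] = cand.rs_id
                    break
        if rv is None:
            log.record(rs, "dropped_unknown_id")
            continue

        pos_corrected = False
        has_pos = row["chrom"] not in ("", None) and not pd.isna(row["pos"])
        if has_pos and (str(row["chrom"]) != rv.chrom or int(row["pos"]) != rv.pos):
            if policy.position == "drop":
                log.record(rs, "position_corrected")
                continue
            pos_corrected = True
        row["chrom"], row["pos"] = rv.chrom, rv.pos

        ref_set = {rv.a1, rv.a2}
        strand = False
        if {ea, ra} != ref_set:
            cea, cra = _complement(ea), _complement(ra)
            if cea is not None and cra is not None and {cea, cra} == ref_set:
                ea, ra, strand = cea, cra, True
            else:
                log.record(rs, "dropped_allele_mismatch")
                continue

        if _is_palindromic(ea, ra):
            if policy.palindromic == "drop":
                log.record(rs, "dropped_palindromic")
                continue
            # freq-resolve: trust the frequency when it is informative
            eaf = row["eaf"]
            if pd.isna(eaf) or abs(rv.af2 - 0.5) <= policy.freq_margin:
                log.record(rs, "dropped_palindromic")
                continue
            if ea != rv.a2:
                ea, ra = ra, ea
                row["beta"], row["z"] = -row["beta"], -row["z"]
                eaf = 1.0 - eaf
            if (eaf > 0.5) != (rv.af2 > 0.5):
                row["beta"], row["z"] = -row["beta"], -row["z"]
                eaf = 1.0 - eaf
            row["ea"], row["ra"], row["eaf"] = ea, ra, eaf
            out_rows.append(row)
            log.record(rs, "strand_flipped" if strand else "ok")
            continue

        sign = False
        if ea == rv.a1:
            ea, ra = ra, ea
            row["beta"], row["z"] = -row["beta"], -row["z"]
            if not pd.isna(row["eaf"]):
                row["eaf"] = 1.0 - row["eaf"]
            sign = True
        row["ea"], row["ra"] = ea, ra
        out_rows.append(row)
        if strand:
            log.record(rs, "strand_flipped")
        elif sign:
            log.record(rs, "sign_flipped")
        elif pos_corrected:
            log.record(rs, "position_corrected")
        else:
            log.record(rs, "ok")

    out = pd.DataFrame(out_rows, columns=SCHEMA) if out_rows else pd.DataFrame(columns=SCHEMA)
    log.n_kept = len(out)
    return HarmonizedStudy(study_key=study_key, records=out.reset_index(drop=True), log=log)
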
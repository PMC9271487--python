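"""The reference table ("linkage disequilibrium catalogue" annotation).

The reference table is the per-variant annotation of the genotyped
reference population: identifier, coordinate, the two alleles stored in
lexicographic order (a1 < a2 bytewise), and the frequency of a2.  It is
the single coordinate and allele-orientation authority that every
summary-statistics study is harmonized against.

Building it from a panel applies the catalogue filters: duplicated
variants are collapsed to their first occurrence, monomorphic variants
and sex-chromosome rows are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

__all__ = [
    "ReferenceVariant",
    "ReferenceTable",
    "FilterLog",
    "build_reference_table",
    "DEFAULT_SEX_CHROMS",
]

#: .bim dialects label sex chromosomes differently; in the OAR assembly
#: numeric codes are used ("27" = X in sheep), elsewhere "X"/"Y".
DEFAULT_SEX_CHROMS: frozenset[str] = frozenset({"X", "Y", "XY", "MT", "27"})

_TSV_COLUMNS = ["rs_id", "chrom", "pos", "a1", "a2", "af2"]


@dataclass(frozen=True)
class ReferenceVariant:
    rs_id: str
    chrom: str
    pos: int
    a1: str  # lexicographically smaller allele
    a2: str  # lexicographically larger allele; af2 tracks this one
    af2: float


@dataclass
class FilterLog:
    """Counts of variants removed per catalogue filter rule."""

    input_variants: int = 0
    duplicates: int = 0
    monomorphic: int = 0
    sex_chrom: int = 0
    all_missing: int = 0

    @property
    def kept(self) -> int:
        return (
            self.input_variants
            - self.duplicates
            - self.monomorphic
            - self.sex_chrom
            - self.all_missing
        )


class ReferenceTable:
    """Per-variant catalogue with O(1) lookup by rs_id or (chrom, pos).

    Invariants: unique rs_id, unique (chrom, pos, a1, a2), a1 < a2
    bytewise, 0 < af2 < 1, no sex-chromosome rows (when built by
    :func:`build_reference_table`).
    """

    def __init__(self, rows: list[ReferenceVariant]):
        self.rows = list(rows)
        self._by_id: dict[str, ReferenceVariant] = {}
        self._by_locus: dict[tuple[str, int], list[ReferenceVariant]] = {}
        for r in self.rows:
            if r.rs_id in self._by_id:
                raise ValueError(f"duplicate rs_id in reference table: {r.rs_id}")
            if not r.a1 < r.a2:
                raise ValueError(f"{r.rs_id}: alleles not in lexicographic order")
            if not 0.0 < r.af2 < 1.0:
                raise ValueError(f"{r.rs_id}: af2 must be in (0, 1)")
            self._by_id[r.rs_id] = r
            self._by_locus.setdefault((r.chrom, r.pos), []).append(r)

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, rs_id: str) -> bool:
        return rs_id in self._by_id

    def get(self, rs_id: str) -> ReferenceVariant | None:
        return self._by_id.get(rs_id)

    def __getitem__(self, rs_id: str) -> ReferenceVariant:
        return self._by_id[rs_id]

    def at_locus(self, chrom: str, pos: int) -> list[ReferenceVariant]:
        return self._by_locus.get((chrom, pos), [])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.rs_id, r.chrom, r.pos, r.a1, r.a2, r.af2) for r in self.rows],
            columns=_TSV_COLUMNS,
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t", dtype={"rs_id": str, "chrom": str, "a1": str, "a2": str})
        rows = [
            ReferenceVariant(r.rs_id, r.chrom, int(r.pos), r.a1, r.a2, float(r.af2))
            for r in df.itertuples(index=False)
        ]
        return cls(rows)


def build_reference_table(
    panel: GenotypePanel,
    excluded_chroms: frozenset[str] | set[str] = DEFAULT_SEX_CHROMS,
) -> tuple[ReferenceTable, FilterLog]:
    """Apply the catalogue filters to ``panel`` and return the table.

    Filters, in order per variant: sex-chromosome exclusion, duplicate
    collapse (same rs_id, or same chrom+pos+unordered allele pair; first
    occurrence in file order wins), monomorphic removal (allele2
    frequency 0 or 1 among non-missing calls).  Alleles are stored with
    ``a1 < a2``; when the .bim order had allele1 > allele2, af2 is
    complemented so it keeps tracking the stored a2.
    """
    excluded = frozenset(excluded_chroms)
    log = FilterLog(input_variants=panel.n_variants)
    seen_ids: set[str] = set()
    seen_loci: set[tuple[str, int, frozenset[str]]] = set()
    rows: list[ReferenceVariant] = []

    for j, v in enumerate(panel.variants):
        if v.chrom in excluded:
            log.sex_chrom += 1
            continue
        locus_key = (v.chrom, v.pos, frozenset((v.allele1, v.allele2)))
        if v.rs_id in seen_ids or locus_key in seen_loci:
            log.duplicates += 1
            continue
        seen_ids.add(v.rs_id)
        seen_loci.add(locus_key)

        d = panel.dosages[:, j]
        called = d[d != MISSING]
        if called.size == 0:
            log.all_missing += 1
            continue
        af2 = float(called.sum()) / (2.0 * called.size)
        if af2 <= 0.0 or af2 >= 1.0:
            log.monomorphic += 1
            continue

        if v.allele1 < v.allele2:
            a1, a2, af = v.allele1, v.allele2, af2
        else:
            a1, a2, af = v.allele2, v.allele1, 1.0 - af2
        rows.append(ReferenceVariant(v.rs_id, v.chrom, v.pos, a1, a2, af))

    return ReferenceTable(rows), log
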
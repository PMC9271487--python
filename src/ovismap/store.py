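"""Local registry of harmonized studies and their metadata.

A single-file SQLite database plays the role the platform assigns to
its database pair: one table of study metadata (provenance, trait,
model, cohort size, QC verdict) and one table of harmonized association
records, joined on study_key.  Queries are read-only and return
denormalized :class:`AssociationHit` rows.
"""

from __future__ import annotations

import datetime
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DuplicateStudyError, QCNotPassedError, UnknownStudyError
from .sumstats import SCHEMA, HarmonizedStudy

__all__ = ["StudyMetadata", "AssociationHit", "Store"]


@dataclass
class StudyMetadata:
    """Provenance descriptors of a stored study.

    The platform's metadata list is longer than the core fields; extras
    (population subsets, model covariates, array name, ...) travel in
    the open ``extra`` mapping rather than being guessed as columns.
    """

    study_key: str
    trait_name: str
    publication: str = ""
    model_description: str = ""
    n_animals: int | None = None
    population: str = ""
    qc_passed: bool = False
    date_loaded: str = ""
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_animals is not None and self.n_animals <= 0:
            raise ValueError("n_animals must be positive when given")


@dataclass(frozen=True)
class AssociationHit:
    study_key: str
    trait_name: str
    rs_id: str
    chrom: str
    pos: int
    ea: str
    ra: str
    eaf: float
    beta: float
    se: float
    z: float
    p: float


_DDL = """
CREATE TABLE IF NOT EXISTS studies (
    study_key TEXT PRIMARY KEY,
    trait_name TEXT NOT NULL,
    publication TEXT,
    model_description TEXT,
    n_animals INTEGER,
    population TEXT,
    qc_passed INTEGER NOT NULL,
    date_loaded TEXT,
    extra TEXT,
    insertion_order INTEGER
);
CREATE TABLE IF NOT EXISTS associations (
    study_key TEXT NOT NULL REFERENCES studies(study_key),
    rs_id TEXT NOT NULL,
    chrom TEXT,
    pos INTEGER,
    ea TEXT,
    ra TEXT,
    eaf REAL,
    beta REAL,
    se REAL,
    z REAL,
    p REAL,
    n REAL
);
CREATE INDEX IF NOT EXISTS idx_assoc_rs ON associations(rs_id);
CREATE INDEX IF NOT EXISTS idx_assoc_region ON associations(study_key, chrom, pos);
"""


class Store:
    """Embedded registry; open with a path (":memory:" for ephemeral)."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._con = sqlite3.connect(self.path)
        self._con.executescript(_DDL)
        self._con.commit()

    def close(self) -> None:
        self._con.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- registration -------------------------------------------------

    def register_study(
        self,
        study: HarmonizedStudy,
        meta: StudyMetadata,
        require_qc: bool = True,
    ) -> str:
        """Store a harmonized study under its metadata key.

        Refuses a duplicate study_key, and (by default) a study whose
        metadata says it did not pass QC — only controlled data enter
        the registry.
        """
        if require_qc and not meta.qc_passed:
            raise QCNotPassedError(f"{meta.study_key}: study did not pass QC")
        cur = self._con.execute(
            "SELECT 1 FROM studies WHERE study_key = ?", (meta.study_key,)
        )
        if cur.fetchone() is not None:
            raise DuplicateStudyError(meta.study_key)

        order = self._con.execute(
            "SELECT COALESCE(MAX(insertion_order), 0) + 1 FROM studies"
        ).fetchone()[0]
        self._con.execute(
            "INSERT INTO studies VALUES (?,?,?,?,?,?,?,?,?,?)",
            (
                meta.study_key,
                meta.trait_name,
                meta.publication,
                meta.model_description,
                meta.n_animals,
                meta.population,
                int(meta.qc_passed),
                meta.date_loaded or datetime.datetime.now().isoformat(timespec="seconds"),
                json.dumps(meta.extra),
                order,
            ),
        )
        df = study.records[SCHEMA].copy()
        df.insert(0, "study_key", meta.study_key)
        df = df.rename(columns={})[["study_key"] + SCHEMA]
        df.to_sql("associations", self._con, if_exists="append", index=False)
        self._con.commit()
        return meta.study_key

    # -- queries ------------------------------------------------------

    def list_studies(self) -> list[StudyMetadata]:
        cur = self._con.execute(
            "SELECT study_key, trait_name, publication, model_description, "
            "n_animals, population, qc_passed, date_loaded, extra "
            "FROM studies ORDER BY insertion_order"
        )
        return [
            StudyMetadata(
                study_key=r[0],
                trait_name=r[1],
                publication=r[2],
                model_description=r[3],
                n_animals=r[4],
                population=r[5],
                qc_passed=bool(r[6]),
                date_loaded=r[7],
                extra=json.loads(r[8] or "{}"),
            )
            for r in cur.fetchall()
        ]

    def _hits(self, sql: str, params: tuple) -> list[AssociationHit]:
        cur = self._con.execute(sql, params)
        return [
            AssociationHit(
                study_key=r[0],
                trait_name=r[1],
                rs_id=r[2],
                chrom=r[3],
                pos=int(r[4]),
                ea=r[5],
                ra=r[6],
                eaf=r[7] if r[7] is not None else float("nan"),
                beta=r[8],
                se=r[9],
                z=r[10],
                p=r[11],
            )
            for r in cur.fetchall()
        ]

    def query_variant(self, rs_id: str) -> list[AssociationHit]:
        """All associations for one SNP across studies, ascending p."""
        return self._hits(
            "SELECT a.study_key, s.trait_name, a.rs_id, a.chrom, a.pos, a.ea, "
            "a.ra, a.eaf, a.beta, a.se, a.z, a.p "
            "FROM associations a JOIN studies s USING (study_key) "
            "WHERE a.rs_id = ? ORDER BY a.p ASC, a.study_key",
            (rs_id,),
        )

    def query_region(
        self, chrom: str, start: int, end: int, study_key: str
    ) -> list[AssociationHit]:
        """One study's associations with start <= pos <= end, by position."""
        if start > end:
            raise ValueError("start must be <= end")
        if not any(m.study_key == study_key for m in self.list_studies()):
            raise UnknownStudyError(study_key)
        return self._hits(
            "SELECT a.study_key, s.trait_name, a.rs_id, a.chrom, a.pos, a.ea, "
            "a.ra, a.eaf, a.beta, a.se, a.z, a.p "
            "FROM associations a JOIN studies s USING (study_key) "
            "WHERE a.study_key = ? AND a.chrom = ? AND a.pos BETWEEN ? AND ? "
            "ORDER BY a.pos ASC, a.rs_id",
            (study_key, str(chrom), start, end),
        )

    def study_records(self, study_key: str) -> pd.DataFrame:
        """The full harmonized record table of one study."""
        if not any(m.study_key == study_key for m in self.list_studies()):
            raise UnknownStudyError(study_key)
        return pd.read_sql_query(
            "SELECT " + ", ".join(SCHEMA) + " FROM associations WHERE study_key = ?",
            self._con,
            params=(study_key,),
        )
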
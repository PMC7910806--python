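"""Single-file embedded project database (SQLite).

One portable file holds everything: raw sheet ingests stored as close as
possible to their original form, the derived core tables that link samples
to taxa, images, wells and sequencing outcomes, and the audit tables that
keep every detected error permanently. Raw tables are append-only; every
derived table can be rebuilt from them, so provenance stays auditable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import ProjectConfig

SCHEMA_VERSION = 1

RAW_TABLES = (
    "raw_taxonomy",
    "raw_sampling",
    "raw_plates",
    "raw_yields",
    "raw_locus_recovery",
    "raw_photo_log",
)

VIOLATION_KINDS = (
    "duplicate_sample_id",
    "unreadable_code",
    "multi_taxon_mapping",
    "orphan_reference",
    "malformed_row",
)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE IF NOT EXISTS ingest_log (
    id INTEGER PRIMARY KEY,
    table_name TEXT NOT NULL,
    source TEXT NOT NULL,
    content_hash TEXT NOT NULL,
    n_rows INTEGER NOT NULL,
    duplicate_of INTEGER,
    ingested_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS raw_rows (
    table_name TEXT NOT NULL,
    ingest_id INTEGER NOT NULL,
    row_index INTEGER NOT NULL,
    row_json TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS violations (
    kind TEXT NOT NULL,
    subject TEXT NOT NULL,
    details TEXT NOT NULL,
    source TEXT NOT NULL,
    UNIQUE (kind, subject, details, source)
);
CREATE TABLE IF NOT EXISTS taxa (
    taxon_id TEXT PRIMARY KEY,
    family TEXT NOT NULL,
    accepted_name TEXT NOT NULL UNIQUE,
    synonyms TEXT NOT NULL DEFAULT ''
);
CREATE TABLE IF NOT EXISTS taxon_sample_links (
    taxon_id TEXT NOT NULL,
    sample_uuid TEXT NOT NULL,
    UNIQUE (taxon_id, sample_uuid),
    UNIQUE (sample_uuid)
);
CREATE TABLE IF NOT EXISTS sampling_events (
    event_id INTEGER PRIMARY KEY,
    sample_uuid TEXT NOT NULL,
    name_query TEXT NOT NULL,
    provider TEXT NOT NULL,
    provider_barcode TEXT,
    recorded_at TEXT,
    note TEXT
);
CREATE TABLE IF NOT EXISTS images (
    path TEXT PRIMARY KEY,
    content_hash TEXT NOT NULL,
    sample_uuid TEXT,
    event_id INTEGER,
    status TEXT NOT NULL CHECK (status IN ('linked','unreadable','duplicate'))
);
CREATE TABLE IF NOT EXISTS image_errors (
    path TEXT NOT NULL,
    content_hash TEXT NOT NULL,
    reason TEXT NOT NULL,
    UNIQUE (path, reason)
);
CREATE TABLE IF NOT EXISTS plates (
    plate_uuid TEXT PRIMARY KEY,
    plate_order INTEGER NOT NULL,
    entry_date TEXT,
    operator TEXT,
    notes TEXT
);
CREATE TABLE IF NOT EXISTS extraction_wells (
    plate_uuid TEXT NOT NULL,
    well TEXT NOT NULL,
    sample_uuid TEXT,
    UNIQUE (plate_uuid, well)
);
CREATE TABLE IF NOT EXISTS yields (
    sample_uuid TEXT PRIMARY KEY,
    total_dna_ng REAL NOT NULL CHECK (total_dna_ng >= 0)
);
CREATE TABLE IF NOT EXISTS sequencing_wells (
    dest_plate TEXT,
    dest_well TEXT,
    sample_uuid TEXT NOT NULL,
    decision TEXT NOT NULL CHECK (decision IN
        ('included','excluded_low_yield','excluded_quota_met')),
    yield_ng REAL
);
CREATE TABLE IF NOT EXISTS locus_recovery (
    sample_uuid TEXT NOT NULL,
    locus_id TEXT NOT NULL,
    reference_coverage REAL NOT NULL CHECK (reference_coverage >= 0),
    assembled_length INTEGER NOT NULL CHECK (assembled_length >= 0),
    high_copy INTEGER NOT NULL DEFAULT 0,
    UNIQUE (sample_uuid, locus_id)
);
CREATE TABLE IF NOT EXISTS qc_summary (
    sample_uuid TEXT PRIMARY KEY,
    n_loci_scored INTEGER NOT NULL,
    n_success INTEGER NOT NULL,
    fraction REAL NOT NULL,
    failed INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS stage_state (
    stage TEXT PRIMARY KEY,
    input_hash TEXT NOT NULL,
    completed_at TEXT NOT NULL
);
"""

# Tables derived (rebuildable) from the raw ingests + decoded images.
DERIVED_TABLES = (
    "taxa", "taxon_sample_links", "sampling_events", "plates",
    "extraction_wells", "yields", "locus_recovery", "qc_summary",
    "sequencing_wells", "violations",
)


@dataclass(frozen=True)
class AuditViolation:
    kind: str
    subject: str
    details: str
    source: str

    def __post_init__(self) -> None:
        if self.kind not in VIOLATION_KINDS:
            raise ValueError(f"unknown violation kind: {self.kind}")
        if not self.subject:
            raise ValueError("violation subject must be non-empty")

    def key(self) -> tuple[str, str, str, str]:
        return (self.kind, self.subject, self.details, self.source)


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


class ProjectDB:
    """Handle on the single-file project database."""

    def __init__(self, path: str | Path, config: ProjectConfig | None = None):
        self.path = Path(path)
        try:
            self.conn = sqlite3.connect(self.path)
        except sqlite3.OperationalError as e:
            raise OSError(f"cannot open database at {self.path}: {e}") from e
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_SCHEMA)
        stored = self._meta_get("schema_version")
        if stored is None:
            self._meta_set("schema_version", str(SCHEMA_VERSION))
        elif int(stored) != SCHEMA_VERSION:
            raise RuntimeError(
                f"database schema version {stored} does not match "
                f"supported version {SCHEMA_VERSION}")
        if config is not None:
            self._meta_set("config", json.dumps(
                config.__dict__, sort_keys=True))
        self.conn.commit()

    # -- lifecycle -----------------------------------------------------

    @classmethod
    def init_project(cls, config: ProjectConfig) -> "ProjectDB":
        """Create (or re-open) the project database named by the config.

        Idempotent: re-opening an existing database never destroys data.
        """
        path = Path(config.db_path)
        if path.parent != Path("") and not path.parent.exists():
            raise OSError(f"directory does not exist: {path.parent}")
        return cls(path, config=config)

    @property
    def config(self) -> ProjectConfig:
        raw = self._meta_get("config")
        if raw is None:
            return ProjectConfig(db_path=str(self.path))
        return ProjectConfig.from_dict(json.loads(raw))

    def close(self) -> None:
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def _meta_get(self, key: str) -> str | None:
        row = self.conn.execute(
            "SELECT value FROM meta WHERE key = ?", (key,)).fetchone()
        return None if row is None else row["value"]

    def _meta_set(self, key: str, value: str) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO meta (key, value) VALUES (?, ?)",
            (key, value))

    # -- raw ingests ---------------------------------------------------

    def ingest_raw_table(self, name: str, rows: list[list[str]],
                         source: str = "") -> int:
        """Store rows verbatim (header first) under a registered raw table.

        Ragged rows (width differing from the header) are skipped with a
        malformed_row violation. Re-ingesting a byte-identical table is
        flagged as a duplicate ingest and adds nothing.
        """
        if name not in RAW_TABLES:
            raise ValueError(f"unknown raw table: {name!r}")
        if not rows:
            raise ValueError("rows must include a header")
        header = rows[0]
        payload = json.dumps(rows, sort_keys=True).encode()
        digest = hashlib.sha256(payload).hexdigest()
        prior = self.conn.execute(
            "SELECT id FROM ingest_log WHERE table_name = ? AND content_hash = ?"
            " AND duplicate_of IS NULL", (name, digest)).fetchone()
        if prior is not None:
            self.conn.execute(
                "INSERT INTO ingest_log (table_name, source, content_hash,"
                " n_rows, duplicate_of, ingested_at) VALUES (?,?,?,?,?,?)",
                (name, source, digest, 0, prior["id"], _now()))
            self.conn.commit()
            return 0
        cur = self.conn.execute(
            "INSERT INTO ingest_log (table_name, source, content_hash,"
            " n_rows, duplicate_of, ingested_at) VALUES (?,?,?,?,NULL,?)",
            (name, source, digest, 0, _now()))
        ingest_id = cur.lastrowid
        n = 0
        for i, row in enumerate(rows[1:], start=1):
            if len(row) != len(header):
                self.add_violation(AuditViolation(
                    "malformed_row", f"{source or name}:row{i}",
                    f"expected {len(header)} fields, got {len(row)}", name))
                continue
            self.conn.execute(
                "INSERT INTO raw_rows (table_name, ingest_id, row_index,"
                " row_json) VALUES (?,?,?,?)",
                (name, ingest_id, i, json.dumps(dict(zip(header, row)))))
            n += 1
        self.conn.execute(
            "UPDATE ingest_log SET n_rows = ? WHERE id = ?", (n, ingest_id))
        self.conn.commit()
        return n

    def raw_frame(self, name: str) -> pd.DataFrame:
        """All non-duplicate rows of a raw table, in ingest order."""
        rows = self.conn.execute(
            "SELECT row_json FROM raw_rows WHERE table_name = ?"
            " ORDER BY ingest_id, row_index", (name,)).fetchall()
        return pd.DataFrame([json.loads(r["row_json"]) for r in rows])

    # -- violations ----------------------------------------------------

    def add_violation(self, v: AuditViolation) -> None:
        self.conn.execute(
            "INSERT OR IGNORE INTO violations (kind, subject, details, source)"
            " VALUES (?,?,?,?)", v.key())

    def violations(self) -> list[AuditViolation]:
        rows = self.conn.execute(
            "SELECT kind, subject, details, source FROM violations"
            " ORDER BY kind, subject, details, source").fetchall()
        return [AuditViolation(**dict(r)) for r in rows]

    def audit_integrity(self) -> list[AuditViolation]:
        """Every detected violation, in deterministic (kind, subject) order.

        Combines violations queued during ingest with structural checks on
        the derived tables; reports and never mutates.
        """
        found = {v.key(): v for v in self.violations()}

        def add(kind, subject, details, source):
            v = AuditViolation(kind, subject, details, source)
            found.setdefault(v.key(), v)

        # A sample UUID must not occupy wells on two plates (or two wells).
        for r in self.conn.execute(
                "SELECT sample_uuid, GROUP_CONCAT(plate_uuid || ':' || well)"
                " AS wells, COUNT(*) AS n FROM extraction_wells"
                " WHERE sample_uuid IS NOT NULL GROUP BY sample_uuid"
                " HAVING n > 1"):
            add("duplicate_sample_id", r["sample_uuid"],
                f"sample in multiple wells: {r['wells']}", "extraction_wells")
        # Every filled well must reference a sampling event.
        for r in self.conn.execute(
                "SELECT w.plate_uuid, w.well, w.sample_uuid FROM"
                " extraction_wells w LEFT JOIN sampling_events e"
                " ON e.sample_uuid = w.sample_uuid WHERE w.sample_uuid IS NOT"
                " NULL AND e.sample_uuid IS NULL"):
            add("orphan_reference", r["sample_uuid"],
                f"well {r['plate_uuid']}:{r['well']} references an unknown"
                " sample", "extraction_wells")
        # A sample must map to at most one taxon.
        for r in self.conn.execute(
                "SELECT sample_uuid, COUNT(DISTINCT taxon_id) AS n FROM"
                " taxon_sample_links GROUP BY sample_uuid HAVING n > 1"):
            add("multi_taxon_mapping", r["sample_uuid"],
                "sample linked to multiple taxa", "taxon_sample_links")
        return sorted(found.values(), key=lambda v: v.key())

    # -- rebuild support ----------------------------------------------

    def drop_derived(self) -> None:
        for t in DERIVED_TABLES:
            self.conn.execute(f"DELETE FROM {t}")
        self.conn.execute("DELETE FROM stage_state")
        self.conn.commit()

    def table_frame(self, name: str) -> pd.DataFrame:
        return pd.read_sql_query(
            f"SELECT * FROM {name} ORDER BY rowid", self.conn)

    def table_counts(self) -> dict[str, int]:
        names = [r["name"] for r in self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type = 'table'"
            " ORDER BY name")]
        return {
            n: self.conn.execute(f"SELECT COUNT(*) AS c FROM {n}").fetchone()["c"]
            for n in names
        }

    def derived_digest(self) -> str:
        """Deterministic digest over all derived tables (rebuild checks)."""
        h = hashlib.sha256()
        for t in DERIVED_TABLES:
            df = self.table_frame(t)
            if "event_id" in df.columns:
                df = df.drop(columns=["event_id"])
            order = [c for c in df.columns]
            df = df.sort_values(order).reset_index(drop=True)
            h.update(t.encode())
            h.update(df.to_csv(index=False).encode())
        return h.hexdigest()
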
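"""File ingestion: sampling sheets, photo batches, yields, locus recovery.

Everything enters through the raw tables and is then processed into the
derived tables, recording every error class on the way: malformed rows,
duplicated sample UUIDs (printer errors put the same code on two
envelopes), unreadable QR photographs, samples mapping to several taxa,
and references to unknown samples. Error rows are kept permanently;
corrections are added alongside, never by deleting evidence.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .datastore import AuditViolation, ProjectDB
from .identifiers import decode_qr, is_canonical_uuid
from .taxonomy import Taxonomy, link_sample

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def read_csv_rows(path: str | Path) -> list[list[str]]:
    """Raw CSV rows (header first), preserving ragged rows for auditing."""
    with open(path, newline="", encoding="utf-8") as fh:
        return [row for row in csv.reader(fh)]


def load_taxonomy(db: ProjectDB, rows: list[list[str]] | pd.DataFrame,
                  source: str = "taxonomy") -> int:
    """Ingest the master taxonomy and build its derived table.

    Returns the number of taxa stored. Duplicate accepted names or missing
    columns abort the ingest (a broken master taxonomy poisons every later
    stage).
    """
    if isinstance(rows, pd.DataFrame):
        rows = [list(rows.columns)] + rows.astype(str).values.tolist()
    db.ingest_raw_table("raw_taxonomy", rows, source)
    tax = Taxonomy.from_frame(db.raw_frame("raw_taxonomy"))
    db.conn.execute("DELETE FROM taxa")
    for rec in tax.records.values():
        db.conn.execute(
            "INSERT INTO taxa (taxon_id, family, accepted_name, synonyms)"
            " VALUES (?,?,?,?)",
            (rec.taxon_id, rec.family, rec.accepted_name,
             "|".join(rec.synonyms)))
    db.conn.commit()
    return len(tax)


def taxonomy_from_db(db: ProjectDB) -> Taxonomy:
    df = db.table_frame("taxa")
    if df.empty:
        raise RuntimeError("no taxonomy loaded")
    df = df.rename(columns={"accepted_name": "scientific_name"})
    return Taxonomy.from_frame(df)


def ingest_sampling_sheet(db: ProjectDB, rows: list[list[str]],
                          source: str = "sampling",
                          taxonomy: Taxonomy | None = None,
                          ) -> tuple[int, list[AuditViolation]]:
    """Ingest a sampling-event sheet (columns: uuid, name, provider,
    barcode optional, plus free extras).

    Every row with a canonical UUID becomes a sampling event (the envelope
    was scanned, so the event happened even when the UUID duplicates an
    earlier one); duplicates and name-resolution problems queue violations.
    Returns (events stored, violations added by this call).
    """
    db.ingest_raw_table("raw_sampling", rows, source)
    if taxonomy is None:
        taxonomy = taxonomy_from_db(db)
    before = {v.key() for v in db.violations()}
    header = [h.strip().lower() for h in rows[0]]
    for col in ("uuid", "name", "provider"):
        if col not in header:
            raise ValueError(f"sampling sheet missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    n_events = 0
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            continue  # already recorded as malformed by the raw ingest
        uuid = row[idx["uuid"]].strip().lower()
        name = row[idx["name"]].strip()
        provider = row[idx["provider"]].strip()
        barcode = row[idx["barcode"]].strip() if "barcode" in idx else None
        if not is_canonical_uuid(uuid):
            db.add_violation(AuditViolation(
                "malformed_row", f"{source}:row{i}",
                f"malformed uuid {uuid!r}", "sampling"))
            continue
        if not provider:
            db.add_violation(AuditViolation(
                "malformed_row", f"{source}:row{i}",
                "missing provider acronym", "sampling"))
            continue
        dup = db.conn.execute(
            "SELECT event_id FROM sampling_events WHERE sample_uuid = ?",
            (uuid,)).fetchone()
        if dup is not None:
            db.add_violation(AuditViolation(
                "duplicate_sample_id", uuid,
                f"uuid recorded again in {source} row {i} (first event"
                f" {dup['event_id']})", "sampling"))
        db.conn.execute(
            "INSERT INTO sampling_events (sample_uuid, name_query, provider,"
            " provider_barcode) VALUES (?,?,?,?)",
            (uuid, name, provider, barcode))
        n_events += 1
        link_sample(db, taxonomy, uuid, name)
    db.conn.commit()
    added = [v for v in db.violations() if v.key() not in before]
    return n_events, added


@dataclass
class ScanSummary:
    n_images: int
    n_linked: int
    n_unreadable: int
    n_duplicate_images: int
    n_duplicate_groups: int


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def ingest_photo_log(db: ProjectDB, rows: list[list[str]],
                     source: str = "photo_log") -> int:
    """Photo log mapping image filename -> provider barcode of the
    photographed specimen (written during sampling; used to attribute
    unreadable photos to their sampling events)."""
    return db.ingest_raw_table("raw_photo_log", rows, source)


def _photo_log_event_map(db: ProjectDB) -> dict[str, int]:
    """filename -> event_id via the provider barcode recorded in the log."""
    log = db.raw_frame("raw_photo_log")
    if log.empty:
        return {}
    barcode_events: dict[str, int] = {}
    for r in db.conn.execute(
            "SELECT event_id, provider_barcode FROM sampling_events"
            " WHERE provider_barcode IS NOT NULL"):
        barcode_events.setdefault(r["provider_barcode"], r["event_id"])
    out = {}
    for rec in log.itertuples(index=False):
        ev = barcode_events.get(str(rec.provider_barcode))
        if ev is not None:
            out[str(rec.filename)] = ev
    return out


def scan_image_batch(db: ProjectDB, directory: str | Path) -> ScanSummary:
    """Decode the QR code in every specimen photograph of a directory.

    Deterministic over file-name ordering and idempotent: an image already
    scanned (same path, same content) is skipped. A UUID decoded from
    distinct photographs of *different* sampling events marks all of those
    images as duplicates (two envelopes printed with the same code);
    repeated photographs of one event are consistent re-shoots, not errors.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    event_of = _photo_log_event_map(db)
    n_new_unreadable = 0
    for path in files:
        digest = _file_hash(path)
        prior = db.conn.execute(
            "SELECT content_hash FROM images WHERE path = ?",
            (path.name,)).fetchone()
        if prior is not None and prior["content_hash"] == digest:
            continue
        outcome = decode_qr(path)
        event_id = event_of.get(path.name)
        if outcome.ok:
            db.conn.execute(
                "INSERT OR REPLACE INTO images (path, content_hash,"
                " sample_uuid, event_id, status) VALUES (?,?,?,?,'linked')",
                (path.name, digest, outcome.uuid, event_id))
        else:
            db.conn.execute(
                "INSERT OR REPLACE INTO images (path, content_hash,"
                " sample_uuid, event_id, status)"
                " VALUES (?,?,NULL,?,'unreadable')",
                (path.name, digest, event_id))
            db.conn.execute(
                "INSERT OR IGNORE INTO image_errors (path, content_hash,"
                " reason) VALUES (?,?,?)", (path.name, digest, outcome.reason))
            db.add_violation(AuditViolation(
                "unreadable_code", path.name, outcome.reason or "unreadable",
                "images"))
            n_new_unreadable += 1

    # Recompute duplicate groups over all decoded images.
    db.conn.execute(
        "UPDATE images SET status = 'linked' WHERE status = 'duplicate'")
    dup_groups = 0
    dup_images = 0
    for r in db.conn.execute(
            "SELECT sample_uuid, COUNT(DISTINCT content_hash) AS n_img,"
            " COUNT(DISTINCT COALESCE(event_id, 'img:' || content_hash))"
            " AS n_ev FROM images WHERE sample_uuid IS NOT NULL"
            " GROUP BY sample_uuid HAVING n_img > 1 AND n_ev > 1").fetchall():
        dup_groups += 1
        db.conn.execute(
            "UPDATE images SET status = 'duplicate' WHERE sample_uuid = ?",
            (r["sample_uuid"],))
        paths = [row["path"] for row in db.conn.execute(
            "SELECT path FROM images WHERE sample_uuid = ? ORDER BY path",
            (r["sample_uuid"],))]
        dup_images += len(paths)
        db.add_violation(AuditViolation(
            "duplicate_sample_id", r["sample_uuid"],
            f"uuid decoded from {len(paths)} images of {r['n_ev']} events:"
            f" {', '.join(paths)}", "images"))
    # Violations for unreadable images are re-asserted from the error
    # table so a derived-table rebuild reproduces them even though the
    # images themselves are skipped as already scanned.
    for r in db.conn.execute(
            "SELECT path, reason FROM image_errors"):
        db.add_violation(AuditViolation(
            "unreadable_code", r["path"], r["reason"], "images"))
    db.conn.commit()
    counts = {s: n for s, n in db.conn.execute(
        "SELECT status, COUNT(*) FROM images GROUP BY status")}
    return ScanSummary(
        n_images=sum(counts.values()),
        n_linked=counts.get("linked", 0),
        n_unreadable=counts.get("unreadable", 0),
        n_duplicate_images=counts.get("duplicate", 0),
        n_duplicate_groups=dup_groups,
    )


@dataclass(frozen=True)
class ErrorRateSummary:
    n_events: int
    n_unreadable_images: int
    n_duplicate_groups: int
    n_duplicate_images: int
    unreadable_pct: float
    duplicate_pct: float
    overall_pct: float


class NoEventsError(RuntimeError):
    pass


def error_rate_summary(db: ProjectDB) -> ErrorRateSummary:
    """Sampling error rates as percentages of sampling events.

    The overall rate is the fraction of events affected by at least one
    error class (union semantics: an event both duplicated and unreadable
    counts once, so the overall rate can be below the component sum).
    Unreadable images are attributed to events through the photo log when
    present; otherwise each counts as a distinct affected event.
    """
    n_events = db.conn.execute(
        "SELECT COUNT(*) FROM sampling_events").fetchone()[0]
    if n_events == 0:
        raise NoEventsError("no sampling events ingested")

    unreadable_keys: set[object] = set()
    for r in db.conn.execute(
            "SELECT path, event_id FROM images WHERE status = 'unreadable'"):
        unreadable_keys.add(
            r["event_id"] if r["event_id"] is not None else f"img:{r['path']}")
    dup_keys: set[object] = set()
    n_dup_groups = 0
    n_dup_images = 0
    for r in db.conn.execute(
            "SELECT sample_uuid FROM images WHERE status = 'duplicate'"
            " GROUP BY sample_uuid"):
        n_dup_groups += 1
    for r in db.conn.execute(
            "SELECT path, event_id FROM images WHERE status = 'duplicate'"):
        n_dup_images += 1
        dup_keys.add(
            r["event_id"] if r["event_id"] is not None else f"img:{r['path']}")

    n_unreadable_images = db.conn.execute(
        "SELECT COUNT(*) FROM images WHERE status = 'unreadable'").fetchone()[0]
    return ErrorRateSummary(
        n_events=n_events,
        n_unreadable_images=n_unreadable_images,
        n_duplicate_groups=n_dup_groups,
        n_duplicate_images=n_dup_images,
        unreadable_pct=100.0 * len(unreadable_keys) / n_events,
        duplicate_pct=100.0 * len(dup_keys) / n_events,
        overall_pct=100.0 * len(unreadable_keys | dup_keys) / n_events,
    )


def ingest_yields(db: ProjectDB, rows: list[list[str]],
                  source: str = "yields") -> int:
    """Total-DNA quantification per sample (nanograms). Unknown UUIDs are
    orphan references; negative yields are malformed rows."""
    db.ingest_raw_table("raw_yields", rows, source)
    df = db.raw_frame("raw_yields")
    return _process_yields(db, df, source)


def _process_yields(db: ProjectDB, df: pd.DataFrame, source: str) -> int:
    n = 0
    known = {r["sample_uuid"] for r in db.conn.execute(
        "SELECT DISTINCT sample_uuid FROM sampling_events")}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        uuid = str(rec.sample_uuid).strip().lower()
        try:
            ng = float(rec.total_dna_ng)
        except (TypeError, ValueError):
            db.add_violation(AuditViolation(
                "malformed_row", f"{source}:row{i}",
                f"unparseable yield {rec.total_dna_ng!r}", "yields"))
            continue
        if ng < 0:
            db.add_violation(AuditViolation(
                "malformed_row", f"{source}:row{i}",
                f"negative yield {ng}", "yields"))
            continue
        if uuid not in known:
            db.add_violation(AuditViolation(
                "orphan_reference", uuid,
                "yield reported for unknown sample", "yields"))
            continue
        db.conn.execute(
            "INSERT OR REPLACE INTO yields (sample_uuid, total_dna_ng)"
            " VALUES (?,?)", (uuid, ng))
        n += 1
    db.conn.commit()
    return n


def ingest_locus_recovery(db: ProjectDB, rows: list[list[str]],
                          source: str = "locus_recovery") -> int:
    """Per (sample, locus) assembly summary: reference coverage, assembled
    length, high-copy flag. The (sample, locus) pair is unique; repeated
    pairs are rejected with a violation."""
    db.ingest_raw_table("raw_locus_recovery", rows, source)
    df = db.raw_frame("raw_locus_recovery")
    return _process_locus_recovery(db, df, source)


def _process_locus_recovery(db: ProjectDB, df: pd.DataFrame,
                            source: str) -> int:
    n = 0
    known = {r["sample_uuid"] for r in db.conn.execute(
        "SELECT DISTINCT sample_uuid FROM sampling_events")}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        uuid = str(rec.sample_uuid).strip().lower()
        locus = str(rec.locus_id).strip()
        try:
            cov = float(rec.coverage)
            length = int(float(rec.length_bp))
            high_copy = int(getattr(rec, "high_copy", 0) or 0)
        except (TypeError, ValueError):
            db.add_violation(AuditViolation(
                "malformed_row", f"{source}:row{i}", "unparseable locus row",
                "locus_recovery"))
            continue
        if cov < 0 or length < 0:
            db.add_violation(AuditViolation(
                "malformed_row", f"{source}:row{i}",
                f"negative coverage/length for {uuid}:{locus}",
                "locus_recovery"))
            continue
        if uuid not in known:
            db.add_violation(AuditViolation(
                "orphan_reference", uuid,
                f"locus recovery reported for unknown sample (locus {locus})",
                "locus_recovery"))
            continue
        cur = db.conn.execute(
            "INSERT OR IGNORE INTO locus_recovery (sample_uuid, locus_id,"
            " reference_coverage, assembled_length, high_copy)"
            " VALUES (?,?,?,?,?)", (uuid, locus, cov, length, high_copy))
        if cur.rowcount == 0:
            db.add_violation(AuditViolation(
                "malformed_row", f"{uuid}:{locus}",
                "duplicate (sample, locus) row rejected", "locus_recovery"))
            continue
        n += 1
    db.conn.commit()
    return n
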
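"""96-well extraction plates and the sequencing reformat.

Extraction plates are entered as spreadsheet-style templates (8 rows A-H x
12 columns) with a plate UUID and metadata block; entry fail-safes reject
duplicated sample IDs within and across plates before ingestion. At
submission time, samples are robotically reformatted onto destination
plates, excluding those under the 10-ng yield floor and those from genera
whose sequencing goal is already met.
"""

from __future__ import annotations

import csv
import io
import math
import uuid as _uuid
from dataclasses import dataclass, field
from pathlib import Path

from .config import ProjectConfig
from .datastore import AuditViolation, ProjectDB
from .identifiers import is_canonical_uuid
from .taxonomy import Taxonomy

ROWS = "ABCDEFGH"
COLS = range(1, 13)
WELLS = [f"{r}{c}" for r in ROWS for c in COLS]  # row-major, 96 wells


@dataclass
class PlateLayout:
    plate_uuid: str
    wells: dict[str, str | None] = field(
        default_factory=lambda: {w: None for w in WELLS})
    metadata: dict[str, str] = field(
        default_factory=lambda: {"entry_date": "", "operator": "", "notes": ""})

    def filled(self) -> list[tuple[str, str]]:
        return [(w, u) for w, u in self.wells.items() if u]


def new_plate_template(rng=None) -> PlateLayout:
    """A blank 96-well template with a fresh plate UUID."""
    if rng is not None:
        pu = str(_uuid.UUID(int=rng.getrandbits(128), version=4))
    else:
        pu = str(_uuid.uuid4())
    return PlateLayout(plate_uuid=pu)


def write_template(layout: PlateLayout, path: str | Path | None = None) -> str:
    """Spreadsheet-style CSV: metadata block, then the 8x12 grid."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["plate_uuid", layout.plate_uuid])
    for k in ("entry_date", "operator", "notes"):
        w.writerow([k, layout.metadata.get(k, "")])
    w.writerow([""] + [str(c) for c in COLS])
    for r in ROWS:
        w.writerow([r] + [layout.wells[f"{r}{c}"] or "" for c in COLS])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_template(source: str | Path) -> PlateLayout:
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source:
        text = Path(source).read_text()
    rows = list(csv.reader(io.StringIO(text)))
    head = {r[0]: (r[1] if len(r) > 1 else "") for r in rows[:4]}
    if "plate_uuid" not in head:
        raise ValueError("plate template missing plate_uuid")
    layout = PlateLayout(plate_uuid=head["plate_uuid"])
    layout.metadata = {k: head.get(k, "") for k in
                       ("entry_date", "operator", "notes")}
    grid = rows[5:13]
    if len(grid) != 8:
        raise ValueError("plate template grid must have 8 rows A-H")
    for r_label, row in zip(ROWS, grid):
        if row[0] != r_label:
            raise ValueError(f"unexpected grid row label {row[0]!r}")
        for c in COLS:
            cell = row[c].strip() if c < len(row) else ""
            layout.wells[f"{r_label}{c}"] = cell.lower() or None
    return layout


def validate_plate(layout: PlateLayout, db: ProjectDB) -> list[AuditViolation]:
    """Entry fail-safes: malformed UUIDs, duplicates within the plate,
    duplicates against every previously ingested plate, and samples with
    no sampling event. Returns violations (empty = ok); never raises."""
    out: list[AuditViolation] = []
    seen: dict[str, str] = {}
    known = {r["sample_uuid"] for r in db.conn.execute(
        "SELECT DISTINCT sample_uuid FROM sampling_events")}
    for well, u in layout.filled():
        if not is_canonical_uuid(u):
            out.append(AuditViolation(
                "malformed_row", f"{layout.plate_uuid}:{well}",
                f"not a canonical uuid: {u!r}", "plates"))
            continue
        if u in seen:
            out.append(AuditViolation(
                "duplicate_sample_id", u,
                f"wells {seen[u]}, {well} on plate {layout.plate_uuid}",
                "plates"))
            continue
        seen[u] = well
        prior = db.conn.execute(
            "SELECT plate_uuid, well FROM extraction_wells WHERE"
            " sample_uuid = ?", (u,)).fetchone()
        if prior is not None and prior["plate_uuid"] != layout.plate_uuid:
            out.append(AuditViolation(
                "duplicate_sample_id", u,
                f"already on plate {prior['plate_uuid']} well"
                f" {prior['well']}, re-entered at {layout.plate_uuid}:{well}",
                "plates"))
        if u not in known:
            out.append(AuditViolation(
                "orphan_reference", u,
                f"well {layout.plate_uuid}:{well} has no sampling event",
                "plates"))
    return sorted(out, key=lambda v: v.key())


def ingest_plate(db: ProjectDB, layout: PlateLayout,
                 source: str = "plate") -> list[AuditViolation]:
    """Validate then store a plate; offending wells are stored anyway with
    their violations queued (evidence is kept, never dropped)."""
    violations = validate_plate(layout, db)
    for v in violations:
        db.add_violation(v)
    prior = db.conn.execute(
        "SELECT plate_order FROM plates WHERE plate_uuid = ?",
        (layout.plate_uuid,)).fetchone()
    if prior is not None:
        order = prior["plate_order"]
    else:
        order = db.conn.execute(
            "SELECT COALESCE(MAX(plate_order), 0) + 1 FROM plates"
        ).fetchone()[0]
    db.conn.execute(
        "INSERT OR REPLACE INTO plates (plate_uuid, plate_order, entry_date,"
        " operator, notes) VALUES (?,?,?,?,?)",
        (layout.plate_uuid, order, layout.metadata.get("entry_date"),
         layout.metadata.get("operator"), layout.metadata.get("notes")))
    for well in WELLS:
        db.conn.execute(
            "INSERT OR REPLACE INTO extraction_wells (plate_uuid, well,"
            " sample_uuid) VALUES (?,?,?)",
            (layout.plate_uuid, well, layout.wells[well]))
    db.conn.commit()
    return violations


@dataclass(frozen=True)
class SequencingWell:
    dest_plate: str | None
    dest_well: str | None
    sample_uuid: str
    decision: str  # included | excluded_low_yield | excluded_quota_met
    yield_ng: float


class MissingYieldError(RuntimeError):
    pass


class MissingTaxonError(RuntimeError):
    pass


def reformat_for_sequencing(db: ProjectDB, taxonomy: Taxonomy | None = None,
                            config: ProjectConfig | None = None,
                            ) -> list[SequencingWell]:
    """Plan the reformatted submission plates.

    Samples are processed in deterministic order (plate ingest order, then
    row-major wells). A sample is included iff its yield is at least the
    10-ng floor AND its genus is still under quota at decision time
    (sequential greedy: earlier-plated samples win boundary ties). The
    per-genus goal defaults to half of the genus's accepted species;
    "samples" mode counts included samples against the same target.
    Included samples are packed row-major onto destination plates.
    """
    from .ingest import taxonomy_from_db

    config = config or db.config
    taxonomy = taxonomy or taxonomy_from_db(db)
    yields = {r["sample_uuid"]: r["total_dna_ng"] for r in db.conn.execute(
        "SELECT sample_uuid, total_dna_ng FROM yields")}
    taxon_of = {r["sample_uuid"]: r["taxon_id"] for r in db.conn.execute(
        "SELECT sample_uuid, taxon_id FROM taxon_sample_links")}
    species_counts = taxonomy.species_per_genus()
    quota_target = {
        g: max(1, math.ceil(config.quota_fraction * n))
        for g, n in species_counts.items()
    }

    ordered = db.conn.execute(
        "SELECT w.sample_uuid AS u FROM extraction_wells w JOIN plates p ON"
        " p.plate_uuid = w.plate_uuid WHERE w.sample_uuid IS NOT NULL"
        " ORDER BY p.plate_order, SUBSTR(w.well, 1, 1),"
        " CAST(SUBSTR(w.well, 2) AS INTEGER)").fetchall()

    included_species: dict[str, set[str]] = {}
    included_samples: dict[str, int] = {}
    decisions: list[SequencingWell] = []
    seen: set[str] = set()
    for row in ordered:
        u = row["u"]
        if u in seen:  # cross-plate duplicate: first placement decides
            continue
        seen.add(u)
        if u not in yields:
            if config.missing_yield_policy == "fatal":
                raise MissingYieldError(f"sample {u} has no yield record")
            db.add_violation(AuditViolation(
                "orphan_reference", u, "plated sample has no yield record",
                "sequencing"))
            decisions.append(SequencingWell(None, None, u,
                                            "excluded_low_yield", 0.0))
            continue
        ng = yields[u]
        if u not in taxon_of:
            raise MissingTaxonError(f"sample {u} has no taxon link")
        tid = taxon_of[u]
        genus = taxonomy.genus_of(tid)
        if ng < config.yield_min_ng:
            decisions.append(SequencingWell(None, None, u,
                                            "excluded_low_yield", ng))
            continue
        if config.quota_mode == "species":
            used = len(included_species.get(genus, ()))
        else:
            used = included_samples.get(genus, 0)
        if used >= quota_target.get(genus, 1):
            decisions.append(SequencingWell(None, None, u,
                                            "excluded_quota_met", ng))
            continue
        k = sum(1 for d in decisions if d.decision == "included")
        plate_no, well_no = divmod(k, 96)
        decisions.append(SequencingWell(
            f"SEQ-{plate_no + 1:03d}", WELLS[well_no], u, "included", ng))
        included_species.setdefault(genus, set()).add(tid)
        included_samples[genus] = included_samples.get(genus, 0) + 1

    db.conn.execute("DELETE FROM sequencing_wells")
    for d in decisions:
        db.conn.execute(
            "INSERT INTO sequencing_wells (dest_plate, dest_well,"
            " sample_uuid, decision, yield_ng) VALUES (?,?,?,?,?)",
            (d.dest_plate, d.dest_well, d.sample_uuid, d.decision, d.yield_ng))
    db.conn.commit()
    return decisions


def export_submission_manifest(wells: list[SequencingWell],
                               taxonomy: Taxonomy, taxon_of: dict[str, str],
                               path: str | Path,
                               exclusions_path: str | Path | None = None,
                               ) -> int:
    """Submission manifest CSV (included wells only) plus an exclusions
    side-file carrying every excluded sample and its reason."""
    included = [w for w in wells if w.decision == "included"]
    if not included:
        raise ValueError("no included wells: nothing to submit")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["dest_plate", "dest_well", "sample_uuid", "taxon_name",
                    "yield_ng"])
        for well in included:
            name = taxonomy.records[taxon_of[well.sample_uuid]].accepted_name
            w.writerow([well.dest_plate, well.dest_well, well.sample_uuid,
                        name, f"{well.yield_ng:g}"])
    if exclusions_path is not None:
        with open(exclusions_path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["sample_uuid", "reason", "yield_ng"])
            for well in wells:
                if well.decision != "included":
                    w.writerow([well.sample_uuid, well.decision,
                                f"{well.yield_ng:g}"])
    return len(included)


def import_submission_manifest(path: str | Path) -> list[SequencingWell]:
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append(SequencingWell(
                rec["dest_plate"], rec["dest_well"], rec["sample_uuid"],
                "included", float(rec["yield_ng"])))
    return out
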
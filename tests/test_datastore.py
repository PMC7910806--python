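"""Project database: raw ingests, audit, idempotence, rebuild."""

import pytest

from slims.config import ProjectConfig
from slims.datastore import AuditViolation, ProjectDB


def test_fresh_project_has_empty_tables(db):
    counts = db.table_counts()
    for name, n in counts.items():
        if name != "meta":
            assert n == 0, name


def test_reopen_preserves_data(tmp_path):
    cfg = ProjectConfig(db_path=str(tmp_path / "p.sqlite"))
    with ProjectDB.init_project(cfg) as db:
        db.ingest_raw_table("raw_yields",
                            [["sample_uuid", "total_dna_ng"], ["u", "5"]],
                            source="y.csv")
        before = db.table_counts()
    with ProjectDB.init_project(cfg) as db:
        assert db.table_counts() == before


def test_init_rejects_unwritable_path(tmp_path):
    cfg = ProjectConfig(db_path=str(tmp_path / "no_such_dir" / "p.sqlite"))
    with pytest.raises(OSError):
        ProjectDB.init_project(cfg)


def test_config_defaults_applied_and_persisted(tmp_path):
    cfg = ProjectConfig(db_path=str(tmp_path / "p.sqlite"))
    with ProjectDB.init_project(cfg) as db:
        stored = db.config
    assert stored.coverage_min == 6.0
    assert stored.length_min_bp == 350
    assert stored.failure_fraction == 0.05
    assert stored.yield_min_ng == 10.0


def test_raw_ingest_counts_and_ragged_rows(db):
    rows = [["a", "b"], ["1", "2"], ["3", "4"], ["5", "6"]]
    assert db.ingest_raw_table("raw_yields", rows, source="f.csv") == 3
    ragged = [["a", "b"], ["1", "2"], ["only-one"], ["3", "4"]]
    assert db.ingest_raw_table("raw_yields", ragged, source="g.csv") == 2
    kinds = [v.kind for v in db.violations()]
    assert kinds.count("malformed_row") == 1


def test_reingest_same_content_adds_nothing(db):
    rows = [["a"], ["1"], ["2"]]
    assert db.ingest_raw_table("raw_sampling", rows, source="s.csv") == 2
    assert db.ingest_raw_table("raw_sampling", rows, source="s.csv") == 0
    assert len(db.raw_frame("raw_sampling")) == 2


def test_unknown_raw_table_is_fatal(db):
    with pytest.raises(ValueError):
        db.ingest_raw_table("raw_nonsense", [["a"], ["1"]])


def test_violation_kind_and_subject_validated():
    with pytest.raises(ValueError):
        AuditViolation("bogus_kind", "x", "", "t")
    with pytest.raises(ValueError):
        AuditViolation("malformed_row", "", "", "t")


def test_audit_clean_project_is_empty(db):
    assert db.audit_integrity() == []


def test_audit_reports_cross_plate_duplicate(db):
    db.conn.execute(
        "INSERT INTO sampling_events (sample_uuid, name_query, provider)"
        " VALUES ('u1', 'x', 'NY')")
    for plate, well in [("P1", "A1"), ("P2", "B3")]:
        db.conn.execute(
            "INSERT INTO extraction_wells (plate_uuid, well, sample_uuid)"
            " VALUES (?,?, 'u1')", (plate, well))
    viols = db.audit_integrity()
    assert len(viols) == 1
    v = viols[0]
    assert v.kind == "duplicate_sample_id" and v.subject == "u1"
    assert "P1:A1" in v.details and "P2:B3" in v.details


def test_audit_is_deterministic_and_sorted(db):
    db.add_violation(AuditViolation("unreadable_code", "b.png", "x", "images"))
    db.add_violation(AuditViolation("malformed_row", "r1", "x", "s"))
    db.add_violation(AuditViolation("malformed_row", "r0", "x", "s"))
    keys = [(v.kind, v.subject) for v in db.audit_integrity()]
    assert keys == sorted(keys)
    assert keys == [(v.kind, v.subject) for v in db.audit_integrity()]


def test_rebuild_reproduces_derived_tables(sim_small_run, tmp_path):
    """Dropping all derived tables and re-running ingest+processing from the
    same inputs reproduces them exactly."""
    from slims.cli import run_all, _open_db
    out, manifest, db, _ = sim_small_run
    before = db.derived_digest()
    db.drop_derived()
    assert db.table_counts()["sampling_events"] == 0
    run_all(out, force=True)
    db2 = _open_db(out)
    try:
        assert db2.derived_digest() == before
    finally:
        db2.close()
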
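"""Sampling sheets, image batches, error rates, yields, locus tables."""

import numpy as np
import pytest
from PIL import Image

from slims.datastore import ProjectDB
from slims.identifiers import encode_qr, generate_uuids
from slims.ingest import (NoEventsError, error_rate_summary,
                          ingest_locus_recovery, ingest_photo_log,
                          ingest_sampling_sheet, ingest_yields,
                          load_taxonomy, scan_image_batch)

from conftest import TAXONOMY_ROWS


@pytest.fixture
def loaded_db(db):
    load_taxonomy(db, TAXONOMY_ROWS)
    return db


def _sheet(pairs):
    rows = [["uuid", "name", "provider", "barcode"]]
    for i, (u, name) in enumerate(pairs):
        rows.append([u, name, "NY", f"BC{i:04d}"])
    return rows


def test_clean_sheet_all_events_no_violations(loaded_db):
    uuids = generate_uuids(10, seed=1)
    n, viols = ingest_sampling_sheet(
        loaded_db, _sheet([(u, "Glycine soja") for u in uuids]))
    assert n == 10 and viols == []


def test_duplicate_uuid_across_rows(loaded_db):
    u = generate_uuids(1, seed=2)[0]
    n, viols = ingest_sampling_sheet(
        loaded_db, _sheet([(u, "Glycine soja"), (u, "Glycine soja")]))
    assert n == 2  # both envelopes were scanned: both events exist
    assert [v.kind for v in viols] == ["duplicate_sample_id"]


def test_malformed_uuid_skipped_with_violation(loaded_db):
    u = generate_uuids(1, seed=3)[0]
    n, viols = ingest_sampling_sheet(
        loaded_db, _sheet([(u, "Glycine soja"), ("oops", "Glycine max")]))
    assert n == 1
    assert [v.kind for v in viols] == ["malformed_row"]


def _write_photo(path, uuid=None, rng=None, scale=3):
    rng = rng or np.random.default_rng(0)
    img = np.full((260, 360), 235, dtype=np.uint8)
    for _ in range(6):
        x0, y0 = int(rng.integers(0, 300)), int(rng.integers(0, 200))
        img[y0:y0 + 20, x0:x0 + 20] = int(rng.integers(50, 150))
    if uuid is not None:
        q = np.asarray(encode_qr(uuid, scale=scale))
        img[30:30 + q.shape[0], 40:40 + q.shape[1]] = q
    Image.fromarray(img).save(path)


def test_scan_batch_links_unreadable_and_idempotent(loaded_db, tmp_path):
    uuids = generate_uuids(5, seed=4)
    ingest_sampling_sheet(
        loaded_db, _sheet([(u, "Glycine soja") for u in uuids]))
    rng = np.random.default_rng(1)
    d = tmp_path / "photos"
    d.mkdir()
    for i, u in enumerate(uuids):
        _write_photo(d / f"img_{i}.png", u, rng)
    _write_photo(d / "img_blank.png", None, rng)
    s = scan_image_batch(loaded_db, d)
    assert (s.n_images, s.n_linked, s.n_unreadable) == (6, 5, 1)
    assert s.n_duplicate_images == 0
    again = scan_image_batch(loaded_db, d)
    assert again.__dict__ == s.__dict__  # idempotent re-scan
    assert s.n_linked + s.n_unreadable == s.n_images


def test_scan_batch_flags_printer_duplicates(loaded_db, tmp_path):
    """The same UUID decoded from photos of two different events is a
    duplicate; a re-shoot of one event is not."""
    u1, u2 = generate_uuids(2, seed=5)
    rows = [["uuid", "name", "provider", "barcode"],
            [u1, "Glycine soja", "NY", "B1"],
            [u1, "Rosa palustris", "NY", "B2"],  # printer-duplicated code
            [u2, "Glycine max", "NY", "B3"]]
    ingest_sampling_sheet(loaded_db, rows)
    ingest_photo_log(loaded_db, [["filename", "provider_barcode"],
                                 ["a.png", "B1"], ["b.png", "B2"],
                                 ["c.png", "B3"], ["c2.png", "B3"]])
    rng = np.random.default_rng(2)
    d = tmp_path / "photos"
    d.mkdir()
    _write_photo(d / "a.png", u1, rng)
    _write_photo(d / "b.png", u1, rng)
    _write_photo(d / "c.png", u2, rng)
    _write_photo(d / "c2.png", u2, rng)  # re-shoot of event B3
    s = scan_image_batch(loaded_db, d)
    assert s.n_duplicate_groups == 1
    assert s.n_duplicate_images == 2  # a.png and b.png only
    rates = error_rate_summary(loaded_db)
    assert rates.duplicate_pct == pytest.approx(100 * 2 / 3)


def test_error_rates_simple_arithmetic(loaded_db, tmp_path):
    """300 events, 3 unreadable photos -> 1.00% unreadable and overall."""
    uuids = generate_uuids(300, seed=6)
    ingest_sampling_sheet(
        loaded_db, _sheet([(u, "Glycine soja") for u in uuids]))
    ingest_photo_log(loaded_db, [["filename", "provider_barcode"]] + [
        [f"u{i}.png", f"BC{i:04d}"] for i in range(3)])
    d = tmp_path / "photos"
    d.mkdir()
    rng = np.random.default_rng(3)
    for i in range(3):
        _write_photo(d / f"u{i}.png", None, rng)
    scan_image_batch(loaded_db, d)
    rates = error_rate_summary(loaded_db)
    assert rates.unreadable_pct == pytest.approx(1.00)
    assert rates.duplicate_pct == 0.0
    assert rates.overall_pct == pytest.approx(1.00)


def test_error_rates_union_semantics(sim_small_run):
    """Overall rate counts each affected event once, so it never exceeds
    the component sum, and equals the manifest's union exactly."""
    _, manifest, db, _ = sim_small_run
    rates = error_rate_summary(db)
    exp = manifest.expected_error_rates
    assert rates.unreadable_pct == pytest.approx(exp["unreadable_pct"])
    assert rates.duplicate_pct == pytest.approx(exp["duplicate_pct"])
    assert rates.overall_pct == pytest.approx(exp["overall_pct"])
    assert rates.overall_pct <= rates.unreadable_pct + rates.duplicate_pct


def test_error_rates_need_events(db):
    with pytest.raises(NoEventsError):
        error_rate_summary(db)


def test_yields_known_unknown_negative(loaded_db):
    uuids = generate_uuids(3, seed=7)
    ingest_sampling_sheet(
        loaded_db, _sheet([(u, "Glycine soja") for u in uuids]))
    other = generate_uuids(1, seed=8)[0]
    rows = [["sample_uuid", "total_dna_ng"],
            [uuids[0], "25.0"], [uuids[1], "3.5"],
            [other, "10.0"], [uuids[2], "-1"]]
    assert ingest_yields(loaded_db, rows) == 2
    kinds = sorted(v.kind for v in loaded_db.violations())
    assert kinds == ["malformed_row", "orphan_reference"]


def test_locus_recovery_duplicate_pair_rejected(loaded_db):
    u = generate_uuids(1, seed=9)[0]
    ingest_sampling_sheet(loaded_db, _sheet([(u, "Glycine soja")]))
    rows = [["sample_uuid", "locus_id", "coverage", "length_bp", "high_copy"],
            [u, "L1", "10", "500", "0"],
            [u, "L2", "2", "100", "0"],
            [u, "L1", "99", "999", "0"]]  # repeated (sample, locus)
    assert ingest_locus_recovery(loaded_db, rows) == 2
    stored = loaded_db.table_frame("locus_recovery")
    assert len(stored) == 2
    first = stored[stored.locus_id == "L1"].iloc[0]
    assert first["reference_coverage"] == 10  # first row wins
    assert any(v.kind == "malformed_row" and "duplicate (sample, locus)"
               in v.details for v in loaded_db.violations())
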
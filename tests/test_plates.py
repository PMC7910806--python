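"""Plate templates, entry fail-safes, and the sequencing reformat."""

import math

import pytest

from slims.config import ProjectConfig
from slims.ingest import ingest_sampling_sheet, ingest_yields, load_taxonomy
from slims.identifiers import generate_uuids
from slims.plates import (PlateLayout, WELLS, export_submission_manifest,
                          import_submission_manifest, ingest_plate,
                          new_plate_template, parse_template,
                          reformat_for_sequencing, validate_plate,
                          write_template)
from slims.taxonomy import Taxonomy

from conftest import TAXONOMY_ROWS


def test_template_has_96_empty_wells():
    layout = new_plate_template()
    assert len(layout.wells) == 96
    assert list(layout.wells) == WELLS
    assert all(v is None for v in layout.wells.values())
    assert WELLS[0] == "A1" and WELLS[-1] == "H12"


def test_two_templates_distinct_uuids():
    assert new_plate_template().plate_uuid != new_plate_template().plate_uuid


def test_template_round_trips_through_csv(tmp_path):
    layout = new_plate_template()
    uuids = generate_uuids(5, seed=1)
    for well, u in zip(["A1", "B7", "C12", "H1", "H12"], uuids):
        layout.wells[well] = u
    layout.metadata = {"entry_date": "2020-05-01", "operator": "hk",
                       "notes": "pilot"}
    path = tmp_path / "plate.csv"
    write_template(layout, path)
    back = parse_template(path)
    assert back.plate_uuid == layout.plate_uuid
    assert back.wells == layout.wells
    assert back.metadata == layout.metadata


@pytest.fixture
def project(db):
    load_taxonomy(db, TAXONOMY_ROWS)
    uuids = generate_uuids(8, seed=2)
    names = ["Glycine soja", "Glycine max", "Rosa palustris",
             "Rosa carolina", "Ulmus alata", "Glycine soja",
             "Rosa palustris", "Ulmus alata"]
    rows = [["uuid", "name", "provider", "barcode"]] + [
        [u, n, "NY", f"B{i}"] for i, (u, n) in enumerate(zip(uuids, names))]
    ingest_sampling_sheet(db, rows)
    return db, uuids


def test_validate_rejects_in_plate_duplicate(project):
    db, uuids = project
    layout = new_plate_template()
    layout.wells["A1"] = uuids[0]
    layout.wells["B3"] = uuids[0]
    viols = validate_plate(layout, db)
    assert len(viols) == 1
    assert viols[0].kind == "duplicate_sample_id"
    assert "A1" in viols[0].details and "B3" in viols[0].details


def test_validate_rejects_cross_plate_duplicate_and_orphan(project):
    db, uuids = project
    first = new_plate_template()
    first.wells["A1"] = uuids[0]
    assert ingest_plate(db, first) == []
    second = new_plate_template()
    second.wells["C2"] = uuids[0]                      # already plated
    second.wells["D4"] = generate_uuids(1, seed=99)[0]  # never sampled
    kinds = sorted(v.kind for v in validate_plate(second, db))
    assert kinds == ["duplicate_sample_id", "orphan_reference"]


def _plate_and_yield(db, uuids, ngs):
    layout = new_plate_template()
    for well, u in zip(WELLS, uuids):
        layout.wells[well] = u
    ingest_plate(db, layout)
    rows = [["sample_uuid", "total_dna_ng"]] + [
        [u, str(ng)] for u, ng in zip(uuids, ngs)]
    ingest_yields(db, rows)


def test_reformat_boundary_and_reasons(project):
    """9.9 ng is excluded, 10.0 ng included (strict 'below 10 ng')."""
    db, uuids = project
    _plate_and_yield(db, uuids[:5], [9.9, 10.0, 50, 50, 50])
    wells = reformat_for_sequencing(db)
    by_uuid = {w.sample_uuid: w for w in wells}
    assert by_uuid[uuids[0]].decision == "excluded_low_yield"
    assert by_uuid[uuids[1]].decision == "included"


def test_reformat_partition_and_quota(project):
    """Included + excluded_low_yield + excluded_quota_met partitions the
    plated samples; the genus quota (ceil(0.5 x species)) binds greedily in
    plate order."""
    db, uuids = project
    # 8 samples: Glycine x3 (2 species), Rosa x3 (2 species), Ulmus x2.
    _plate_and_yield(db, uuids, [50, 50, 50, 50, 50, 50, 50, 9.0])
    wells = reformat_for_sequencing(db)
    assert len(wells) == 8
    decisions = {w.sample_uuid: w.decision for w in wells}
    assert sorted(decisions.values()).count("included") + \
        sorted(decisions.values()).count("excluded_low_yield") + \
        sorted(decisions.values()).count("excluded_quota_met") == 8
    # Glycine has 2 accepted species -> quota 1: first sample only.
    assert decisions[uuids[0]] == "included"
    assert decisions[uuids[1]] == "excluded_quota_met"
    assert decisions[uuids[5]] == "excluded_quota_met"
    # Rosa: quota 1 of its 2 species.
    assert decisions[uuids[2]] == "included"
    assert decisions[uuids[3]] == "excluded_quota_met"
    # Ulmus: 1 species, quota 1; second Ulmus sample is low-yield anyway.
    assert decisions[uuids[4]] == "included"
    assert decisions[uuids[7]] == "excluded_low_yield"
    # Included wells are packed row-major onto the destination plate.
    included = [w for w in wells if w.decision == "included"]
    assert [w.dest_well for w in included] == WELLS[:len(included)]


def test_quota_monotonicity(project):
    """Raising the quota fraction never excludes a previously included
    sample."""
    db, uuids = project
    _plate_and_yield(db, uuids, [50] * 8)
    base = ProjectConfig(db_path="ignored", quota_fraction=0.5)
    high = ProjectConfig(db_path="ignored", quota_fraction=1.0)
    inc_base = {w.sample_uuid for w in reformat_for_sequencing(db, config=base)
                if w.decision == "included"}
    inc_high = {w.sample_uuid for w in reformat_for_sequencing(db, config=high)
                if w.decision == "included"}
    assert inc_base <= inc_high


def test_manifest_round_trip_and_exclusion_sidefile(project, tmp_path):
    db, uuids = project
    _plate_and_yield(db, uuids[:5], [50, 9.0, 50, 50, 50])
    taxonomy = Taxonomy.from_frame(
        __import__("pandas").DataFrame(TAXONOMY_ROWS[1:],
                                       columns=TAXONOMY_ROWS[0]))
    wells = reformat_for_sequencing(db, taxonomy)
    taxon_of = {r["sample_uuid"]: r["taxon_id"] for r in db.conn.execute(
        "SELECT sample_uuid, taxon_id FROM taxon_sample_links")}
    mpath = tmp_path / "manifest.csv"
    epath = tmp_path / "exclusions.csv"
    n = export_submission_manifest(wells, taxonomy, taxon_of, mpath, epath)
    back = import_submission_manifest(mpath)
    included = [w for w in wells if w.decision == "included"]
    assert n == len(included)
    assert {(w.dest_plate, w.dest_well, w.sample_uuid) for w in back} == \
        {(w.dest_plate, w.dest_well, w.sample_uuid) for w in included}
    # Excluded samples appear only in the side-file, with reasons.
    import csv
    with open(epath) as fh:
        excl = {r["sample_uuid"]: r["reason"] for r in csv.DictReader(fh)}
    assert set(excl) == {w.sample_uuid for w in wells
                         if w.decision != "included"}
    assert set(excl) & {w.sample_uuid for w in back} == set()


def test_manifest_export_requires_included(project, tmp_path):
    db, uuids = project
    _plate_and_yield(db, uuids[:2], [1.0, 2.0])
    taxonomy = Taxonomy.from_frame(
        __import__("pandas").DataFrame(TAXONOMY_ROWS[1:],
                                       columns=TAXONOMY_ROWS[0]))
    wells = reformat_for_sequencing(db, taxonomy)
    with pytest.raises(ValueError, match="no included wells"):
        export_submission_manifest(wells, taxonomy, {}, tmp_path / "m.csv")
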
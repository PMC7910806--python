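"""The synthetic-project generator and its ground-truth manifest."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from slims import fixtures
from slims.fixtures import (GroundTruthManifest, SimulationParams,
                            plant_family_effect, simulate_project)
from slims.qc import anova_by_family


def _tree_hash(root: Path) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    return out


def test_same_seed_byte_identical(tmp_path):
    params = SimulationParams(n_samples=60)
    simulate_project(tmp_path / "a", seed=5, params=params)
    simulate_project(tmp_path / "b", seed=5, params=params)
    assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")


def test_different_seed_differs(tmp_path):
    params = SimulationParams(n_samples=60, write_images=False)
    simulate_project(tmp_path / "a", seed=5, params=params)
    simulate_project(tmp_path / "b", seed=6, params=params)
    assert _tree_hash(tmp_path / "a") != _tree_hash(tmp_path / "b")


def test_manifest_serialises_losslessly(tmp_path):
    params = SimulationParams(n_samples=40, write_images=False)
    m = simulate_project(tmp_path, seed=3, params=params)
    back = GroundTruthManifest.from_json(tmp_path / "manifest.json")
    assert back == m


def test_zero_error_rates_zero_violations(tmp_path):
    from slims.cli import run_all, _open_db
    params = SimulationParams(n_samples=60, unreadable_rate=0,
                              duplicate_rate=0)
    m = simulate_project(tmp_path, seed=7, params=params)
    assert m.expected_violations == []
    run_all(tmp_path)
    db = _open_db(tmp_path)
    try:
        assert db.audit_integrity() == []
    finally:
        db.close()


def test_default_duplicate_rate_plants_76_pairs_at_16000(tmp_path):
    """At the default duplicate rate, a 16,000-event project carries 76
    printer-duplicated envelope pairs."""
    params = SimulationParams(n_samples=16000, write_images=False)
    m = simulate_project(tmp_path, seed=2, params=params)
    assert len(m.duplicate_pairs) == 76
    assert len(m.unreadable_images) >= round(0.0028 * 16000)


def test_infeasible_params_fatal(tmp_path):
    params = SimulationParams(n_samples=4, duplicate_rate=10.0)
    with pytest.raises(ValueError, match="duplicate pairs"):
        simulate_project(tmp_path, seed=1, params=params)


def test_plant_family_effect_degenerate_targets():
    _, eta = plant_family_effect({"A": 0.5, "B": 0.5}, 100, seed=1)
    assert eta == 0.0
    _, eta = plant_family_effect({"A": 1.0, "B": 0.0}, 100, seed=1)
    assert eta == 1.0
    with pytest.raises(ValueError):
        plant_family_effect({"A": 0.5}, 100)


def test_planted_eta_squared_recovered_at_n5000():
    """A planted family effect of eta^2 ~= 0.16 is recovered within +-0.02
    by the ANOVA at 5,000 samples."""
    n_loci = 86
    p_bar, eta_target = 0.872, 0.1589
    vw = n_loci * p_bar * (1 - p_bar)
    sd_p = np.sqrt(eta_target / (1 - eta_target) * vw) / n_loci
    offsets = np.linspace(-1.55, 1.55, 10)  # sd(offsets) ~= 1.0
    probs = {f"F{i:02d}": float(p_bar + o * sd_p)
             for i, o in enumerate(offsets)}
    df, eta_planted = plant_family_effect(probs, 500, n_loci=n_loci, seed=12)
    assert eta_planted == pytest.approx(eta_target, abs=0.03)
    res, _ = anova_by_family(df["n_success"], df["family"], min_n=50)
    assert res.eta_squared == pytest.approx(eta_planted, abs=0.02)


def test_manifest_determines_pipeline_outcomes(sim_small_run):
    """Violation sets, exclusion sets, QC failures and stage counts from a
    pipeline run equal the manifest exactly."""
    out, m, db, _ = sim_small_run
    viol = {(v.kind, v.subject) for v in db.audit_integrity()}
    assert viol == {tuple(v) for v in m.expected_violations}
    by_decision = {}
    for r in db.conn.execute(
            "SELECT decision, sample_uuid FROM sequencing_wells"):
        by_decision.setdefault(r["decision"], []).append(r["sample_uuid"])
    assert sorted(by_decision.get("included", [])) == m.expected_included
    assert sorted(by_decision.get("excluded_low_yield", [])) == \
        m.expected_excluded_low_yield
    assert sorted(by_decision.get("excluded_quota_met", [])) == \
        m.expected_excluded_quota
    failed = sorted(r["sample_uuid"] for r in db.conn.execute(
        "SELECT sample_uuid FROM qc_summary WHERE failed = 1"))
    assert failed == m.expected_failed
    qc_db = {r["sample_uuid"]: (r["n_loci_scored"], r["n_success"])
             for r in db.conn.execute(
                 "SELECT sample_uuid, n_loci_scored, n_success FROM"
                 " qc_summary")}
    qc_manifest = {u: (rec["n_scored"], rec["n_success"])
                   for u, rec in m.per_sample_recovery.items()}
    assert qc_db == qc_manifest
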
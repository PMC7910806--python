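import pandas as pd
import pytest

from slims import fixtures
from slims.config import ProjectConfig
from slims.datastore import ProjectDB
from slims.taxonomy import Taxonomy

TAXONOMY_ROWS = [
    ["family", "scientific_name", "synonyms", "taxon_id"],
    ["Fabaceae", "Glycine soja", "Glycine ussuriensis", "T1"],
    ["Fabaceae", "Glycine max", "", "T2"],
    ["Rosaceae", "Rosa palustris", "Rosa floridana|Rosa lancifolia", "T3"],
    ["Rosaceae", "Rosa carolina", "Rosa serrulata", "T4"],
    ["Ulmaceae", "Ulmus alata", "", "T5"],
]


@pytest.fixture
def small_taxonomy() -> Taxonomy:
    df = pd.DataFrame(TAXONOMY_ROWS[1:], columns=TAXONOMY_ROWS[0])
    return Taxonomy.from_frame(df)


@pytest.fixture
def db(tmp_path) -> ProjectDB:
    cfg = ProjectConfig(db_path=str(tmp_path / "test.sqlite"))
    handle = ProjectDB.init_project(cfg)
    yield handle
    handle.close()


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """Small simulated bundle with images, shared across read-only tests."""
    out = tmp_path_factory.mktemp("sim_small")
    params = fixtures.SimulationParams(n_samples=150)
    manifest = fixtures.simulate_project(out, seed=11, params=params)
    return out, manifest


@pytest.fixture(scope="session")
def sim_small_run(sim_small):
    """The small bundle after a full pipeline run (read-only)."""
    from slims.cli import run_all, _open_db
    out, manifest = sim_small
    summary = run_all(out)
    db = _open_db(out)
    yield out, manifest, db, summary
    db.close()
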
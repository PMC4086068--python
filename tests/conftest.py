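import pytest
from hypothesis import settings

import oratox as ox
from oratox import fixtures as fx

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_data():
    """Default synthetic reference set: rows + ground-truth manifest."""
    rows, manifest = ox.generate_fixture_db(ox.FixtureSpec(seed=1))
    return rows, manifest


@pytest.fixture(scope="session")
def db(fixture_data):
    rows, _ = fixture_data
    database, report = ox.build_database(rows)
    assert report.rows_rejected == 0
    return database


@pytest.fixture(scope="session")
def manifest(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def fragment_library(db):
    return ox.mine_fragment_library(db)


@pytest.fixture(scope="session")
def loo_similarity_only(db):
    """LOO-CV with the similarity search alone (FP24, median of 3, cutoff 0.7)."""
    return ox.loo_cross_validate(db, ox.PredictionConfig(use_fragments=False))


@pytest.fixture(scope="session")
def loo_with_fragments(db, fragment_library):
    return ox.loo_cross_validate(
        db, ox.PredictionConfig(use_fragments=True), fragment_library
    )


@pytest.fixture(scope="session")
def target_fixtures(db):
    """Three validated synthetic targets with ligands, decoys and fit tables."""
    fixtures = fx.generate_fixture_targets(n_targets=3, separation=2.0, seed=5, db=db)
    for target, vset in fixtures:
        ox.validate_toxicophores(target, vset)
    return fixtures
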
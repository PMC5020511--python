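import pytest

from geneora import fixtures
from geneora.model import DbName, GeneSet, GeneSetDatabase, IdKind


@pytest.fixture(scope="session")
def small_spec() -> fixtures.FixtureSpec:
    """A miniature benchmark spec: quick to generate, still overlapping."""
    return fixtures.FixtureSpec(
        n_terms=15, term_size_range=(4, 10), universe_size=150,
        list_size=12, signal_fraction=0.5, seed=11,
    )


@pytest.fixture(scope="session")
def small_db(small_spec):
    return fixtures.make_database(small_spec)


@pytest.fixture(scope="session")
def default_spec() -> fixtures.FixtureSpec:
    """The standard study condition (200 terms, 5000-gene pool, d=100)."""
    return fixtures.FixtureSpec(seed=5)


@pytest.fixture
def tiny_db() -> GeneSetDatabase:
    """Three hand-written sets over a 6-gene universe, for exact assertions."""
    return GeneSetDatabase(
        db_name=DbName.REACTOME,
        organism="hsa",
        sets=(
            GeneSet("T1", "alpha", frozenset({"A", "B", "C"})),
            GeneSet("T2", "beta", frozenset({"B", "C", "D"})),
            GeneSet("T3", "gamma", frozenset({"E", "F"})),
        ),
        id_kind=IdKind.SYM,
    )


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory, small_spec):
    """The small fixture database serialized in every dialect."""
    out = tmp_path_factory.mktemp("dialects")
    return fixtures.write_dialect_files(small_spec, out)
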
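import pytest

from linckit.core_io import Config, read_fasta
from linckit.families import SpeciesPanel, build_families
from linckit.fixtures import FixtureSpec, make_identify_fixture, make_panel_fixture
from linckit.search import BuiltinSearchEngine


@pytest.fixture(scope="session")
def cfg():
    return Config()


@pytest.fixture(scope="session")
def engine():
    return BuiltinSearchEngine()


@pytest.fixture(scope="session")
def identify_fixture(tmp_path_factory):
    """Small planted-truth transcript assembly spanning every class."""
    spec = FixtureSpec(
        seed=7, n_coding=15, n_coding_by_hit=3, n_lincrna=12, n_cage=4,
        n_known_overlap=3, n_te=6, n_sot=6, n_aot=6, n_short=5, n_ambiguous=3,
    )
    return make_identify_fixture(spec, tmp_path_factory.mktemp("idfx"))


@pytest.fixture(scope="session")
def panel_fixture(tmp_path_factory):
    """Five-species evolved panel: 20 queries, one deep loss, one duplication."""
    spec = FixtureSpec(
        seed=11, n_panel_queries=20, substitution_rate=0.03,
        loss_species={"LINC002": ["SpD", "SpE"]},
        duplication_species={"LINC003": ["SpB"]},
    )
    return make_panel_fixture(spec, tmp_path_factory.mktemp("panelfx"))


@pytest.fixture(scope="session")
def panel_build(panel_fixture, engine, cfg):
    """Family build over the session panel (default 1e-20 cutoff, paralogs kept)."""
    panel = SpeciesPanel.from_file(panel_fixture.species_list)
    queries = read_fasta(panel_fixture.queries)
    result = build_families(
        queries, panel, engine, cfg,
        query_loci=panel_fixture.query_loci, include_paralogs=True,
    )
    return panel, queries, result
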
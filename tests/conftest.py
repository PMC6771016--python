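import pytest

from virotriage.kmer_taxonomy import Taxonomy
from virotriage.synthetic import SimulationConfig, make_fixture


@pytest.fixture(scope="session")
def small_taxonomy() -> Taxonomy:
    """root(1) -> genus 10 (species 100, 101), genus 11 (species 102)."""
    return Taxonomy.from_nodes({
        1: (1, "root", "root"),
        10: (1, "genus", "genus_a"),
        11: (1, "genus", "genus_b"),
        100: (10, "species", "sp_a1"),
        101: (10, "species", "sp_a2"),
        102: (11, "species", "sp_b1"),
    })


@pytest.fixture(scope="session")
def standard_fixture() -> dict:
    """The default synthetic world, generated once per test session."""
    return make_fixture(SimulationConfig(seed=1))


@pytest.fixture
def fixture_dir(standard_fixture, tmp_path):
    from virotriage.synthetic import write_fixture

    return write_fixture(standard_fixture, tmp_path / "fixture")
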
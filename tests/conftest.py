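import numpy as np
import pytest

from iabkit.fixtures import make_fixtures, make_toy_receptor, make_vh_panel
from iabkit.grafting import PositionFrequencyTable, load_graft_sets
from iabkit.numbering import load_references, number_vh


@pytest.fixture(scope="session")
def references():
    return load_references()


@pytest.fixture(scope="session")
def graft_sets():
    return load_graft_sets()


@pytest.fixture(scope="session")
def freq_table():
    return PositionFrequencyTable.from_tsv()


@pytest.fixture(scope="session")
def vh_panel():
    return make_vh_panel(seed=0)


@pytest.fixture(scope="session")
def numbered_panel(vh_panel, references):
    return [number_vh(seq, references) for seq in vh_panel]


@pytest.fixture(scope="session")
def toy_receptor():
    """(ecd, structure, records, planted_epitope, decoy_position)"""
    return make_toy_receptor(seed=11)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    return make_fixtures(seed=7, outdir=tmp_path_factory.mktemp("bundle"))
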
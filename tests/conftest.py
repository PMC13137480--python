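import pytest

from peptax.fixtures import curated_fixture
from peptax.molgraph import parse_smiles
from peptax.taxonomy import build_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return build_taxonomy()


@pytest.fixture
def fixture_mol():
    """Parse a curated fixture by name."""

    def _load(name):
        smiles, _ = curated_fixture(name)
        return parse_smiles(smiles, name)

    return _load
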
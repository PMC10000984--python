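import pytest

from consenstax.fixtures import FixtureSpec, make_taxonomy, write_taxdump
from consenstax.taxonomy import TaxNode, Taxonomy

# Hand-built vertebrate mini-tree with real NCBI taxids, used across tests.
# Lineage of Bos taurus spans 7 nodes: root > Vertebrata > Mammalia >
# Cetartiodactyla > Bovidae > Bos > Bos taurus.
_BOVID_NODES = [
    # taxid, parent, rank, name
    (1, 1, "no rank", "root"),
    (7742, 1, "clade", "Vertebrata"),
    (40674, 7742, "class", "Mammalia"),
    (91561, 40674, "order", "Cetartiodactyla"),
    (9895, 91561, "family", "Bovidae"),
    (9903, 9895, "genus", "Bos"),
    (9913, 9903, "species", "Bos taurus"),
    (9915, 9903, "species", "Bos indicus"),
    (9904, 9895, "genus", "Bison"),
    (9901, 9904, "species", "Bison bison"),
    (9821, 91561, "family", "Suidae"),
    (9822, 9821, "genus", "Sus"),
    (9823, 9822, "species", "Sus scrofa"),
    (8782, 7742, "class", "Aves"),
    (9005, 8782, "family", "Phasianidae"),
    (9030, 9005, "genus", "Gallus"),
    (9031, 9030, "species", "Gallus gallus"),
]

# taxid 9917 is treated as merged into Bos taurus in the dump fixtures
BOVID_MERGED = {9917: 9913}


def bovid_nodes() -> dict[int, TaxNode]:
    return {t: TaxNode(t, p, r, n) for t, p, r, n in _BOVID_NODES}


@pytest.fixture(scope="session")
def tax() -> Taxonomy:
    return Taxonomy(bovid_nodes(), merged=BOVID_MERGED)


@pytest.fixture(scope="session")
def taxdump_dir(tmp_path_factory):
    """The bovid tree written out in the NCBI dmp dialect."""
    out = tmp_path_factory.mktemp("taxdump")
    write_taxdump(Taxonomy(bovid_nodes()), out, merged=BOVID_MERGED)
    return out


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fixture_tax(fixture_spec) -> Taxonomy:
    return make_taxonomy(fixture_spec)
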
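import pytest

from retroprompt.data import ReactionRecord
from retroprompt.toychem import ToyDatasetParams, generate_dataset


def _rec(id, precursors, product):
    return ReactionRecord(id=id, precursors=tuple(precursors), product=product)


@pytest.fixture
def cleaning_fixture():
    """Hand-built records exercising one rule each: a duplicate pair, a
    two-product reaction, a single-atom product, an over-charged product,
    and two clean reactions. Three records survive."""
    return [
        _rec("clean-ester", ["CC(=O)O", "OCC"], "CC(=O)OCC"),
        _rec("dup-a", ["CCO", "BrCC"], "CCOCC"),
        _rec("dup-b", ["CCO", "BrCC"], "CCOCC"),
        _rec("two-products", ["CCO"], "CC=O.CCOCC"),
        _rec("single-atom", ["[NaH]"], "[Na+]"),
        _rec("charge-3", ["OP(O)(O)=O"], "[O-]P([O-])([O-])=O"),
        _rec("clean-thioether", ["CCS", "BrC"], "CCSC"),
    ]


@pytest.fixture(scope="session")
def toy_records():
    """A small deterministic toy corpus shared across test modules."""
    return generate_dataset(
        ToyDatasetParams(n_reactions=200, n_families=4, seed=11)
    )
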
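import numpy as np
import pytest

from rnarefine.rna_io import CATALOG, Atom, Residue, RnaStructure, element_of
from rnarefine.synthetic_fixtures import (
    ideal_duplex,
    ideal_hairpin,
    nucleotide_template,
    single_strand,
)


def residue_from_template(base: str, chain_id: str = "A", auth: int = 1,
                          index: int = 0, offset=(0.0, 0.0, 0.0)) -> Residue:
    """A complete residue at idealized template geometry."""
    r = Residue(chain_id=chain_id, auth_number=auth, index=index, base=base, atoms={})
    for name, pos in nucleotide_template(base).items():
        r.atoms[name] = Atom(name, element_of(name), np.asarray(pos) + np.asarray(offset))
    return r


def structure_of(residues, sid="fixture") -> RnaStructure:
    chains: dict[str, list[Residue]] = {}
    for r in residues:
        chains.setdefault(r.chain_id, []).append(r)
    s = RnaStructure(id=sid, chains=list(chains.values()))
    s.reindex()
    return s


@pytest.fixture(scope="session")
def adenosine() -> RnaStructure:
    """One complete adenosine (22 heavy atoms)."""
    return structure_of([residue_from_template("A")], sid="adenosine")


@pytest.fixture(scope="session")
def duplex6():
    """A 6-bp ideal duplex with its planted pairs and dot-bracket."""
    return ideal_duplex("GCAUGC", structure_id="duplex6")


@pytest.fixture(scope="session")
def hairpin():
    return ideal_hairpin("GCAG", "UUCG", structure_id="hairpin4x4")


@pytest.fixture(scope="session")
def strand6() -> RnaStructure:
    return single_strand("GCAUGC", structure_id="strand6")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
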
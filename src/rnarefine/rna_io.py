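"""Reading, cleaning and writing RNA structures.

The in-memory currency of the package is :class:`RnaStructure`: ordered
chains of ordered residues, each residue holding named heavy atoms with 3D
coordinates in Å. Parsing and PDB/mmCIF serialisation are delegated to
`gemmi`; this module adds the RNA-specific policy on top (heavy atoms only,
altloc resolution, rejection of modified nucleotides) and houses the
canonical 85-entry heavy-atom catalog and the five-point coarse-grained
selection used throughout the pipeline.
"""

from __future__ import annotations

import copy as _copy
import functools
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    FormatError,
    IntegrityError,
    MissingFivePointError,
    ModifiedNucleotideError,
)

STANDARD_BASES = ("A", "U", "G", "C")

#: Sugar-phosphate heavy atoms shared by all four nucleotides (no OP3, no H).
SUGAR_PHOSPHATE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
)

#: Base heavy atoms per nucleotide, in a fixed canonical order.
BASE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

#: Three base atoms of the five-point coarse-grained representation.
FIVE_POINT_BASE_ATOMS = {
    "A": ("N9", "C6", "C2"),
    "G": ("N9", "C6", "C2"),
    "C": ("N1", "N3", "C5"),
    "U": ("N1", "N3", "C5"),
}

PURINES = ("A", "G")
PYRIMIDINES = ("C", "U")

# Common modified-nucleotide residue names; presence triggers rejection in
# clean_structure rather than silent dropping.
MODIFIED_NUCLEOTIDES = frozenset({
    "PSU", "H2U", "5MC", "5MU", "1MA", "2MG", "M2G", "7MG", "OMC", "OMG",
    "OMU", "4SU", "I", "YG", "1MG", "M7G", "A2M", "MIA", "T6A", "UR3",
})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def five_point_names(base: str) -> tuple[str, ...]:
    """The 5 anchor atom names of a nucleotide: C4', C1' and 3 base atoms."""
    return ("C4'", "C1'") + FIVE_POINT_BASE_ATOMS[base]


class CanonicalAtomCatalog:
    """The 85 canonical heavy atoms of the four standard ribonucleotides.

    12 sugar-phosphate atoms per base plus 10/11/8/8 base atoms for A/G/C/U.
    Provides a bijection between (base, atom-name) pairs and indices 0..84,
    used as the atom-identity one-hot in graph encoding.
    """

    def __init__(self) -> None:
        self._names: dict[str, tuple[str, ...]] = {
            b: SUGAR_PHOSPHATE_ATOMS + BASE_ATOMS[b] for b in STANDARD_BASES
        }
        self._index: dict[tuple[str, str], int] = {}
        for b in STANDARD_BASES:
            for name in self._names[b]:
                self._index[(b, name)] = len(self._index)

    def names(self, base: str) -> tuple[str, ...]:
        return self._names[base]

    def index(self, base: str, name: str) -> int:
        return self._index[(base, name)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._index

    def __len__(self) -> int:
        return len(self._index)


#: Module-level singleton; the catalog is immutable.
CATALOG = CanonicalAtomCatalog()


def element_of(name: str) -> str:
    """Chemical element implied by a PDB heavy-atom name (C/N/O/P)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise FormatError(f"cannot derive element from atom name {name!r}")


@dataclass
class Atom:
    """A named heavy atom with Cartesian coordinates in Å."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise IntegrityError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    """One nucleotide: chain id, author numbering, 0-based index, base, atoms."""

    chain_id: str
    auth_number: int
    index: int
    base: str
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def is_purine(self) -> bool:
        return self.base in PURINES

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].position

    def has(self, name: str) -> bool:
        return name in self.atoms


@dataclass
class RnaStructure:
    """Chains of residues; the universal container of the pipeline."""

    id: str
    chains: list[list[Residue]]
    provenance: str = ""

    @property
    def residues(self) -> list[Residue]:
        """All residues flattened in chain order (global 0-based indexing)."""
        return [r for chain in self.chains for r in chain]

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def sequence(self) -> str:
        """Concatenated sequence over all chains."""
        return "".join(r.base for r in self.residues)

    def chain_of(self, global_index: int) -> int:
        """Chain number owning the residue at a global index."""
        offset = 0
        for ci, chain in enumerate(self.chains):
            if global_index < offset + len(chain):
                return ci
            offset += len(chain)
        raise IndexError(global_index)

    def chain_bounds(self) -> list[tuple[int, int]]:
        """Per chain, the (start, stop) global-index half-open interval."""
        bounds, offset = [], 0
        for chain in self.chains:
            bounds.append((offset, offset + len(chain)))
            offset += len(chain)
        return bounds

    def copy(self) -> "RnaStructure":
        return _copy.deepcopy(self)

    def reindex(self) -> None:
        """Re-assign contiguous 0-based per-chain residue indices."""
        for chain in self.chains:
            for i, r in enumerate(chain):
                r.index = i


def _looks_like_nucleotide(residue: gemmi.Residue) -> bool:
    names = {a.name for a in residue}
    return "C1'" in names and "O4'" in names


def _resolve_altlocs(residue: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc 'A'."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
            continue
        key = (atom.occ, -ord(atom.altloc or "A"))
        prev_key = (prev.occ, -ord(prev.altloc or "A"))
        if key > prev_key:
            chosen[atom.name] = atom
    return chosen


def read_structure(source: str | os.PathLike, fmt: str | None = None) -> RnaStructure:
    """Read a PDB or mmCIF structure (path or literal text).

    Captures ATOM records of polymer residues; HETATM entities, waters,
    hydrogens and lower-occupancy altlocs are dropped. Raises
    :class:`FormatError` on unparseable input and
    :class:`EmptyStructureError` when no nucleic residue survives.
    """
    text: str | None = None
    path: str | None = None
    src = os.fspath(source) if isinstance(source, os.PathLike) else source
    if isinstance(src, str) and ("\n" in src or src.lstrip().startswith(("ATOM", "HETATM", "data_"))):
        text = src
    else:
        path = str(src)

    if fmt is None:
        probe = text if text is not None else path
        fmt = "mmcif" if (probe.lstrip().startswith("data_") or str(probe).endswith((".cif", ".mmcif"))) else "pdb"

    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text) if text is not None else gemmi.read_pdb(path)
        elif fmt == "mmcif":
            doc = gemmi.cif.read_string(text) if text is not None else gemmi.cif.read(path)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {fmt} input: {exc}") from exc

    st.setup_entities()
    chains: list[list[Residue]] = []
    n_nucleic = 0
    for model in st:
        for chain in model:
            residues: list[Residue] = []
            for res in chain:
                if res.het_flag == "H" or res.name in _WATER_NAMES:
                    continue
                atoms = _resolve_altlocs(res)
                if not atoms:
                    continue
                base = res.name.strip()
                if _looks_like_nucleotide(res):
                    n_nucleic += 1
                out = Residue(
                    chain_id=chain.name,
                    auth_number=res.seqid.num,
                    index=len(residues),
                    base=base,
                    atoms={},
                )
                for name, a in atoms.items():
                    el = a.element.name.upper() if a.element.name else element_of(name)
                    out.atoms[name] = Atom(name=name, element=el,
                                           position=np.array([a.pos.x, a.pos.y, a.pos.z]))
                residues.append(out)
            if residues:
                chains.append(residues)
        break  # first model only
    if n_nucleic == 0:
        raise EmptyStructureError("no RNA residues found in input")
    ident = st.name or (os.path.basename(path) if path else "structure")
    return RnaStructure(id=ident, chains=chains, provenance=f"read:{fmt}")


def clean_structure(raw: RnaStructure) -> RnaStructure:
    """Retain only standard RNA residues (A/U/G/C); reject modified ones.

    Proteins, ions, ligands and other non-RNA residues are silently removed.
    A residue recognisably a nucleotide but not a standard ribonucleotide
    raises :class:`ModifiedNucleotideError` — such entries are excluded from
    the supported chemical space rather than coerced.
    """
    chains: list[list[Residue]] = []
    for chain in raw.chains:
        kept: list[Residue] = []
        for r in chain:
            if r.base in STANDARD_BASES:
                if not r.atoms:
                    raise IntegrityError(
                        f"residue {r.chain_id}{r.auth_number} has zero atoms")
                kept.append(_copy.deepcopy(r))
            elif r.base in MODIFIED_NUCLEOTIDES or _nucleotide_like(r):
                raise ModifiedNucleotideError(
                    f"non-standard nucleotide {r.base!r} at {r.chain_id}{r.auth_number}")
            # else: protein / ion / ligand → dropped
        if kept:
            chains.append(kept)
    if not chains:
        raise EmptyStructureError("no standard RNA residues after cleaning")
    out = RnaStructure(id=raw.id, chains=chains, provenance=raw.provenance + "|cleaned")
    out.reindex()
    return out


def _nucleotide_like(r: Residue) -> bool:
    return "C1'" in r.atoms and "O4'" in r.atoms and "O2'" in r.atoms


def detect_missing_atoms(s: RnaStructure) -> list[tuple[Residue, list[str]]]:
    """Per residue, catalog atoms that are absent.

    5'-terminal residues are exempt from P/OP1/OP2 flags: deposited
    structures routinely lack the terminal phosphate and it should not
    trigger reconstruction.
    """
    out: list[tuple[Residue, list[str]]] = []
    for chain in s.chains:
        for r in chain:
            expected = set(CATALOG.names(r.base))
            if r.index == 0:
                expected -= {"P", "OP1", "OP2"}
            missing = sorted(expected - set(r.atoms), key=CATALOG.names(r.base).index)
            if missing:
                out.append((r, missing))
    return out


def five_point_selection(r: Residue) -> list[Atom]:
    """The ordered five-point atoms [C4', C1', base1, base2, base3]."""
    names = five_point_names(r.base)
    missing = [n for n in names if n not in r.atoms]
    if missing:
        raise MissingFivePointError(
            f"residue {r.chain_id}{r.auth_number} lacks five-point atoms {missing}")
    return [r.atoms[n] for n in names]


def write_structure(s: RnaStructure, path: str | os.PathLike | None = None) -> str:
    """Serialise to PDB text (author numbering, 3-decimal coordinates).

    Round-trips with :func:`read_structure` to 1e-3 Å. Returns the text;
    also writes it to ``path`` when given.
    """
    if s.n_residues == 0 or s.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for chain_res in s.chains:
        if not chain_res:
            continue
        chain = gemmi.Chain(chain_res[0].chain_id)
        for r in chain_res:
            if len(r.base) > 3:
                raise FormatError(f"residue name {r.base!r} exceeds PDB columns")
            if abs(r.auth_number) > 9999:
                raise FormatError(f"residue number {r.auth_number} exceeds PDB columns")
            res = gemmi.Residue()
            res.name = r.base
            res.seqid = gemmi.SeqId(r.auth_number, " ")
            res.het_flag = "A"
            for atom in r.atoms.values():
                if len(atom.name) > 4:
                    raise FormatError(f"atom name {atom.name!r} exceeds PDB columns")
                a = gemmi.Atom()
                a.name = atom.name
                a.element = gemmi.Element(atom.element)
                a.pos = gemmi.Position(*atom.position)
                a.occ = 1.0
                res.add_atom(a)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


@functools.lru_cache(maxsize=None)
def canonical_bonds(base: str) -> tuple[tuple[str, str], ...]:
    """Heavy-atom covalent bonds of a standard nucleotide (by atom name).

    Derived from the ideal component geometry shipped with biotite's
    chemical component dictionary; OP3 and hydrogens are excluded.
    """
    import biotite.structure.info as _info

    arr = _info.residue(base)
    names = arr.atom_name
    keep = {n for n in names if n in CATALOG.names(base)}
    bonds = []
    for i, j, _order in arr.bonds.as_array():
        ni, nj = names[int(i)], names[int(j)]
        if ni in keep and nj in keep:
            bonds.append(tuple(sorted((ni, nj))))
    return tuple(sorted(set(bonds)))
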
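"""Distance-based steric clash detection and clash metrics.

A clash is a non-bonded heavy-atom pair whose separation is smaller than
the sum of the two van der Waals radii minus a cutoff; the default cutoff
of 0.6 Å corresponds to severe clashes. Pairs within three covalent bonds
(using the canonical intra-residue bond graph plus the O3'(i)-P(i+1)
backbone link) and the hydrogen-bond donor-acceptor pairs of annotated
Watson-Crick pairs are excluded.

The internal detector is heavy-atom only. An optional adapter can delegate
to external MolProbity binaries (REDUCE/PROBE) when they are installed;
absolute counts of the two routes differ because MolProbity places and
scores hydrogens.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import CapabilityError, UndefinedRateError, RnaRefineError
from .rna_io import RnaStructure, canonical_bonds
from .secondary_structure import BasePair

#: Default van der Waals radii in Å for RNA heavy atoms.
DEFAULT_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80}

DEFAULT_CLASH_THRESHOLD = 0.6

#: Hydrogen-bond donor-acceptor atom names of canonical WC pairs,
#: keyed by (purine base, pyrimidine base).
WC_HBOND_ATOMS = {
    ("A", "U"): (("N1", "N3"), ("N6", "O4")),
    ("G", "C"): (("N1", "N3"), ("O6", "N4"), ("N2", "O2")),
}


@dataclass(frozen=True)
class AtomRef:
    """Reference to one atom: global residue index and atom name."""

    residue: int
    name: str


@dataclass
class ClashPair:
    i: AtomRef
    j: AtomRef
    distance: float
    overlap: float


@dataclass
class ClashReport:
    pairs: list[ClashPair]
    clashing_residues: set[int]
    n_atoms: int
    threshold: float
    provenance: str = "internal"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def worst_overlap(self) -> float:
        return max((p.overlap for p in self.pairs), default=0.0)

    @property
    def clashscore(self) -> float:
        return clash_score(self, self.n_atoms)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "clashscore": self.clashscore,
            "worst_overlap": self.worst_overlap,
            "threshold": self.threshold,
            "clashing_residues": sorted(self.clashing_residues),
            "provenance": self.provenance,
            "pairs": [
                {
                    "i": [p.i.residue, p.i.name],
                    "j": [p.j.residue, p.j.name],
                    "distance": p.distance,
                    "overlap": p.overlap,
                }
                for p in self.pairs
            ],
        }


def flatten_atoms(s: RnaStructure):
    """Flat arrays over all atoms: coords, elements, residue index, names."""
    coords, elements, res_idx, names = [], [], [], []
    for gi, r in enumerate(s.residues):
        for a in r.atoms.values():
            coords.append(a.position)
            elements.append(a.element)
            res_idx.append(gi)
            names.append(a.name)
    return (np.asarray(coords, dtype=float).reshape(-1, 3), elements,
            np.asarray(res_idx, dtype=int), names)


def _bonded_within(s: RnaStructure, max_bonds: int = 3) -> set[frozenset[int]]:
    """Flat-index atom pairs connected by <= max_bonds covalent bonds."""
    # Build flat index per (residue, atom name).
    flat: dict[tuple[int, str], int] = {}
    k = 0
    for gi, r in enumerate(s.residues):
        for name in r.atoms:
            flat[(gi, name)] = k
            k += 1
    adj: dict[int, set[int]] = {i: set() for i in range(k)}

    def link(a: int | None, b: int | None) -> None:
        if a is not None and b is not None:
            adj[a].add(b)
            adj[b].add(a)

    for gi, r in enumerate(s.residues):
        if r.base in ("A", "U", "G", "C"):
            for na, nb in canonical_bonds(r.base):
                link(flat.get((gi, na)), flat.get((gi, nb)))
    for lo, hi in s.chain_bounds():
        for gi in range(lo, hi - 1):
            link(flat.get((gi, "O3'")), flat.get((gi + 1, "P")))

    excluded: set[frozenset[int]] = set()
    for start in range(k):
        frontier = {start}
        seen = {start}
        for _ in range(max_bonds):
            frontier = {n for f in frontier for n in adj[f]} - seen
            seen |= frontier
            for f in frontier:
                excluded.add(frozenset((start, f)))
    return excluded


def _wc_excluded(s: RnaStructure, pairs: set[BasePair] | None) -> set[frozenset[tuple[int, str]]]:
    out: set[frozenset[tuple[int, str]]] = set()
    if not pairs:
        return out
    residues = s.residues
    for i, j in pairs:
        bi, bj = residues[i].base, residues[j].base
        key = (i, j) if bi in ("A", "G") else (j, i)
        names = WC_HBOND_ATOMS.get((residues[key[0]].base, residues[key[1]].base))
        if names is None:
            continue
        for na, nb in names:
            out.add(frozenset(((key[0], na), (key[1], nb))))
    return out


def detect_clashes(
    s: RnaStructure,
    radii: dict[str, float] | None = None,
    threshold: float = DEFAULT_CLASH_THRESHOLD,
    pairs: set[BasePair] | None = None,
    method: str = "binned",
) -> ClashReport:
    """All heavy-atom pairs with VdW overlap strictly greater than ``threshold``.

    ``method="binned"`` uses a k-d tree restricted to the maximal clash
    radius; ``method="exhaustive"`` scans all O(N^2) pairs. Both return
    identical reports; the binned path is the default.
    """
    radii = dict(DEFAULT_VDW_RADII) if radii is None else radii
    coords, elements, res_idx, names = flatten_atoms(s)
    n = len(coords)
    try:
        r_atom = np.array([radii[e] for e in elements])
    except KeyError as exc:
        raise RnaRefineError(f"no VdW radius for element {exc}") from exc

    if n == 0:
        return ClashReport([], set(), 0, threshold)

    if method == "binned":
        max_reach = 2.0 * float(r_atom.max()) - threshold
        candidates = cKDTree(coords).query_pairs(max_reach, output_type="ndarray")
    elif method == "exhaustive":
        ii, jj = np.triu_indices(n, k=1)
        candidates = np.column_stack([ii, jj])
    else:
        raise ValueError(f"unknown method {method!r}")

    bonded = _bonded_within(s, max_bonds=3)
    wc_excl = _wc_excluded(s, pairs)

    out: list[ClashPair] = []
    clashing: set[int] = set()
    if len(candidates):
        d = np.linalg.norm(coords[candidates[:, 0]] - coords[candidates[:, 1]], axis=1)
        overlap = r_atom[candidates[:, 0]] + r_atom[candidates[:, 1]] - d
        hits = np.nonzero(overlap > threshold)[0]
        for h in hits:
            a, b = int(candidates[h, 0]), int(candidates[h, 1])
            if frozenset((a, b)) in bonded:
                continue
            key = frozenset(((int(res_idx[a]), names[a]), (int(res_idx[b]), names[b])))
            if key in wc_excl:
                continue
            pa = AtomRef(int(res_idx[a]), names[a])
            pb = AtomRef(int(res_idx[b]), names[b])
            if (pb.residue, pb.name) < (pa.residue, pa.name):
                pa, pb = pb, pa
            out.append(ClashPair(pa, pb, float(d[h]), float(overlap[h])))
            clashing.update((pa.residue, pb.residue))
    out.sort(key=lambda p: (p.i.residue, p.i.name, p.j.residue, p.j.name))
    return ClashReport(out, clashing, n, threshold)


def clash_score(report: ClashReport, n_atoms: int) -> float:
    """Severe overlaps per 1000 atoms."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return 1000.0 * report.n_pairs / n_atoms


def reduction_rate(n_initial: int, n_final: int) -> float:
    """(N_initial - N_final) / N_initial; undefined for zero initial clashes."""
    if n_initial < 1:
        raise UndefinedRateError("reduction rate undefined for n_initial = 0")
    return (n_initial - n_final) / n_initial


def molprobity_adapter(
    s: RnaStructure,
    reduce_path: str | None = None,
    probe_path: str | None = None,
) -> ClashReport:
    """Clash report via external MolProbity (REDUCE hydrogen placement +
    PROBE contact analysis), when those binaries are installed.

    Raises :class:`CapabilityError` with a pointer to the internal detector
    when either binary is absent. The returned report carries
    ``provenance="external"`` and feeds the masking stage unchanged.
    """
    from .rna_io import write_structure

    reduce_exe = shutil.which(reduce_path or "reduce")
    probe_exe = shutil.which(probe_path or "probe")
    if not reduce_exe or not probe_exe:
        raise CapabilityError(
            "MolProbity binaries (reduce/probe) not found; "
            "use detect_clashes() for the built-in heavy-atom detector")

    pdb_text = write_structure(s)
    reduced = subprocess.run(
        [reduce_exe, "-BUILD", "-"], input=pdb_text, text=True,
        capture_output=True, check=False).stdout
    probe_out = subprocess.run(
        [probe_exe, "-u", "-q", "-mc", "-once", "CLASH", "ALL", "-"],
        input=reduced, text=True, capture_output=True, check=False).stdout

    auth_to_global = {
        (r.chain_id, r.auth_number): gi for gi, r in enumerate(s.residues)
    }
    pairs_out: list[ClashPair] = []
    clashing: set[int] = set()
    for line in probe_out.splitlines():
        cols = line.split(":")
        if len(cols) < 8 or cols[2] not in ("so", "bo"):
            continue
        try:
            src, dst = cols[3], cols[4]
            gap = abs(float(cols[6]))
        except (IndexError, ValueError):
            continue

        def ref(token: str) -> AtomRef | None:
            chain = token[:2].strip()
            try:
                num = int(token[2:6])
            except ValueError:
                return None
            name = token[11:15].strip()
            gi = auth_to_global.get((chain, num))
            return AtomRef(gi, name) if gi is not None else None

        a, b = ref(src), ref(dst)
        if a is None or b is None or gap <= DEFAULT_CLASH_THRESHOLD:
            continue
        pairs_out.append(ClashPair(a, b, distance=-1.0, overlap=gap))
        clashing.update((a.residue, b.residue))
    return ClashReport(pairs_out, clashing, s.n_atoms,
                       DEFAULT_CLASH_THRESHOLD, provenance="external")
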
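"""Synthetic clash-free RNA fixtures for desk-scale training and testing.

Structures are assembled from idealized nucleotide templates (heavy-atom
coordinates from the chemical component dictionary bundled with biotite)
placed along a helical transform (32.7° twist per step, with base pairs
displaced off the axis and complementary bases arranged face-to-face so
the N1(purine)-N3(pyrimidine) hydrogen-bond distance matches the
canonical Watson-Crick window). The rise, glycosidic torsion and
phosphate orientation are implementation constants chosen so that every
generated structure clears the 0.6 Å severe-clash criterion with margin;
rigid ideal-geometry templates cannot reproduce the tighter packing of a
real A-form helix without internal collisions, so the synthetic helix is
deliberately more open than A-RNA. Hairpin loops are laid out on an arc
above the stem.

The geometry makes no claim of crystallographic fidelity; its contract is
behavioural: generated structures are clash-free under the internal
detector at the 0.6 Å threshold, their planted pairs are recovered by the
geometric annotator, and defects injected by :func:`inject_clash` /
:func:`delete_atoms` are detectable and maskable.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .clash_detection import detect_clashes
from .errors import GenerationError, MissingFivePointError
from .rna_io import (
    CATALOG,
    Atom,
    Residue,
    RnaStructure,
    element_of,
    five_point_names,
)
from .secondary_structure import BasePair, WC_COMPLEMENT

HELIX_RISE = 4.8          # Å per step (see module docstring)
HELIX_TWIST = np.deg2rad(32.7)
HBOND_LENGTH = 2.9        # Å, N1(purine)-N3(pyrimidine)

#: Pair displacement from the helix axis, in the pair frame (Å).
PAIR_OFFSET = np.array([0.0, -5.3, 0.0])

#: Glycosidic torsion (deg, internal convention) the sugar is rotated to,
#: and the spin (deg) applied to OP1/OP2 about the O5'-P axis. Together
#: with the rise and offset these are the constants found to keep every
#: generated fixture free of >0.6 Å overlaps; they carry no claim of
#: crystallographic fidelity.
CHI_PURINE = 102.0
CHI_PYRIMIDINE = 118.0
PHOSPHATE_SPIN = 323.0

_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

_SUGAR_MOIETY = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                 "O3'", "C2'", "O2'")


def _torsion(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m1 @ n2, n1 @ n2))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


@functools.lru_cache(maxsize=None)
def nucleotide_template(base: str) -> dict[str, np.ndarray]:
    """Idealized heavy-atom coordinates in the base's Watson-Crick frame.

    Frame: origin at the WC hydrogen-bond atom (N1 for purines, N3 for
    pyrimidines), x pointing outward through the WC edge, z the base-plane
    normal oriented so C1' falls at negative y. The sugar-phosphate moiety
    is rotated about the glycosidic bond to the standard torsion above and
    the terminal phosphate oxygens are spun clear of the backbone, so that
    stacked neighbours do not collide.
    """
    import biotite.structure.info as _info

    arr = _info.residue(base)
    keep = set(CATALOG.names(base))
    sel = np.array([n in keep for n in arr.atom_name])
    names = list(arr.atom_name[sel])
    coords = np.asarray(arr.coord[sel], dtype=float)
    pos = dict(zip(names, coords))

    purine = base in ("A", "G")
    ring = _PURINE_RING if purine else _PYRIMIDINE_RING
    ring_xyz = np.array([pos[n] for n in ring])
    centroid = ring_xyz.mean(axis=0)
    w = pos["N1"] if purine else pos["N3"]

    x_ax = w - centroid
    x_ax /= np.linalg.norm(x_ax)
    _, _, vt = np.linalg.svd(ring_xyz - centroid)
    z_ax = vt[-1]
    z_ax -= x_ax * (z_ax @ x_ax)
    z_ax /= np.linalg.norm(z_ax)
    y_ax = np.cross(z_ax, x_ax)
    if (pos["C1'"] - w) @ y_ax > 0:
        z_ax, y_ax = -z_ax, -y_ax
    frame = np.column_stack([x_ax, y_ax, z_ax])
    loc = {n: (p - w) @ frame for n, p in pos.items()}

    # glycosidic torsion normalisation
    ng = "N9" if purine else "N1"
    cref = "C4" if purine else "C2"
    target = np.deg2rad(CHI_PURINE if purine else CHI_PYRIMIDINE)
    chi = _torsion(loc["O4'"], loc["C1'"], loc[ng], loc[cref])
    axis = loc["C1'"] - loc[ng]
    for sign in (1.0, -1.0):
        R = _axis_rotation(axis, sign * (target - chi))
        trial = dict(loc)
        for n in _SUGAR_MOIETY:
            trial[n] = loc[ng] + R @ (loc[n] - loc[ng])
        chi2 = _torsion(trial["O4'"], trial["C1'"], trial[ng], trial[cref])
        if abs(((chi2 - target) + np.pi) % (2 * np.pi) - np.pi) < 1e-6:
            loc = trial
            break

    # phosphate oxygen spin about the O5'-P bond
    R = _axis_rotation(loc["P"] - loc["O5'"], np.deg2rad(PHOSPHATE_SPIN))
    for n in ("OP1", "OP2"):
        loc[n] = loc["P"] + R @ (loc[n] - loc["P"])
    return loc


def _place(base: str, origin: np.ndarray, ex: np.ndarray, ey: np.ndarray,
           ez: np.ndarray) -> dict[str, np.ndarray]:
    axes = np.vstack([ex, ey, ez])
    return {n: origin + local @ axes for n, local in nucleotide_template(base).items()}


def _make_residue(chain_id: str, auth: int, base: str,
                  atoms: dict[str, np.ndarray]) -> Residue:
    r = Residue(chain_id=chain_id, auth_number=auth, index=0, base=base, atoms={})
    for name in CATALOG.names(base):
        if name in atoms:
            r.atoms[name] = Atom(name, element_of(name), atoms[name])
    return r


def _helix_transform(k: int):
    """Rigid transform of helical step k: rotation about z plus rise."""
    c, s = np.cos(k * HELIX_TWIST), np.sin(k * HELIX_TWIST)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t = np.array([0.0, 0.0, k * HELIX_RISE])
    return R, t


def _paired_placement(b1: str, b2: str, k: int):
    """World coordinates for the two bases of helical pair k."""
    R, t = _helix_transform(k)
    half = HBOND_LENGTH / 2.0
    X, Y, Z = np.eye(3)
    a1 = _place(b1, -half * X, X, Y, Z)
    a2 = _place(b2, +half * X, -X, Y, -Z)
    a1 = {n: R @ (p + PAIR_OFFSET) + t for n, p in a1.items()}
    a2 = {n: R @ (p + PAIR_OFFSET) + t for n, p in a2.items()}
    return a1, a2


def ideal_duplex(
    sequence: str,
    rng: np.random.Generator | None = None,
    structure_id: str = "duplex",
    validate: bool = True,
) -> tuple[RnaStructure, set[BasePair], str]:
    """Two complementary strands along the helical transform.

    ``sequence`` is the 5'->3' first strand; the second strand is its
    reverse complement. Returns the structure, the planted pair set over
    the concatenated indexing, and the dot-bracket string.
    """
    if not sequence:
        raise GenerationError("empty sequence")
    n = len(sequence)
    strand1, strand2 = [], []
    for k, b1 in enumerate(sequence):
        b2 = WC_COMPLEMENT[b1]
        a1, a2 = _paired_placement(b1, b2, k)
        strand1.append(_make_residue("A", k + 1, b1, a1))
        strand2.append(_make_residue("B", n - k, b2, a2))
    strand2.reverse()  # 5'->3' order of the antiparallel strand
    s = RnaStructure(id=structure_id, chains=[strand1, strand2],
                     provenance="synthetic:ideal_duplex")
    s.reindex()
    pairs = {(k, 2 * n - 1 - k) for k in range(n)}
    db = "(" * n + ")" * n
    if validate:
        _assert_clash_free(s, pairs)
    return s, pairs, db


def ideal_hairpin(
    stem_sequence: str,
    loop_sequence: str,
    structure_id: str = "hairpin",
    validate: bool = True,
) -> tuple[RnaStructure, set[BasePair], str]:
    """A stem capped by a loop laid out on an arc above the helix."""
    ns, m = len(stem_sequence), len(loop_sequence)
    if ns < 2 or m < 3:
        raise GenerationError("hairpin needs a stem >= 2 and a loop >= 3")
    side1, side2 = [], []
    for k, b1 in enumerate(stem_sequence):
        b2 = WC_COMPLEMENT[b1]
        a1, a2 = _paired_placement(b1, b2, k)
        side1.append((b1, a1))
        side2.append((b2, a2))
    side2.reverse()

    # Loop arc above the closing pair: radius set by a ~8 Å chord between
    # consecutive residues, expressed in the top pair's helical frame.
    dtheta = np.pi / (m + 1)
    rho = max(6.0, 8.0 / (2.0 * np.sin(dtheta / 2.0)))
    R_top, t_top = _helix_transform(ns - 1)
    center_local = PAIR_OFFSET + np.array([0.0, 0.0, 5.0])
    loop = []
    for l, b in enumerate(loop_sequence, start=1):
        theta = np.pi - l * dtheta
        radial = np.array([np.cos(theta), 0.0, np.sin(theta)])
        origin = center_local + rho * radial
        ex = -radial                       # WC edge faces the arc center,
        ez = np.array([0.0, 1.0, 0.0])     # rings fan outward
        ey = np.cross(ez, ex)
        atoms = _place(b, origin, ex, ey, ez)
        loop.append((b, {n: R_top @ p + t_top for n, p in atoms.items()}))

    chain = []
    auth = 1
    for b, atoms in [*side1, *loop, *side2]:
        chain.append(_make_residue("A", auth, b, atoms))
        auth += 1
    s = RnaStructure(id=structure_id, chains=[chain],
                     provenance="synthetic:ideal_hairpin")
    s.reindex()
    total = 2 * ns + m
    pairs = {(k, total - 1 - k) for k in range(ns)}
    db = "(" * ns + "." * m + ")" * ns
    if validate:
        _assert_clash_free(s, pairs)
    return s, pairs, db


def single_strand(sequence: str, structure_id: str = "strand") -> RnaStructure:
    """One helical strand with no partner (unpaired control fixture)."""
    X, Y, Z = np.eye(3)
    half = HBOND_LENGTH / 2.0
    chain = []
    for k, b in enumerate(sequence):
        R, t = _helix_transform(k)
        atoms = {n: R @ (p + PAIR_OFFSET) + t
                 for n, p in _place(b, -half * X, X, Y, Z).items()}
        chain.append(_make_residue("A", k + 1, b, atoms))
    s = RnaStructure(id=structure_id, chains=[chain],
                     provenance="synthetic:single_strand")
    s.reindex()
    return s


def _assert_clash_free(s: RnaStructure, pairs: set[BasePair]) -> None:
    report = detect_clashes(s, pairs=pairs)
    if report.n_pairs:
        worst = report.pairs[0]
        raise GenerationError(
            f"synthetic fixture is not clash-free: {report.n_pairs} pairs, "
            f"e.g. {worst.i}-{worst.j} overlap {worst.overlap:.2f} Å")


def inject_clash(
    s: RnaStructure,
    residue_index: int,
    displacement: float = 0.5,
    rng: np.random.Generator | None = None,
    pairs: set[BasePair] | None = None,
    max_displacement: float = 10.0,
) -> RnaStructure:
    """Displace a residue's non-five-point atoms until a clash appears.

    The atoms move rigidly toward the nearest neighbouring residue in
    increments of ``displacement``; five-point atoms stay put so inference
    masks anchored on them remain valid. Raises :class:`GenerationError`
    when no clash can be produced within ``max_displacement``.
    """
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    residues = s.residues
    target = residues[residue_index]
    c4 = target.coord("C4'")
    best, best_d = None, np.inf
    for gj, r in enumerate(residues):
        if gj == residue_index or not r.has("C4'"):
            continue
        d = float(np.linalg.norm(r.coord("C4'") - c4))
        if d < best_d:
            best, best_d = r.coord("C4'"), d
    if best is None:
        raise GenerationError("no neighbouring residue to clash against")
    direction = best - c4
    direction = direction / np.linalg.norm(direction)
    direction += 0.05 * rng.standard_normal(3)
    direction /= np.linalg.norm(direction)

    fp = set(five_point_names(target.base))
    movable = [n for n in target.atoms if n not in fp]
    step = displacement
    while step <= max_displacement:
        out = s.copy()
        res = out.residues[residue_index]
        for n in movable:
            res.atoms[n].position = target.atoms[n].position + step * direction
        report = detect_clashes(out, pairs=pairs)
        if any(residue_index in (p.i.residue, p.j.residue) for p in report.pairs):
            out.provenance += f"|clash_injected:{residue_index}"
            return out
        step += displacement
    raise GenerationError(
        f"could not produce a clash within {max_displacement} Å of displacement")


def delete_atoms(
    s: RnaStructure,
    residue_index: int,
    names: list[str] | None = None,
    count: int | None = None,
    rng: np.random.Generator | None = None,
) -> RnaStructure:
    """Remove non-five-point atoms from one residue.

    Either an explicit name list or a count of randomly chosen candidates;
    requesting a five-point atom raises :class:`MissingFivePointError`.
    """
    residues = s.residues
    target = residues[residue_index]
    fp = set(five_point_names(target.base))
    if names is None:
        if count is None:
            raise ValueError("give either names or count")
        pool = [n for n in target.atoms if n not in fp]
        rng = rng if rng is not None else np.random.default_rng()
        names = list(rng.choice(pool, size=min(count, len(pool)), replace=False))
    bad = [n for n in names if n in fp]
    if bad:
        raise MissingFivePointError(f"refusing to delete five-point atoms {bad}")
    out = s.copy()
    res = out.residues[residue_index]
    for n in names:
        res.atoms.pop(n, None)
    out.provenance += f"|atoms_deleted:{residue_index}"
    return out


@dataclass
class ToyRecord:
    """One synthetic training/evaluation record."""

    structure: RnaStructure
    pairs: set[BasePair]
    dotbracket: str
    kind: str
    has_clashes: bool = False
    meta: dict = field(default_factory=dict)


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("AUGC"), size=n))


def toy_corpus(
    n: int,
    length_range: tuple[int, int] = (6, 20),
    hairpin_fraction: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> list[ToyRecord]:
    """``n`` clash-free duplex/hairpin records, reproducible from the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    records: list[ToyRecord] = []
    for k in range(n):
        total = int(rng.integers(length_range[0], length_range[1] + 1))
        if rng.random() < hairpin_fraction and total >= 8:
            m = int(rng.integers(3, min(6, total - 4) + 1))
            ns = max(2, (total - m) // 2)
            stem = _random_sequence(ns, rng)
            loop = _random_sequence(m, rng)
            s, pairs, db = ideal_hairpin(stem, loop, structure_id=f"toy{k:04d}")
            kind = "hairpin"
        else:
            npairs = max(3, total // 2)
            seq = _random_sequence(npairs, rng)
            s, pairs, db = ideal_duplex(seq, structure_id=f"toy{k:04d}")
            kind = "duplex"
        records.append(ToyRecord(s, pairs, db, kind))
    return records
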
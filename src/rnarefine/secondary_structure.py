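"""Secondary structure: dot-bracket parsing, geometric Watson-Crick
annotation, and motif decomposition.

Base pairs are represented as a plain ``set`` of 0-based index tuples
``(i, j)`` with ``i < j`` over the concatenated sequence. Dot-bracket input
is the primary source (e.g. from an external annotator); a geometric
fallback infers canonical A-U / G-C pairs from the N1(purine)-N3(pyrimidine)
hydrogen-bond distance when only 3D coordinates are available.

Motif decomposition walks the pseudoknot-free secondary-structure tree and
emits stems (maximal stacks of consecutive pairs), hairpin loops, internal
loops, bulges and multi-way junctions. Motif records include the closing
base pairs of their adjacent stems, so each record is a self-contained
structural unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, PseudoknotError
from .rna_io import PURINES, PYRIMIDINES, RnaStructure

BasePair = tuple[int, int]

#: Canonical Watson-Crick complements.
WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Default N1(purine)-N3(pyrimidine) distance window in Å.
DEFAULT_WC_WINDOW = (2.6, 3.4)


def parse_dot_bracket(db: str) -> set[BasePair]:
    """Stack-match a dot-bracket string into a set of (i, j) pairs, i < j."""
    stack: list[int] = []
    pairs: set[BasePair] = set()
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise FormatError(f"unexpected character {ch!r} at position {i}")
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def partner_map(pairs: set[BasePair], n: int) -> np.ndarray:
    """Array of length n with each index's partner, -1 when unpaired."""
    partner = np.full(n, -1, dtype=int)
    for i, j in pairs:
        if partner[i] != -1 or partner[j] != -1:
            raise FormatError(f"index in two pairs: {(i, j)}")
        partner[i], partner[j] = j, i
    return partner


def check_pseudoknot_free(pairs: set[BasePair]) -> None:
    """Raise :class:`PseudoknotError` if any two pairs cross."""
    ordered = sorted(pairs)
    for a, (i, j) in enumerate(ordered):
        for k, l in ordered[a + 1:]:
            if k >= j:
                break
            if i < k < j < l:
                raise PseudoknotError(f"crossing pairs {(i, j)} and {(k, l)}")


def annotate_wc_geometric(
    s: RnaStructure,
    window: tuple[float, float] = DEFAULT_WC_WINDOW,
) -> set[BasePair]:
    """Infer canonical WC pairs from N1(purine)-N3(pyrimidine) distances.

    Candidate pairs must be complementary (A-U or G-C) and have their
    glycosidic-edge hydrogen-bond distance within ``window``. Conflicts are
    resolved greedily: candidates are visited by increasing distance and a
    residue joins at most one pair.
    """
    residues = s.residues
    candidates: list[tuple[float, int, int]] = []
    for gi, ri in enumerate(residues):
        if ri.base not in PURINES or not ri.has("N1"):
            continue
        for gj, rj in enumerate(residues):
            if gi == gj or rj.base not in PYRIMIDINES or not rj.has("N3"):
                continue
            if WC_COMPLEMENT[ri.base] != rj.base:
                continue
            d = float(np.linalg.norm(ri.coord("N1") - rj.coord("N3")))
            if window[0] <= d <= window[1]:
                candidates.append((d, min(gi, gj), max(gi, gj)))
    taken: set[int] = set()
    pairs: set[BasePair] = set()
    for d, i, j in sorted(candidates):
        if i in taken or j in taken:
            continue
        pairs.add((i, j))
        taken.update((i, j))
    return pairs


@dataclass
class MotifRecord:
    """A stem, hairpin loop, internal loop, bulge or junction.

    ``residue_indices`` are global 0-based indices of all member residues
    (closing pairs included); ``sequence`` and ``dotbracket`` are the
    corresponding character slices. ``coordinates`` is filled only when a
    structure is supplied to :func:`extract_motifs`.
    """

    motif_type: str
    residue_indices: tuple[int, ...]
    sequence: str
    dotbracket: str
    coordinates: list[dict[str, list[float]]] | None = field(default=None, repr=False)

    def to_json(self) -> str:
        return json.dumps({
            "type": self.motif_type,
            "sequence": self.sequence,
            "dotbracket": self.dotbracket,
            "residue_indices": list(self.residue_indices),
        })


def _stems(pairs: set[BasePair]) -> list[list[BasePair]]:
    """Maximal stacks of consecutive pairs (i,j),(i+1,j-1),..."""
    pair_set = set(pairs)
    stems = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pair_set:
            continue  # not the outermost pair of its stack
        stem = [(i, j)]
        while (stem[-1][0] + 1, stem[-1][1] - 1) in pair_set:
            stem.append((stem[-1][0] + 1, stem[-1][1] - 1))
        stems.append(stem)
    return stems


def _children(lo: int, hi: int, partner: np.ndarray) -> tuple[list[BasePair], list[int]]:
    """Outermost pairs and unpaired indices inside the open interval (lo, hi)."""
    kids, unpaired = [], []
    k = lo
    while k < hi:
        p = partner[k]
        if p == -1:
            unpaired.append(k)
            k += 1
        else:
            kids.append((k, int(p)))
            k = int(p) + 1
    return kids, unpaired


def extract_motifs(
    pairs: set[BasePair],
    sequence: str,
    structure: RnaStructure | None = None,
) -> list[MotifRecord]:
    """Decompose a pseudoknot-free secondary structure into motifs.

    Every stem is emitted once; each loop-type motif (hairpin loop,
    internal loop, bulge, junction) is emitted once for the tree node it
    closes, carrying the closing pairs of the adjacent stems. An exterior
    node with three or more outermost stems is reported as a junction.
    """
    n = len(sequence)
    check_pseudoknot_free(pairs)
    partner = partner_map(pairs, n)
    records: list[MotifRecord] = []

    def make(motif_type: str, indices: list[int]) -> None:
        idx = tuple(sorted(set(indices)))
        seq = "".join(sequence[i] for i in idx)
        db = "".join(
            "(" if partner[i] > i else (")" if 0 <= partner[i] < i else ".")
            for i in idx
        )
        coords = None
        if structure is not None:
            residues = structure.residues
            coords = [
                {name: atom.position.tolist() for name, atom in residues[i].atoms.items()}
                for i in idx
            ]
        records.append(MotifRecord(motif_type, idx, seq, db, coords))

    for stem in _stems(pairs):
        make("stem", [i for p in stem for i in p])
        c, d = stem[-1]  # innermost closing pair
        kids, unpaired = _children(c + 1, d, partner)
        if not kids:
            make("hairpin_loop", [c, d] + unpaired)
        elif len(kids) == 1:
            (k, m) = kids[0]
            left = [x for x in unpaired if x < k]
            right = [x for x in unpaired if x > m]
            kind = "internal_loop" if (left and right) else "bulge"
            make(kind, [c, d, k, m] + left + right)
        else:
            make("junction", [c, d] + [i for p in kids for i in p] + unpaired)

    top_kids, top_unpaired = _children(0, n, partner)
    if len(top_kids) >= 3:
        between = [u for u in top_unpaired if top_kids[0][0] < u < top_kids[-1][1]]
        make("junction", [i for p in top_kids for i in p] + between)

    records.sort(key=lambda r: (r.residue_indices, r.motif_type))
    return records


def motifs_to_jsonl(records: list[MotifRecord]) -> str:
    """Serialise motif records as JSON-lines."""
    return "\n".join(r.to_json() for r in records)
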
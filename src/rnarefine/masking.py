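"""Fragment/linker partitions of atoms for conditional generation.

Training masks are produced by a hybrid two-phase procedure that emulates
where clashes occur in deposited structures:

* phase 1 seeds 1-5% of nucleotides at random, then expands each seed once
  to its sequence neighbours (probability 0.4 each side) and its
  Watson-Crick partner (probability 0.3);
* phase 2 ranks residue pairs by C4'-C4' distance and adds the nearest
  pairs that pass exclusion rules (|i-j| <= 3, direct WC partners, and
  second-order neighbours of WC partners are excluded, as are pairs that
  touch the phase-1 set) until the combined mask covers
  K = max(1, round(N * severity * 0.8)) nucleotides, where the severity
  level is sampled from a bucketed law mirroring the clash ratio observed
  in deposited structures.

The linker residue set is the union of the two phases. Inference masks are
deterministic: they come from a clash report or from detected missing
atoms. Atom identifiers are (global residue index, atom name) pairs, so a
mask is meaningful for any graph built over the same structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import AnchoredAtomMissingError
from .rna_io import RnaStructure, five_point_names
from .secondary_structure import BasePair, partner_map

logger = logging.getLogger(__name__)

AtomId = tuple[int, str]


@dataclass
class MaskAssignment:
    """Exhaustive partition of atoms into linker (regenerate) and fragment
    (conditioning anchors)."""

    linker: frozenset[AtomId]
    fragment: frozenset[AtomId]
    linker_residues: frozenset[int]
    mode: str  # "all_atom" or "five_point"

    def __post_init__(self) -> None:
        if self.linker & self.fragment:
            raise ValueError("linker and fragment overlap")

    @property
    def all_atoms(self) -> frozenset[AtomId]:
        return self.linker | self.fragment

    def linker_node_mask(self, graph) -> np.ndarray:
        """Boolean per-node mask over an :class:`RnaGraph`'s nodes."""
        return np.array([key in self.linker for key in graph.node_map], dtype=bool)

    def to_json_dict(self) -> dict:
        return {
            "linker_residues": sorted(self.linker_residues),
            "mode": self.mode,
            "linker": sorted([list(a) for a in self.linker]),
        }


@dataclass
class SeveritySpec:
    """Bucketed severity law: P(severity = 0) and three uniform bands."""

    probabilities: tuple[float, float, float, float] = (0.60, 0.30, 0.09, 0.01)
    bounds: tuple[tuple[float, float], ...] = ((0.0, 0.0), (0.0, 0.2), (0.2, 0.5), (0.5, 1.0))

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.probabilities), 1.0):
            raise ValueError("severity bucket probabilities must sum to 1")


@dataclass
class Phase1Params:
    seed_fraction: tuple[float, float] = (0.01, 0.05)
    p_neighbor: float = 0.4
    p_basepair: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.p_neighbor, self.p_basepair):
            if not 0.0 <= p <= 1.0:
                raise ValueError("expansion probabilities must lie in [0, 1]")


def sample_severity(spec: SeveritySpec, rng: np.random.Generator) -> float:
    """Draw a severity level in [0, 1] from the bucketed law."""
    bucket = rng.choice(len(spec.probabilities), p=spec.probabilities)
    lo, hi = spec.bounds[bucket]
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


def compute_K(N: int, severity: float) -> int:
    """K = max(1, round_half_up(N * severity * 0.8))."""
    return max(1, math.floor(N * severity * 0.8 + 0.5))


def phase1_select(
    N: int,
    pairs: set[BasePair],
    params: Phase1Params,
    rng: np.random.Generator,
) -> set[int]:
    """Sequence- and secondary-structure-based seed selection.

    Seed count is max(1, round(f*N)) with f ~ U[seed_fraction]; the
    expansion to neighbours and WC partners is applied once (seeds only,
    no recursive growth).
    """
    f = rng.uniform(*params.seed_fraction)
    n_seed = max(1, int(math.floor(f * N + 0.5)))
    seeds = set(int(x) for x in rng.choice(N, size=min(n_seed, N), replace=False))
    partner = partner_map(pairs, N)
    selected = set(seeds)
    for s in sorted(seeds):
        for nb in (s - 1, s + 1):
            if 0 <= nb < N and rng.random() < params.p_neighbor:
                selected.add(nb)
        p = int(partner[s])
        if p >= 0 and rng.random() < params.p_basepair:
            selected.add(p)
    return selected


def phase2_select(
    c4_coords: np.ndarray,
    pairs: set[BasePair],
    phase1_set: set[int],
    K: int,
    rng: np.random.Generator | None = None,
    budget: str = "nucleotides",
) -> set[int]:
    """3D K-nearest-pairs selection over C4' distances with exclusions.

    A residue pair (i, j) is admissible when |i - j| > 3, the residues are
    not direct WC partners, neither lies within 2 positions of the other's
    WC partner, and neither belongs to the phase-1 set. Admissible pairs
    are visited by increasing C4'-C4' distance (ties broken by index for
    determinism).

    With ``budget="nucleotides"`` (default), K is the target *nucleotide*
    count of the combined mask: pairs are added until the union with the
    phase-1 set reaches K residues, taking at least one pair — so the
    severity level controls the total corrupted fraction of the
    structure, and masks range from a single pair up to ~80% of the
    sequence at severity 1. With ``budget="pairs"``, exactly the K
    nearest admissible pairs are taken.
    """
    c4 = np.asarray(c4_coords, dtype=float)
    N = len(c4)
    partner = partner_map(pairs, N)
    iu, ju = np.triu_indices(N, k=1)
    ok = (ju - iu) > 3
    pi, pj = partner[iu], partner[ju]
    ok &= pi != ju
    ok &= ~((pi >= 0) & (np.abs(ju - pi) <= 2))
    ok &= ~((pj >= 0) & (np.abs(iu - pj) <= 2))
    if phase1_set:
        p1 = np.fromiter(phase1_set, dtype=int)
        ok &= ~(np.isin(iu, p1) | np.isin(ju, p1))
    iu, ju = iu[ok], ju[ok]
    d = np.linalg.norm(c4[iu] - c4[ju], axis=1)
    order = np.lexsort((ju, iu, d))

    out: set[int] = set()
    if budget == "pairs":
        if len(order) < K:
            logger.info("phase 2: only %d admissible pairs for K=%d", len(order), K)
        for k in order[:K]:
            out.update((int(iu[k]), int(ju[k])))
        return out
    if budget != "nucleotides":
        raise ValueError(f"unknown budget {budget!r}")
    covered = set(phase1_set)
    added = 0
    for k in order:
        if len(covered) >= K and added >= 1:
            break
        i, j = int(iu[k]), int(ju[k])
        out.update((i, j))
        covered.update((i, j))
        added += 1
    if added == 0:
        logger.info("phase 2: no admissible pairs")
    return out


def _partition(s: RnaStructure, linker_residues: set[int], mode: str) -> MaskAssignment:
    linker: set[AtomId] = set()
    fragment: set[AtomId] = set()
    for gi, r in enumerate(s.residues):
        fp = set(five_point_names(r.base))
        for name in r.atoms:
            if mode == "five_point" and name not in fp:
                continue  # not a node at this resolution
            if gi in linker_residues:
                if mode == "all_atom":
                    (fragment if name in fp else linker).add((gi, name))
                else:
                    (fragment if name == "C4'" else linker).add((gi, name))
            else:
                fragment.add((gi, name))
    return MaskAssignment(frozenset(linker), frozenset(fragment),
                          frozenset(linker_residues), mode)


def hybrid_mask(
    s: RnaStructure,
    pairs: set[BasePair],
    spec: SeveritySpec | None = None,
    params: Phase1Params | None = None,
    mode: str = "all_atom",
    rng: np.random.Generator | None = None,
) -> MaskAssignment:
    """Training mask: union of phase-1 and phase-2 residues, partitioned
    into linker/fragment atoms according to ``mode``."""
    spec = spec or SeveritySpec()
    params = params or Phase1Params()
    rng = rng if rng is not None else np.random.default_rng()
    N = s.n_residues
    p1 = phase1_select(N, pairs, params, rng)
    severity = sample_severity(spec, rng)
    K = compute_K(N, severity)
    c4 = np.array([r.coord("C4'") for r in s.residues])
    p2 = phase2_select(c4, pairs, p1, K, rng)
    return _partition(s, p1 | p2, mode)


def masks_from_clash_report(s: RnaStructure, report, mode: str = "all_atom") -> MaskAssignment:
    """Inference mask: residues owning any clashing atom become linker
    residues; an empty report yields an all-fragment no-op mask."""
    return _partition(s, set(report.clashing_residues), mode)


def masks_from_missing_atoms(
    s: RnaStructure,
    missing: list[tuple[object, list[str]]],
    include_residue_atoms: bool = False,
) -> MaskAssignment:
    """Inference mask for reconstruction: missing (non-five-point) atoms
    become linker placeholders; everything present is fragment.

    With ``include_residue_atoms`` the residue's other non-five-point
    atoms are regenerated together with the missing ones.
    """
    residues = s.residues
    global_of = {id(r): gi for gi, r in enumerate(residues)}
    linker: set[AtomId] = set()
    linker_res: set[int] = set()
    for res, names in missing:
        gi = global_of[id(res)]
        fp = set(five_point_names(res.base))
        bad = [n for n in names if n in fp]
        if bad:
            raise AnchoredAtomMissingError(
                f"five-point atom(s) {bad} missing in residue "
                f"{res.chain_id}{res.auth_number}; cannot anchor reconstruction")
        linker_res.add(gi)
        linker.update((gi, n) for n in names)
        if include_residue_atoms:
            linker.update((gi, n) for n in residues[gi].atoms if n not in fp)
    fragment: set[AtomId] = set()
    for gi, r in enumerate(residues):
        for name in r.atoms:
            if (gi, name) not in linker:
                fragment.add((gi, name))
    return MaskAssignment(frozenset(linker), frozenset(fragment),
                          frozenset(linker_res), "all_atom")
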
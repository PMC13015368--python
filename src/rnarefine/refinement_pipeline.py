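"""Orchestration: clash resolution, hierarchical refinement, missing-atom
reconstruction and RMSD evaluation.

Clash resolution is best-of-N with protection: the pipeline detects
clashes, masks the affected residues, draws N candidate structures from
the conditional diffusion model, re-scores each with the detector and
returns the candidate with the fewest clash pairs — unless every candidate
is worse than the input, in which case the input is returned unchanged, so
refinement can never degrade a structure.

The hierarchical strategy relaxes the five-point anchors for hard cases:
a coarse five-point model first proposes 5 re-arrangements of the C1' and
base anchor atoms (C4' stays pinned), then the all-atom model rebuilds the
remaining atoms 5 times for each, and the best of the 25 candidates is
selected under the same protection rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clash_detection import ClashReport, detect_clashes, reduction_rate
from .egnn import DenoiserState
from .egnn_diffusion import constrained_sample
from .errors import AnchoredAtomMissingError, CorrespondenceError
from .graph_encoding import EncodingConfig, RnaGraph, encode_graph
from .masking import MaskAssignment, masks_from_clash_report, masks_from_missing_atoms
from .rna_io import Atom, RnaStructure, detect_missing_atoms, element_of
from .secondary_structure import BasePair

logger = logging.getLogger(__name__)


@dataclass
class RefinementResult:
    structure: RnaStructure
    input_report: ClashReport
    output_report: ClashReport
    n_candidates: int
    candidate_counts: list[int]
    used_hierarchical: bool = False
    no_op: bool = False
    seed: int | None = None

    @property
    def reduction(self) -> float:
        return reduction_rate(self.input_report.n_pairs, self.output_report.n_pairs)


def apply_coords(s: RnaStructure, graph: RnaGraph, coords: np.ndarray) -> RnaStructure:
    """A copy of ``s`` with node coordinates written back from ``coords``."""
    out = s.copy()
    residues = out.residues
    for k, (gi, name) in enumerate(graph.node_map):
        residues[gi].atoms[name].position = np.array(coords[k])
    return out


def _select_candidate(counts, worsts):
    """Argmin by clash count, then worst overlap, then candidate index."""
    order = sorted(range(len(counts)), key=lambda k: (counts[k], worsts[k], k))
    return order[0]


def resolve_clashes(
    s: RnaStructure,
    state: DenoiserState,
    n_candidates: int = 10,
    rng: np.random.Generator | int | None = None,
    pairs: set[BasePair] | None = None,
    threshold: float = 0.6,
    encoding: EncodingConfig | None = None,
) -> RefinementResult:
    """Best-of-N all-atom clash resolution with the protection rule."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    report_in = detect_clashes(s, threshold=threshold, pairs=pairs)
    if report_in.n_pairs == 0:
        logger.info("input is clash-free; returning unchanged")
        return RefinementResult(s, report_in, report_in, 0, [], no_op=True)

    encoding = encoding or EncodingConfig()
    mask = masks_from_clash_report(s, report_in, mode="all_atom")
    graph = encode_graph(s, pairs, encoding)
    samples = constrained_sample(graph, mask, state, n_samples=n_candidates, rng=rng)

    candidates, counts, worsts = [], [], []
    for k in range(n_candidates):
        cand = apply_coords(s, graph, samples[k])
        rep = detect_clashes(cand, threshold=threshold, pairs=pairs)
        candidates.append((cand, rep))
        counts.append(rep.n_pairs)
        worsts.append(rep.worst_overlap)
    best = _select_candidate(counts, worsts)
    logger.info("candidate clash counts %s; input %d; best #%d",
                counts, report_in.n_pairs, best)

    if counts[best] > report_in.n_pairs:
        # protection: never return something worse than the input
        return RefinementResult(s, report_in, report_in, n_candidates, counts,
                                no_op=True)
    cand, rep = candidates[best]
    return RefinementResult(cand, report_in, rep, n_candidates, counts)


def hierarchical_refine(
    s: RnaStructure,
    coarse_state: DenoiserState,
    all_atom_state: DenoiserState,
    rng: np.random.Generator | int | None = None,
    pairs: set[BasePair] | None = None,
    threshold: float = 0.6,
    n_coarse: int = 5,
    n_fine: int = 5,
) -> RefinementResult:
    """Two-stage refinement: five-point proposals, then all-atom rebuilds.

    C4' atoms remain pinned in every candidate; the coarse stage moves the
    other four anchor atoms of clashing residues, and the fine stage
    regenerates the non-five-point atoms conditioned on each proposal.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    report_in = detect_clashes(s, threshold=threshold, pairs=pairs)
    if report_in.n_pairs == 0:
        return RefinementResult(s, report_in, report_in, 0, [],
                                used_hierarchical=True, no_op=True)

    coarse_cfg = EncodingConfig(resolution="five_point", edge_scheme="relation_5type")
    coarse_mask = masks_from_clash_report(s, report_in, mode="five_point")
    coarse_graph = encode_graph(s, pairs, coarse_cfg)
    coarse = constrained_sample(coarse_graph, coarse_mask, coarse_state,
                                n_samples=n_coarse, rng=rng)

    fine_cfg = EncodingConfig()
    candidates, counts, worsts = [], [], []
    for kc in range(n_coarse):
        anchored = apply_coords(s, coarse_graph, coarse[kc])
        mask = masks_from_clash_report(anchored, report_in, mode="all_atom")
        graph = encode_graph(anchored, pairs, fine_cfg)
        fines = constrained_sample(graph, mask, all_atom_state,
                                   n_samples=n_fine, rng=rng)
        for kf in range(n_fine):
            cand = apply_coords(anchored, graph, fines[kf])
            rep = detect_clashes(cand, threshold=threshold, pairs=pairs)
            candidates.append((cand, rep))
            counts.append(rep.n_pairs)
            worsts.append(rep.worst_overlap)

    best = _select_candidate(counts, worsts)
    logger.info("hierarchical counts %s; input %d", counts, report_in.n_pairs)
    if counts[best] > report_in.n_pairs:
        return RefinementResult(s, report_in, report_in, len(candidates), counts,
                                used_hierarchical=True, no_op=True)
    cand, rep = candidates[best]
    return RefinementResult(cand, report_in, rep, len(candidates), counts,
                            used_hierarchical=True)


def reconstruct_missing(
    s: RnaStructure,
    state: DenoiserState,
    rng: np.random.Generator | int | None = None,
    pairs: set[BasePair] | None = None,
    ground_truth: RnaStructure | None = None,
    include_residue_atoms: bool = False,
    placeholder_sigma: float = 1.0,
) -> tuple[RnaStructure, dict[int, float]]:
    """Rebuild missing (non-five-point) atoms by conditional generation.

    Placeholder atoms are created at the owning residue's C4' position
    plus isotropic Gaussian jitter — any finite initialisation is erased
    by the forward-noise start of sampling. Returns the completed
    structure and, when ``ground_truth`` is given, an all-atom RMSD per
    reconstructed residue (global index -> Å).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    missing = detect_missing_atoms(s)
    if not missing:
        return s.copy(), {}
    for res, names in missing:
        from .rna_io import five_point_names
        bad = [n for n in names if n in set(five_point_names(res.base))]
        if bad:
            raise AnchoredAtomMissingError(
                f"five-point atoms {bad} missing in residue "
                f"{res.chain_id}{res.auth_number}")

    work = s.copy()
    work_missing = detect_missing_atoms(work)
    for res, names in work_missing:
        c4 = res.coord("C4'")
        for n in names:
            res.atoms[n] = Atom(n, element_of(n),
                                c4 + placeholder_sigma * rng.standard_normal(3))
    mask = masks_from_missing_atoms(work, work_missing,
                                    include_residue_atoms=include_residue_atoms)
    graph = encode_graph(work, pairs, EncodingConfig())
    sample = constrained_sample(graph, mask, state, n_samples=1, rng=rng)[0]
    completed = apply_coords(work, graph, sample)

    rmsd_table: dict[int, float] = {}
    if ground_truth is not None:
        gt_res = ground_truth.residues
        for res, names in work_missing:
            gi = next(i for i, r in enumerate(work.residues) if r is res)
            out_res = completed.residues[gi]
            sq = [np.sum((out_res.coord(n) - gt_res[gi].coord(n)) ** 2)
                  for n in out_res.atoms if gt_res[gi].has(n)]
            rmsd_table[gi] = float(np.sqrt(np.mean(sq)))
    return completed, rmsd_table


def evaluate_rmsd(a: RnaStructure, b: RnaStructure, atoms=None) -> float:
    """All-atom RMSD in the shared frame (no superposition).

    Generation is frame-anchored by fragment pinning, so superposition
    would mask placement errors. ``atoms`` optionally restricts to a set
    of atom names or a predicate on (residue, atom name).
    """
    index_b = {}
    for r in b.residues:
        for name in r.atoms:
            index_b[(r.chain_id, r.index, name)] = r.coord(name)
    sq = []
    for r in a.residues:
        for name in r.atoms:
            if atoms is not None:
                if callable(atoms):
                    if not atoms(r, name):
                        continue
                elif name not in atoms:
                    continue
            key = (r.chain_id, r.index, name)
            if key not in index_b:
                raise CorrespondenceError(f"atom {key} absent from second structure")
            sq.append(np.sum((r.coord(name) - index_b[key]) ** 2))
    if not sq:
        raise CorrespondenceError("empty atom selection")
    if atoms is None and len(sq) != len(index_b):
        raise CorrespondenceError(
            f"atom sets differ: {len(sq)} matched of {len(index_b)}")
    return float(np.sqrt(np.mean(sq)))
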
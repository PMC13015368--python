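"""Featurized geometric graphs over RNA structures.

Each heavy atom (or, at five-point resolution, each coarse-grained anchor
atom) becomes a node carrying a concatenated feature vector

    [base one-hot (4) | (base, atom-name) one-hot (85) | positional encoding (d)]

and its 3D coordinates. Two edge-typing schemes are available:

``contact_4type``
    intra-residue / sequential / Watson-Crick base-pair / spatial
    (C4'-C4' < 8 Å) edges between atom pairs, with precedence
    intra > sequential > base-pair > spatial so every typed pair receives
    exactly one type.

``relation_5type``
    C4'-C4' adjacent, C4'-C4' non-adjacent, C4'/non-C4' intra-residue,
    non-C4' intra-residue, and inter-residue non-C4' edges within a 14 Å
    C4'-C4' cutoff.

Node ordering is canonical (chain, residue, catalog atom order), so graph
construction is invariant to the record order of the input file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CatalogError, ConfigError
from .rna_io import CATALOG, RnaStructure, five_point_names
from .secondary_structure import BasePair

logger = logging.getLogger(__name__)

BASE_INDEX = {"A": 0, "U": 1, "G": 2, "C": 3}


@dataclass
class EncodingConfig:
    resolution: str = "all_atom"          # or "five_point"
    edge_scheme: str = "contact_4type"    # or "relation_5type"
    pe_dim: int = 16
    spatial_cutoff: float = 8.0           # Å, contact_4type spatial edges
    relation_cutoff: float = 14.0         # Å, relation_5type inter-residue edges
    # Whether the 14 Å cutoff also bounds non-adjacent C4'-C4' edges
    # (class 2); switchable because it primarily controls graph size.
    relation_cutoff_on_c4: bool = True

    def __post_init__(self) -> None:
        if self.pe_dim % 2 != 0 or self.pe_dim <= 0:
            raise ConfigError("pe_dim must be a positive even integer")
        if self.spatial_cutoff <= 0 or self.relation_cutoff <= 0:
            raise ConfigError("cutoffs must be positive")
        if self.resolution not in ("all_atom", "five_point"):
            raise ConfigError(f"unknown resolution {self.resolution!r}")
        if self.edge_scheme not in ("contact_4type", "relation_5type"):
            raise ConfigError(f"unknown edge scheme {self.edge_scheme!r}")

    @property
    def n_edge_types(self) -> int:
        return 4 if self.edge_scheme == "contact_4type" else 5

    @property
    def feature_dim(self) -> int:
        return 4 + len(CATALOG) + self.pe_dim


@dataclass
class RnaGraph:
    """Featurized geometric graph consumed by the denoiser."""

    node_features: np.ndarray              # (N, 4+85+d)
    coords: np.ndarray                     # (N, 3) Å
    edge_index: np.ndarray                 # (E, 2) int, both directions present
    edge_attr: np.ndarray                  # (E, n_types) one-hot
    node_map: list[tuple[int, str]]        # node -> (global residue index, atom name)
    config: EncodingConfig
    node_index: dict[tuple[int, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.node_index:
            self.node_index = {key: k for k, key in enumerate(self.node_map)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_map)

    @property
    def residue_index(self) -> np.ndarray:
        return np.array([ri for ri, _ in self.node_map], dtype=int)

    def to_json_dict(self) -> dict:
        return {
            "node_features": self.node_features.tolist(),
            "coords": self.coords.tolist(),
            "edge_index": self.edge_index.tolist(),
            "edge_attr": self.edge_attr.tolist(),
            "node_map": [[ri, name] for ri, name in self.node_map],
        }


def positional_encoding(i: int, d: int) -> np.ndarray:
    """Sinusoidal residue-position encoding of dimension ``d`` (even).

    PE[2k] = sin(i / 10000^(2k/d)), PE[2k+1] = cos(i / 10000^(2k/d));
    all atoms of residue ``i`` share the same vector.
    """
    if d % 2 != 0 or d <= 0:
        raise ConfigError("positional encoding dimension must be even and positive")
    k = np.arange(d // 2)
    angle = i / np.power(10000.0, 2 * k / d)
    pe = np.empty(d)
    pe[0::2] = np.sin(angle)
    pe[1::2] = np.cos(angle)
    return pe


def _node_list(s: RnaStructure, config: EncodingConfig) -> list[tuple[int, str]]:
    nodes: list[tuple[int, str]] = []
    for gi, r in enumerate(s.residues):
        if config.resolution == "five_point":
            wanted = five_point_names(r.base)
        else:
            wanted = CATALOG.names(r.base)
        for name in wanted:
            if name in r.atoms:
                nodes.append((gi, name))
        for name in r.atoms:
            if (r.base, name) not in CATALOG:
                raise CatalogError(f"atom {name!r} of base {r.base!r} not in catalog")
    return nodes


def build_node_features(s: RnaStructure, config: EncodingConfig) -> np.ndarray:
    """Per-node [base one-hot | atom one-hot | positional encoding] vectors."""
    residues = s.residues
    nodes = _node_list(s, config)
    feats = np.zeros((len(nodes), config.feature_dim))
    pe_cache: dict[int, np.ndarray] = {}
    for k, (gi, name) in enumerate(nodes):
        base = residues[gi].base
        feats[k, BASE_INDEX[base]] = 1.0
        feats[k, 4 + CATALOG.index(base, name)] = 1.0
        if gi not in pe_cache:
            # Global residue index: keeps sequentially distinct residues
            # distinguishable across chains as well as within one chain.
            pe_cache[gi] = positional_encoding(gi, config.pe_dim)
        feats[k, 4 + len(CATALOG):] = pe_cache[gi]
    return feats


def _c4_positions(s: RnaStructure) -> dict[int, np.ndarray]:
    out = {}
    for gi, r in enumerate(s.residues):
        if r.has("C4'"):
            out[gi] = r.coord("C4'")
        else:
            logger.warning("residue %s%s lacks C4'; spatial edge typing skipped",
                           r.chain_id, r.auth_number)
    return out


def _adjacent_pairs(s: RnaStructure) -> set[tuple[int, int]]:
    adj = set()
    for lo, hi in s.chain_bounds():
        for gi in range(lo, hi - 1):
            adj.add((gi, gi + 1))
    return adj


def _expand(nodes_i: list[int], nodes_j: list[int], etype: int,
            out: list[tuple[int, int, int]]) -> None:
    for a in nodes_i:
        for b in nodes_j:
            out.append((a, b, etype))
            out.append((b, a, etype))


def build_edges_contact4(
    s: RnaStructure,
    pairs: set[BasePair],
    spatial_cutoff: float,
    nodes: list[tuple[int, str]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """4-type edges: intra-residue, sequential, base-pair, spatial.

    Residue-pair level precedence (intra > sequential > base-pair >
    spatial) guarantees each atom pair one type. Spatial edges require
    C4'-C4' distance strictly below ``spatial_cutoff``.
    """
    if nodes is None:
        nodes = _node_list(s, EncodingConfig())
    index: dict[tuple[int, str], int] = {key: k for k, key in enumerate(nodes)}
    residues = s.residues
    by_res: dict[int, list[int]] = {}
    base_nodes: dict[int, list[int]] = {}
    for k, (gi, name) in enumerate(nodes):
        by_res.setdefault(gi, []).append(k)
        if name not in ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                        "C3'", "O3'", "C2'", "O2'", "C1'"):
            base_nodes.setdefault(gi, []).append(k)

    edges: list[tuple[int, int, int]] = []
    for gi, members in by_res.items():
        for a_i, a in enumerate(members):
            for b in members[a_i + 1:]:
                edges.append((a, b, 0))
                edges.append((b, a, 0))

    adjacent = _adjacent_pairs(s)
    for gi, gj in adjacent:
        _expand(by_res.get(gi, []), by_res.get(gj, []), 1, edges)

    paired = {tuple(sorted(p)) for p in pairs}
    for gi, gj in paired:
        if (gi, gj) in adjacent:
            continue
        _expand(base_nodes.get(gi, []), base_nodes.get(gj, []), 2, edges)

    c4 = _c4_positions(s)
    n_res = len(residues)
    for gi in range(n_res):
        for gj in range(gi + 1, n_res):
            if (gi, gj) in adjacent or (gi, gj) in paired:
                continue
            if gi not in c4 or gj not in c4:
                continue
            if np.linalg.norm(c4[gi] - c4[gj]) < spatial_cutoff:
                _expand(by_res.get(gi, []), by_res.get(gj, []), 3, edges)

    return _edges_to_arrays(edges, 4)


def build_edges_relation5(
    s: RnaStructure,
    relation_cutoff: float,
    nodes: list[tuple[int, str]] | None = None,
    cutoff_on_c4: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """5-class relational edges centred on the C4' backbone anchor."""
    if nodes is None:
        nodes = _node_list(s, EncodingConfig())
    residues = s.residues
    by_res: dict[int, list[int]] = {}
    c4_node: dict[int, int] = {}
    for k, (gi, name) in enumerate(nodes):
        by_res.setdefault(gi, []).append(k)
        if name == "C4'":
            c4_node[gi] = k

    c4 = _c4_positions(s)
    adjacent = _adjacent_pairs(s)
    edges: list[tuple[int, int, int]] = []
    n_res = len(residues)

    # classes 1-2: C4'-C4'
    for gi in range(n_res):
        for gj in range(gi + 1, n_res):
            if gi not in c4_node or gj not in c4_node:
                continue
            if (gi, gj) in adjacent:
                etype = 0
            else:
                if cutoff_on_c4 and (
                    gi not in c4 or gj not in c4
                    or np.linalg.norm(c4[gi] - c4[gj]) >= relation_cutoff
                ):
                    continue
                etype = 1
            edges.append((c4_node[gi], c4_node[gj], etype))
            edges.append((c4_node[gj], c4_node[gi], etype))

    # classes 3-4: intra-residue
    for gi, members in by_res.items():
        c4k = c4_node.get(gi)
        non_c4 = [k for k in members if k != c4k]
        if c4k is not None:
            for k in non_c4:
                edges.append((k, c4k, 2))
                edges.append((c4k, k, 2))
        for a_i, a in enumerate(non_c4):
            for b in non_c4[a_i + 1:]:
                edges.append((a, b, 3))
                edges.append((b, a, 3))

    # class 5: inter-residue non-C4' within the cutoff
    for gi in range(n_res):
        for gj in range(gi + 1, n_res):
            if gi not in c4 or gj not in c4:
                continue
            if np.linalg.norm(c4[gi] - c4[gj]) >= relation_cutoff:
                continue
            non_i = [k for k in by_res.get(gi, []) if k != c4_node.get(gi)]
            non_j = [k for k in by_res.get(gj, []) if k != c4_node.get(gj)]
            _expand(non_i, non_j, 4, edges)

    return _edges_to_arrays(edges, 5)


def _edges_to_arrays(edges: list[tuple[int, int, int]], n_types: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    if not edges:
        return np.zeros((0, 2), dtype=int), np.zeros((0, n_types))
    arr = np.array(sorted(edges), dtype=int)
    attr = np.zeros((len(arr), n_types))
    attr[np.arange(len(arr)), arr[:, 2]] = 1.0
    return arr[:, :2].copy(), attr


def encode_graph(
    s: RnaStructure,
    pairs: set[BasePair] | None,
    config: EncodingConfig | None = None,
) -> RnaGraph:
    """Full graph: nodes, features, coordinates, typed edges per config."""
    config = config or EncodingConfig()
    pairs = pairs or set()
    nodes = _node_list(s, config)
    residues = s.residues
    coords = np.array([residues[gi].coord(name) for gi, name in nodes]).reshape(-1, 3)
    feats = build_node_features(s, config)
    if config.edge_scheme == "contact_4type":
        edge_index, edge_attr = build_edges_contact4(
            s, pairs, config.spatial_cutoff, nodes)
    else:
        edge_index, edge_attr = build_edges_relation5(
            s, config.relation_cutoff, nodes, config.relation_cutoff_on_c4)
    return RnaGraph(feats, coords, edge_index, edge_attr, nodes, config)
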
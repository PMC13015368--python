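"""Node features, positional encoding and the two edge-typing schemes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rnarefine.errors import CatalogError, ConfigError
from rnarefine.graph_encoding import (
    BASE_INDEX,
    EncodingConfig,
    build_node_features,
    encode_graph,
    positional_encoding,
)
from rnarefine.rna_io import CATALOG

from conftest import residue_from_template, structure_of


class TestPositionalEncoding:
    def test_zero_index_alternates_zero_one(self):
        pe = positional_encoding(0, 8)
        np.testing.assert_allclose(pe, [0, 1] * 4)

    def test_index_one_d4_values(self):
        pe = positional_encoding(1, 4)
        np.testing.assert_allclose(
            pe, [0.8414709848, 0.5403023059, 0.0099998333, 0.9999500004],
            atol=1e-9)

    @pytest.mark.parametrize("i", [0, 1, 7, 123])
    def test_squared_norm_is_half_d(self, i):
        for d in (4, 16, 32):
            assert np.linalg.norm(positional_encoding(i, d)) ** 2 == pytest.approx(d / 2)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ConfigError):
            positional_encoding(3, 5)


class TestNodeFeatures:
    def test_vector_length_and_one_hots(self, adenosine):
        config = EncodingConfig(pe_dim=16)
        feats = build_node_features(adenosine, config)
        assert feats.shape[1] == 4 + 85 + 16
        names = CATALOG.names("A")
        k = names.index("C4'")
        row = feats[k]
        hot = np.nonzero(row[:89])[0]
        assert list(hot) == [BASE_INDEX["A"], 4 + CATALOG.index("A", "C4'")]

    def test_identical_atoms_differ_only_in_pe(self):
        r0 = residue_from_template("A", auth=1, index=0)
        r1 = residue_from_template("A", auth=2, index=1, offset=(30, 0, 0))
        s = structure_of([r0, r1])
        feats = build_node_features(s, EncodingConfig())
        n = len(CATALOG.names("A"))
        np.testing.assert_array_equal(feats[:n, :89], feats[n:2 * n, :89])
        assert not np.allclose(feats[0, 89:], feats[n, 89:])

    def test_unknown_atom_name_raises(self, adenosine):
        s = adenosine.copy()
        atom = s.residues[0].atoms.pop("N7")
        atom.name = "XX9"
        s.residues[0].atoms["XX9"] = atom
        with pytest.raises(CatalogError):
            build_node_features(s, EncodingConfig())


def _edges_by_type(graph):
    out = {}
    types = np.argmax(graph.edge_attr, axis=1)
    for (a, b), tt in zip(graph.edge_index, types):
        out.setdefault(int(tt), set()).add((int(a), int(b)))
    return out


def _res_of(graph):
    return graph.residue_index


class TestContact4Edges:
    def test_adjacent_residues_fully_connected_type2(self):
        r0 = residue_from_template("A", auth=1, index=0)
        r1 = residue_from_template("U", auth=2, index=1, offset=(12, 0, 0))
        s = structure_of([r0, r1])
        g = encode_graph(s, set(), EncodingConfig(spatial_cutoff=8.0))
        res = _res_of(g)
        by_type = _edges_by_type(g)
        cross = {(a, b) for a in range(g.n_nodes) for b in range(g.n_nodes)
                 if res[a] != res[b]}
        assert by_type[1] == cross

    def test_nine_angstrom_apart_no_spatial_edges(self):
        # non-adjacent, unpaired residues with C4'-C4' = 9 Å get nothing
        r0 = residue_from_template("A", auth=1, index=0)
        mid = residue_from_template("G", chain_id="B", auth=1, index=0, offset=(60, 0, 0))
        r2 = residue_from_template("U", chain_id="C", auth=1, index=0)
        delta = r0.coord("C4'") + np.array([9.0, 0, 0]) - r2.coord("C4'")
        for a in r2.atoms.values():
            a.position = a.position + delta
        s = structure_of([r0, mid, r2])
        g = encode_graph(s, set(), EncodingConfig(spatial_cutoff=8.0))
        res = _res_of(g)
        for (a, b) in g.edge_index:
            assert not {res[a], res[b]} == {0, 2}

    def test_basepair_edges_touch_base_atoms_only(self, duplex6):
        s, pairs, _ = duplex6
        g = encode_graph(s, pairs, EncodingConfig())
        by_type = _edges_by_type(g)
        sugar = set(CATALOG.names("A")[:12])
        for a, b in by_type[2]:
            assert g.node_map[a][1] not in sugar
            assert g.node_map[b][1] not in sugar

    def test_types_partition_pairs(self, duplex6):
        s, pairs, _ = duplex6
        g = encode_graph(s, pairs, EncodingConfig())
        seen = {}
        types = np.argmax(g.edge_attr, axis=1)
        for (a, b), tt in zip(g.edge_index, types):
            key = (int(a), int(b))
            assert key not in seen
            seen[key] = tt
        for (a, b), tt in seen.items():
            assert seen[(b, a)] == tt  # symmetric


@pytest.fixture(scope="module")
def relation_graph(duplex6):
    s, pairs, _ = duplex6
    return encode_graph(s, pairs, EncodingConfig(edge_scheme="relation_5type"))


class TestRelation5Edges:

    def test_adjacent_c4_edges_class1(self, relation_graph):
        graph = relation_graph
        res = _res_of(graph)
        by_type = _edges_by_type(graph)
        for a, b in by_type[0]:
            assert graph.node_map[a][1] == "C4'" and graph.node_map[b][1] == "C4'"
            assert abs(res[a] - res[b]) == 1

    def test_intra_residue_classes(self, relation_graph):
        graph = relation_graph
        by_type = _edges_by_type(graph)
        res = _res_of(graph)
        for a, b in by_type[2]:
            assert res[a] == res[b]
            assert "C4'" in (graph.node_map[a][1], graph.node_map[b][1])
        for a, b in by_type[3]:
            assert res[a] == res[b]
            assert graph.node_map[a][1] != "C4'" and graph.node_map[b][1] != "C4'"

    def test_distant_residues_get_no_inter_edges(self):
        r0 = residue_from_template("A", auth=1, index=0)
        r1 = residue_from_template("U", chain_id="B", auth=1, index=0)
        delta = r0.coord("C4'") + np.array([15.0, 0, 0]) - r1.coord("C4'")
        for a in r1.atoms.values():
            a.position = a.position + delta
        s = structure_of([r0, r1])
        g = encode_graph(s, set(), EncodingConfig(edge_scheme="relation_5type",
                                                  relation_cutoff=14.0))
        res = _res_of(g)
        for a, b in g.edge_index:
            assert res[a] == res[b]


class TestEncodeGraph:
    def test_node_count_all_atom(self):
        r0 = residue_from_template("A", auth=1, index=0)
        r1 = residue_from_template("U", auth=2, index=1, offset=(12, 0, 0))
        g = encode_graph(structure_of([r0, r1]), set(), EncodingConfig())
        assert g.n_nodes == 42  # 22 + 20

    def test_node_count_five_point(self, duplex6):
        s, pairs, _ = duplex6
        g = encode_graph(s, pairs, EncodingConfig(resolution="five_point",
                                                  edge_scheme="relation_5type"))
        assert g.n_nodes == 5 * 12

    def test_rigid_motion_leaves_graph_invariant(self, duplex6, rng):
        s, pairs, _ = duplex6
        g0 = encode_graph(s, pairs, EncodingConfig())
        R = Rotation.random(random_state=7).as_matrix()
        v = rng.normal(size=3) * 10
        moved = s.copy()
        for r in moved.residues:
            for a in r.atoms.values():
                a.position = R @ a.position + v
        g1 = encode_graph(moved, pairs, EncodingConfig())
        np.testing.assert_array_equal(g0.edge_index, g1.edge_index)
        np.testing.assert_array_equal(g0.edge_attr, g1.edge_attr)
        np.testing.assert_array_equal(g0.node_features, g1.node_features)

    def test_atom_record_order_irrelevant(self, duplex6):
        s, pairs, _ = duplex6
        shuffled = s.copy()
        for r in shuffled.residues:
            items = list(r.atoms.items())[::-1]
            r.atoms = dict(items)
        g0 = encode_graph(s, pairs, EncodingConfig())
        g1 = encode_graph(shuffled, pairs, EncodingConfig())
        assert g0.node_map == g1.node_map
        np.testing.assert_array_equal(g0.coords, g1.coords)
        np.testing.assert_array_equal(g0.edge_index, g1.edge_index)
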
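"""k-hop enumeration and force-field-style geometric features.

Oracles: brute-force simple-path enumeration via networkx for the k-hop
definition; a law-of-cosines angle and a projection-based signed dihedral for
the internal coordinates; trig multiple-angle identities for the torsion
basis.
"""

import numpy as np
import networkx as nx
import pytest

from ffitrnet.geometry import (
    DegenerateGeometryError,
    GeometryError,
    HopPath,
    bond_angle,
    bond_length,
    dihedral_angle,
    enumerate_khop,
    hop_features,
    path_feature_vector,
)
from ffitrnet.io import MolecularGraph3D

from conftest import random_rotation


def graph_from_edges(edges, n=None, coords=None):
    n = n if n is not None else max(max(e) for e in edges) + 1
    coords = coords if coords is not None else np.zeros((n, 3))
    return MolecularGraph3D("g", ["C"] * n, [tuple(e) for e in edges], np.asarray(coords, float))


def brute_force_khop(edges, n, k):
    """Independent oracle: all simple paths of k edges whose endpoints sit at
    shortest-path distance exactly k."""
    g = nx.Graph(edges)
    g.add_nodes_from(range(n))
    dist = dict(nx.all_pairs_shortest_path_length(g))
    out = set()
    for src in g.nodes:
        for dst in g.nodes:
            if src == dst or dist[src].get(dst) != k:
                continue
            for path in nx.all_simple_paths(g, src, dst, cutoff=k):
                if len(path) == k + 1:
                    out.add(tuple(path))
    return out


class TestKHopEnumeration:
    def test_path_graph_worked_example(self):
        g = graph_from_edges([(0, 1), (1, 2), (2, 3)])
        hop2 = {p.atoms for p in enumerate_khop(g, 2)}
        assert hop2 == {(0, 1, 2), (2, 1, 0), (1, 2, 3), (3, 2, 1)}
        hop3 = {p.atoms for p in enumerate_khop(g, 3)}
        assert hop3 == {(0, 1, 2, 3), (3, 2, 1, 0)}

    def test_benzene_para_partner_via_two_paths(self):
        ring = [(i, (i + 1) % 6) for i in range(6)]
        g = graph_from_edges(ring)
        hop3 = enumerate_khop(g, 3)
        for src in range(6):
            para = (src + 3) % 6
            paths = [p for p in hop3 if p.source == src]
            assert len(paths) == 2
            assert all(p.endpoint == para for p in paths)

    def test_cyclobutane_has_no_hop3(self):
        ring = [(i, (i + 1) % 4) for i in range(4)]
        g = graph_from_edges(ring)
        assert enumerate_khop(g, 3) == []
        # and hop-2 endpoints are the diagonals only
        assert {(p.source, p.endpoint) for p in enumerate_khop(g, 2)} == {
            (0, 2), (2, 0), (1, 3), (3, 1),
        }

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_brute_force_on_random_graphs(self, k):
        rng = np.random.default_rng(k)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            edges = list(g.edges)
            mg = graph_from_edges(edges, n=n)
            ours = {p.atoms for p in enumerate_khop(mg, k)}
            assert ours == brute_force_khop(edges, n, k)

    def test_ordering_is_deterministic(self):
        ring = [(i, (i + 1) % 6) for i in range(6)]
        g = graph_from_edges(ring)
        paths = enumerate_khop(g, 2)
        keys = [(p.source, p.atoms) for p in paths]
        assert keys == sorted(keys)

    def test_invalid_k_raises(self):
        g = graph_from_edges([(0, 1)])
        with pytest.raises(ValueError):
            enumerate_khop(g, 4)

    def test_hop_path_invariants(self):
        with pytest.raises(AssertionError):
            HopPath(2, (0, 1))  # wrong length
        with pytest.raises(AssertionError):
            HopPath(2, (0, 1, 0))  # repeated atom


def oracle_angle(a, b, c):
    """Law-of-cosines angle at b, independent of the dot-product route."""
    ab = np.linalg.norm(a - b)
    cb = np.linalg.norm(c - b)
    ac = np.linalg.norm(a - c)
    return np.arccos(np.clip((ab**2 + cb**2 - ac**2) / (2 * ab * cb), -1, 1))


def oracle_dihedral(a, b, c, d):
    """Projection-based signed dihedral: project the outer bonds onto the
    plane perpendicular to the central bond and take the signed angle."""
    e = (c - b) / np.linalg.norm(c - b)
    u = (a - b) - np.dot(a - b, e) * e
    v = (d - c) - np.dot(d - c, e) * e
    return np.arctan2(np.dot(np.cross(e, u), v), np.dot(u, v))


class TestInternalCoordinates:
    def test_right_angle(self):
        a, b, c = np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 1.0, 0])
        assert bond_angle(a, b, c) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_planar_cis_and_trans_dihedral(self):
        b, c = np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        a_cis = np.array([-1.0, 1.0, 0])
        d_cis = np.array([2.0, 1.0, 0])
        d_trans = np.array([2.0, -1.0, 0])
        assert dihedral_angle(a_cis, b, c, d_cis) == pytest.approx(0.0, abs=1e-12)
        assert abs(dihedral_angle(a_cis, b, c, d_trans)) == pytest.approx(np.pi, abs=1e-12)

    def test_random_angles_and_dihedrals_match_oracles(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 2
            assert bond_angle(*pts[:3]) == pytest.approx(
                oracle_angle(*pts[:3]), abs=1e-10
            )
            assert dihedral_angle(*pts) == pytest.approx(
                oracle_dihedral(*pts), abs=1e-10
            )

    def test_degenerate_geometry_raises(self):
        z = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            bond_angle(z, z, np.array([1.0, 0, 0]))
        collinear = [np.array([float(i), 0, 0]) for i in range(4)]
        with pytest.raises(DegenerateGeometryError):
            dihedral_angle(*collinear)

    def test_bond_length(self):
        assert bond_length(np.zeros(3), np.array([3.0, 4.0, 0.0])) == 5.0


def butane_like():
    """A 4-atom chain with a non-planar geometry."""
    coords = np.array(
        [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.2, 1.3, 0.2], [3.7, 1.4, 0.7]]
    )
    return graph_from_edges([(0, 1), (1, 2), (2, 3)], coords=coords)


class TestHopFeatures:
    def test_hop1_vector_is_length_and_square(self):
        g = graph_from_edges([(0, 1)], coords=[[0, 0, 0], [1.5, 0, 0]])
        fs = hop_features(g)
        i = list(map(tuple, fs.pairs[1])).index((0, 1))
        assert np.allclose(fs.features[1][i], [1.5, 2.25])

    def test_inverse_power_slots_exact(self):
        g = graph_from_edges(
            [(0, 1), (1, 2)], coords=[[0, 0, 0], [1.0, 1.0, 0], [2.0, 0, 0]]
        )
        fs = hop_features(g)
        i = list(map(tuple, fs.pairs[2])).index((0, 2))
        assert np.allclose(fs.features[2][i][2:], [0.5, 0.015625, 0.000244140625])

    def test_torsion_trig_slots_at_cis_and_trans(self):
        coords_cis = [[-1, 1, 0], [0, 0, 0], [1.0, 0, 0], [2.0, 1, 0]]
        g = graph_from_edges([(0, 1), (1, 2), (2, 3)], coords=coords_cis)
        vec = path_feature_vector(g, HopPath(3, (0, 1, 2, 3)))
        assert np.allclose(vec[:6], [1, 1, 1, 0, 0, 0], atol=1e-12)
        coords_trans = [[-1, 1, 0], [0, 0, 0], [1.0, 0, 0], [2.0, -1, 0]]
        g2 = graph_from_edges([(0, 1), (1, 2), (2, 3)], coords=coords_trans)
        vec2 = path_feature_vector(g2, HopPath(3, (0, 1, 2, 3)))
        assert np.allclose(vec2[:6], [-1, 1, -1, 0, 0, 0], atol=1e-12)

    def test_trig_slots_satisfy_multiple_angle_identities(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            g = graph_from_edges(
                [(0, 1), (1, 2), (2, 3)], coords=rng.normal(size=(4, 3)) * 2
            )
            c1, c2, c3, s1, s2, s3 = path_feature_vector(g, HopPath(3, (0, 1, 2, 3)))[:6]
            assert c2 == pytest.approx(2 * c1**2 - 1, abs=1e-10)
            assert s2 == pytest.approx(2 * s1 * c1, abs=1e-10)
            assert c3 == pytest.approx(4 * c1**3 - 3 * c1, abs=1e-10)
            assert s3 == pytest.approx(3 * s1 - 4 * s1**3, abs=1e-10)
            for cn, sn in ((c1, s1), (c2, s2), (c3, s3)):
                assert cn**2 + sn**2 == pytest.approx(1.0, abs=1e-10)

    def test_rigid_motion_invariance(self, small_graphs):
        rng = np.random.default_rng(3)
        g = small_graphs[0]
        ref = hop_features(g)
        for _ in range(20):
            rot = random_rotation(rng)
            shift = rng.normal(size=3) * 5
            g2 = MolecularGraph3D(
                g.mol_id, g.atoms, g.bonds, g.coords @ rot.T + shift
            )
            fs2 = hop_features(g2)
            for k in (1, 2, 3):
                assert np.array_equal(ref.pairs[k], fs2.pairs[k])
                assert np.allclose(ref.features[k], fs2.features[k], atol=1e-8)

    def test_mirror_reflection_flips_only_sin_slots(self):
        g = butane_like()
        ref = hop_features(g)
        mirrored = MolecularGraph3D(
            g.mol_id, g.atoms, g.bonds, g.coords * np.array([1.0, 1.0, -1.0])
        )
        fs = hop_features(mirrored)
        r, m = ref.features[3][0], fs.features[3][0]
        assert np.allclose(m[3:6], -r[3:6], atol=1e-12)  # sin slots flip
        assert np.allclose(m[:3], r[:3], atol=1e-12)     # cos slots fixed
        assert np.allclose(m[6:], r[6:], atol=1e-12)     # distance powers fixed
        for k in (1, 2):
            assert np.allclose(ref.features[k], fs.features[k], atol=1e-12)

    def test_pair_symmetry_under_reversal(self):
        g = butane_like()
        fs = hop_features(g)
        for k in (1, 2):
            lookup = {tuple(p): f for p, f in zip(fs.pairs[k], fs.features[k])}
            for (i, j), f in lookup.items():
                assert np.allclose(f, lookup[(j, i)], atol=1e-12)
        # the standard atan2 dihedral is invariant under path reversal (both
        # plane normals and the central bond flip), so every hop-3 slot is
        # reversal-symmetric; mirror reflection is what flips the sin slots
        lookup3 = {tuple(p): f for p, f in zip(fs.pairs[3], fs.features[3])}
        for (i, j), f in lookup3.items():
            assert np.allclose(f, lookup3[(j, i)], atol=1e-12)

    def test_ring_paths_are_summed_per_pair(self):
        ring = [(i, (i + 1) % 6) for i in range(6)]
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(6, 3)) * 2
        g = graph_from_edges(ring, coords=coords)
        fs = hop_features(g)
        # para pair reached via two 3-bond paths: feature = sum of both
        vecs = [
            path_feature_vector(g, HopPath(3, p.atoms))
            for p in enumerate_khop(g, 3)
            if p.source == 0
        ]
        i = list(map(tuple, fs.pairs[3])).index((0, 3))
        assert np.allclose(fs.features[3][i], np.sum(vecs, axis=0), atol=1e-12)

    def test_close_endpoints_raise(self):
        coords = [[0, 0, 0], [1.0, 0, 0], [0.05, 0.05, 0]]
        g = graph_from_edges([(0, 1), (1, 2)], coords=coords)
        with pytest.raises(GeometryError):
            hop_features(g)

    def test_degenerate_dihedral_zeroes_trig_slots_with_warning(self):
        coords = [[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1.0, 0]]
        g = graph_from_edges([(0, 1), (1, 2), (2, 3)], coords=coords)
        with pytest.warns(UserWarning, match="degenerate"):
            vec = path_feature_vector(g, HopPath(3, (0, 1, 2, 3)))
        assert np.allclose(vec[:6], 0.0)
        assert np.all(vec[6:] > 0)
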
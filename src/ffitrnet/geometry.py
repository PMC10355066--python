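"""k-hop path enumeration and force-field-style geometric features.

In classical force fields the potential energy decomposes into bond, angle,
torsion and non-bonded terms.  Each term is a fixed function of one geometric
argument (bond length l, bond angle theta, dihedral phi, non-bonded distance
r) multiplied by force constants.  Expanding those terms shows each is linear
in a small basis:

    bond     -> (l, l^2)
    angle    -> (theta, theta^2)
    torsion  -> (cos phi, cos 2phi, cos 3phi, sin phi, sin 2phi, sin 3phi)
    non-bond -> (r^-1, r^-6, r^-12)        [Coulomb + Lennard-Jones]

The force constants are absorbed into learnable linear embeddings downstream;
this module computes only the geometric basis.  Non-bonded distance powers are
attached to the 2-hop and 3-hop pairs (the endpoints of angle and torsion
paths), not to a global pairwise matrix.

A k-hop neighbor of atom i is an atom j connected by a simple path of exactly
k bonds whose topological shortest-path distance from i is exactly k, so each
neighbor belongs to exactly one hop class; features of multiple equal-length
paths between the same pair (ring systems) are summed, mirroring the sums over
angles/dihedrals in the energy expressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import MolecularGraph3D

#: geometric feature vector length per hop class
HOP_FEATURE_DIMS = {1: 2, 2: 5, 3: 9}

#: endpoint distances below this (Angstrom) make r^-12 explode
MIN_PAIR_DISTANCE = 0.1


class DegenerateGeometryError(ValueError):
    """Zero-length bond vector or undefined dihedral frame."""


class GeometryError(ValueError):
    """Pathological conformer geometry (e.g. near-coincident endpoints)."""


@dataclass(frozen=True)
class HopPath:
    """An ordered simple path of `hop` bonds starting at the source atom."""

    hop: int
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        assert len(self.atoms) == self.hop + 1
        assert len(set(self.atoms)) == len(self.atoms)

    @property
    def source(self) -> int:
        return self.atoms[0]

    @property
    def endpoint(self) -> int:
        return self.atoms[-1]


@dataclass
class HopFeatureSet:
    """Per ordered atom pair (i, j), geometric features summed over paths.

    ``pairs[k]`` is an (P_k, 2) int array of ordered (source, endpoint) pairs
    and ``features[k]`` the matching (P_k, dim_k) float array, dim = 2/5/9 for
    hop 1/2/3.  Pairs are sorted lexicographically for determinism.
    """

    pairs: dict[int, np.ndarray]
    features: dict[int, np.ndarray]


def _as_nx(graph: MolecularGraph3D) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from(graph.bonds)
    return g


def enumerate_khop(graph: MolecularGraph3D, k: int) -> list[HopPath]:
    """All simple paths of exactly k bonds whose endpoints are at
    shortest-path distance exactly k, in both directions, ordered by
    (source, lexicographic path)."""
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    g = _as_nx(graph)
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=k))
    paths: list[HopPath] = []
    for src in range(graph.n_atoms):
        stack = [(src,)]
        found: list[tuple[int, ...]] = []
        while stack:
            path = stack.pop()
            if len(path) == k + 1:
                if dist[src].get(path[-1]) == k:
                    found.append(path)
                continue
            for nbr in g.neighbors(path[-1]):
                if nbr not in path:
                    stack.append(path + (nbr,))
        paths.extend(HopPath(k, p) for p in sorted(found))
    return paths


# ---------------------------------------------------------------------------
# Internal coordinates
# ---------------------------------------------------------------------------

def bond_length(a: np.ndarray, b: np.ndarray) -> float:
    """Distance between two atoms, Angstrom."""
    return float(np.linalg.norm(np.asarray(b, float) - np.asarray(a, float)))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at the central atom b, in [0, pi] radians."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length bond vector in angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosang))


def dihedral_angle(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> float:
    """Signed dihedral in (-pi, pi] via the atan2 convention on the two plane
    normals; 0 for planar cis, pi for planar trans."""
    p = [np.asarray(x, float) for x in (a, b, c, d)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise DegenerateGeometryError("collinear frame: dihedral undefined")
    phi = np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2))
    if phi <= -np.pi:  # fold -pi onto +pi for the (-pi, pi] convention
        phi = np.pi
    return float(phi)


# ---------------------------------------------------------------------------
# Hop feature vectors
# ---------------------------------------------------------------------------

def _inverse_powers(r: float, where: str) -> tuple[float, float, float]:
    if r < MIN_PAIR_DISTANCE:
        raise GeometryError(
            f"{where}: endpoint distance {r:.4f} A below {MIN_PAIR_DISTANCE} A"
        )
    return 1.0 / r, r ** -6, r ** -12


def path_feature_vector(graph: MolecularGraph3D, path: HopPath) -> np.ndarray:
    """Geometric feature vector of a single path (before per-pair summation)."""
    xyz = graph.coords[list(path.atoms)]
    if path.hop == 1:
        l = bond_length(xyz[0], xyz[1])
        return np.array([l, l * l])
    if path.hop == 2:
        theta = bond_angle(xyz[0], xyz[1], xyz[2])
        r1, r6, r12 = _inverse_powers(
            bond_length(xyz[0], xyz[2]), f"hop-2 pair {path.atoms}"
        )
        return np.array([theta, theta * theta, r1, r6, r12])
    # hop 3: torsion trig basis + non-bonded inverse powers
    r1, r6, r12 = _inverse_powers(
        bond_length(xyz[0], xyz[3]), f"hop-3 pair {path.atoms}"
    )
    try:
        phi = dihedral_angle(*xyz)
        trig = [
            np.cos(phi), np.cos(2 * phi), np.cos(3 * phi),
            np.sin(phi), np.sin(2 * phi), np.sin(3 * phi),
        ]
    except DegenerateGeometryError:
        warnings.warn(
            f"degenerate dihedral frame on path {path.atoms}; "
            "torsion slots set to zero"
        )
        trig = [0.0] * 6
    return np.array(trig + [r1, r6, r12])


def hop_features(graph: MolecularGraph3D) -> HopFeatureSet:
    """Per-pair geometric features for hops 1-3, summed over qualifying paths."""
    pairs: dict[int, np.ndarray] = {}
    feats: dict[int, np.ndarray] = {}
    for k in (1, 2, 3):
        acc: dict[tuple[int, int], np.ndarray] = {}
        for path in enumerate_khop(graph, k):
            vec = path_feature_vector(graph, path)
            key = (path.source, path.endpoint)
            acc[key] = acc.get(key, 0.0) + vec
        if acc:
            keys = sorted(acc)
            pairs[k] = np.array(keys, dtype=np.int64)
            feats[k] = np.stack([acc[key] for key in keys])
        else:
            pairs[k] = np.zeros((0, 2), dtype=np.int64)
            feats[k] = np.zeros((0, HOP_FEATURE_DIMS[k]))
    return HopFeatureSet(pairs=pairs, features=feats)


def dump_features_long(
    graphs: list[MolecularGraph3D], featsets: list[HopFeatureSet]
):
    """Long-form table ``mol_id,hop,i,j,f1..f9`` for inspection/baselines."""
    import pandas as pd

    rows = []
    for g, fs in zip(graphs, featsets):
        for k in (1, 2, 3):
            for (i, j), vec in zip(fs.pairs[k], fs.features[k]):
                row = {"mol_id": g.mol_id, "hop": k, "i": int(i), "j": int(j)}
                for n in range(9):
                    row[f"f{n + 1}"] = vec[n] if n < len(vec) else np.nan
                rows.append(row)
    return pd.DataFrame(rows)
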
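import numpy as np
import pytest

from ffitrnet.io import curate, prepare_graphs
from ffitrnet.model import ModelConfig, ModelParameters
from ffitrnet.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_records():
    """60 deterministic synthetic CHON molecules with surrogate targets."""
    return generate(SyntheticSpec(n=60, seed=11, noise_sd=0.02))


@pytest.fixture(scope="session")
def small_graphs(small_records):
    accepted, _ = curate(small_records, conformer_seed=0)
    return prepare_graphs(accepted, conformer_seed=0)


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(
        d_model=16, n_heads=2, n_ffi_layers=1, dropout=0.0, readout="mean"
    )


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return ModelParameters(tiny_config, seed=3)


def permute_graph(graph, perm):
    """Relabel atoms of a MolecularGraph3D by permutation `perm`
    (new index -> old index)."""
    import copy

    inv = np.argsort(perm)
    g = copy.deepcopy(graph)
    g.atoms = [graph.atoms[i] for i in perm]
    g.coords = graph.coords[perm]
    g.bonds = [(int(inv[a]), int(inv[b])) for a, b in graph.bonds]
    g.annotations = [graph.annotations[i] for i in perm]
    if graph.atom_features is not None:
        g.atom_features = graph.atom_features[perm]
    return g


def random_rotation(rng):
    """Uniform-ish proper rotation matrix from a QR decomposition."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
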
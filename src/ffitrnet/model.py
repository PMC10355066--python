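"""The force-field-inspired graph transformer (FFiTrNet-style architecture).

Per molecule, heavy atoms carry 66-long chemistry feature vectors.  The
forward pass is:

1. a linear atom embedding (66 -> d_model);
2. ``n_ffi_layers`` blocks, each computing three k-hop attention updates
   (k = 1, 2, 3: bond, angle and torsion neighborhoods).  Attention logits
   combine scaled query-key compatibility with a learned per-head projection
   of the pair's energy embedding, and messages add a learned projection of
   the same embedding — the energy embeddings are linear maps of the
   geometric bases (l, l^2), (theta, theta^2, r^-1, r^-6, r^-12) and the
   torsion/non-bonded basis, so the classical force constants are absorbed
   into learnable weights;
3. per atom, the three hop outputs are stacked behind a learnable output
   token and passed through a standard Transformer encoder (1 layer by
   default, positional encoding off by default since the four slots have no
   meaningful order); the encoder state at the output-token slot becomes the
   atom's new representation;
4. readout pooling over atoms (sum by default, mean optional) and a 2-layer
   MLP head producing the scalar density prediction.

Pre-norm residual blocks are used throughout, so an atom with an empty hop-k
neighbor set passes through that hop's attention unchanged.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geometry import HOP_FEATURE_DIMS, HopFeatureSet, hop_features
from .io import ATOM_FEATURE_LENGTH, MolecularGraph3D
from .nn.autodiff import (
    Tensor,
    dropout,
    layer_norm,
    linear,
    segment_softmax,
    softmax,
)

_FFN_FACTOR = 2  # encoder feed-forward width = _FFN_FACTOR * d_model


@dataclass(frozen=True)
class ModelConfig:
    d_model: int = 128
    n_heads: int = 4
    n_ffi_layers: int = 3
    n_encoder_layers: int = 1
    use_positional_encoding: bool = False
    dropout: float = 0.1
    readout: str = "sum"

    def __post_init__(self) -> None:
        if self.d_model <= 0 or self.n_heads <= 0:
            raise ValueError("d_model and n_heads must be positive")
        if self.d_model % self.n_heads:
            raise ValueError("n_heads must divide d_model")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.readout not in ("sum", "mean"):
            raise ValueError("readout must be 'sum' or 'mean'")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


@dataclass(frozen=True)
class Prediction:
    mol_id: str
    rho_pred: float


class ModelParameters:
    """Flat named table of all learnable weights for a given config."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.weights: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        d = config.d_model

        def glorot(name: str, fan_in: int, fan_out: int, shape=None):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            shape = shape or (fan_in, fan_out)
            self.weights[name] = Tensor(rng.uniform(-lim, lim, shape), requires_grad=True)

        def zeros(name: str, shape):
            self.weights[name] = Tensor(np.zeros(shape), requires_grad=True)

        def ones(name: str, shape):
            self.weights[name] = Tensor(np.ones(shape), requires_grad=True)

        glorot("atom_embed.W", ATOM_FEATURE_LENGTH, d)
        zeros("atom_embed.b", (d,))
        for k, dim in HOP_FEATURE_DIMS.items():
            glorot(f"energy.hop{k}.W", dim, d)
            zeros(f"energy.hop{k}.b", (d,))
        for l in range(config.n_ffi_layers):
            for k in (1, 2, 3):
                p = f"ffi{l}.hop{k}"
                ones(f"{p}.ln.g", (d,))
                zeros(f"{p}.ln.b", (d,))
                for w in ("Wq", "Wk", "Wv", "Wm", "Wo"):
                    glorot(f"{p}.{w}", d, d)
                glorot(f"{p}.we", d, config.n_heads)
            for m in range(config.n_encoder_layers):
                p = f"ffi{l}.enc{m}"
                ones(f"{p}.ln1.g", (d,))
                zeros(f"{p}.ln1.b", (d,))
                ones(f"{p}.ln2.g", (d,))
                zeros(f"{p}.ln2.b", (d,))
                for w in ("Wq", "Wk", "Wv", "Wo"):
                    glorot(f"{p}.{w}", d, d)
                glorot(f"{p}.ffn.W1", d, _FFN_FACTOR * d)
                zeros(f"{p}.ffn.b1", (_FFN_FACTOR * d,))
                glorot(f"{p}.ffn.W2", _FFN_FACTOR * d, d)
                zeros(f"{p}.ffn.b2", (d,))
        self.weights["token"] = Tensor(
            rng.normal(0.0, 0.02, (d,)), requires_grad=True
        )
        if config.use_positional_encoding:
            self.weights["pos"] = Tensor(
                rng.normal(0.0, 0.02, (4, d)), requires_grad=True
            )
        glorot("head.W1", d, d)
        zeros("head.b1", (d,))
        glorot("head.W2", d, 1)
        zeros("head.b2", (1,))

    def __getitem__(self, name: str) -> Tensor:
        return self.weights[name]

    def items(self):
        return self.weights.items()

    @property
    def n_params(self) -> int:
        return sum(t.data.size for t in self.weights.values())

    def zero_grad(self) -> None:
        for t in self.weights.values():
            t.grad = None

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.weights.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.weights):
            raise ValueError("weight table does not match this configuration")
        for k, v in state.items():
            if v.shape != self.weights[k].data.shape:
                raise ValueError(f"shape mismatch for weight {k!r}")
            self.weights[k].data = np.asarray(v, dtype=np.float64)


# ---------------------------------------------------------------------------
# Checkpoint format: JSON config header + flat named weight table in one file
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, params: ModelParameters) -> None:
    buf = _stdio.BytesIO()
    np.savez(buf, **{k: t.data for k, t in params.weights.items()})
    header = json.dumps(asdict(params.config)).encode()
    with open(path, "wb") as fh:
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        fh.write(buf.getvalue())


def load_checkpoint(path: str | Path) -> ModelParameters:
    with open(path, "rb") as fh:
        n = int.from_bytes(fh.read(8), "little")
        config = ModelConfig(**json.loads(fh.read(n).decode()))
        npz = np.load(_stdio.BytesIO(fh.read()))
        params = ModelParameters(config, seed=0)
        params.load_state({k: npz[k] for k in npz.files})
    return params


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Several molecular graphs packed into one disjoint-union graph."""

    x: np.ndarray                      # (n_atoms_total, 66)
    mol_index: np.ndarray              # (n_atoms_total,) molecule id per atom
    n_mols: int
    mol_ids: list[str]
    pairs: dict[int, np.ndarray]       # hop -> (P_k, 2) global atom indices
    pair_feats: dict[int, np.ndarray]  # hop -> (P_k, dim_k)
    targets: np.ndarray | None = None  # (n_mols,)

    @property
    def n_atoms(self) -> int:
        return self.x.shape[0]


def make_batch(
    graphs: list[MolecularGraph3D],
    featsets: list[HopFeatureSet] | None = None,
) -> GraphBatch:
    if featsets is None:
        featsets = [hop_features(g) for g in graphs]
    xs, mol_index, ids = [], [], []
    pairs = {k: [] for k in (1, 2, 3)}
    feats = {k: [] for k in (1, 2, 3)}
    targets, have_targets = [], True
    offset = 0
    for i, (g, fs) in enumerate(zip(graphs, featsets)):
        if g.atom_features is None:
            raise ValueError(f"graph {g.mol_id} has no atom features")
        xs.append(g.atom_features)
        mol_index.append(np.full(g.n_atoms, i, dtype=np.int64))
        ids.append(g.mol_id)
        for k in (1, 2, 3):
            pairs[k].append(fs.pairs[k] + offset)
            feats[k].append(fs.features[k])
        targets.append(g.target)
        have_targets = have_targets and g.target is not None
        offset += g.n_atoms
    return GraphBatch(
        x=np.concatenate(xs),
        mol_index=np.concatenate(mol_index),
        n_mols=len(graphs),
        mol_ids=ids,
        pairs={k: np.concatenate(pairs[k]) for k in (1, 2, 3)},
        pair_feats={k: np.concatenate(feats[k]) for k in (1, 2, 3)},
        targets=np.array(targets, dtype=float) if have_targets else None,
    )


# ---------------------------------------------------------------------------
# Forward pass pieces
# ---------------------------------------------------------------------------

def embed_energy(
    features: dict[int, np.ndarray] | HopFeatureSet, params: ModelParameters
) -> dict[int, Tensor]:
    """Affine per-hop maps of the geometric bases into d_model space.

    These linear layers are the learned stand-ins for the force constants
    (K_r, K_theta, V_phi,n, q_i q_j, epsilon, sigma) of the classical energy
    terms.
    """
    feats = features.features if isinstance(features, HopFeatureSet) else features
    out = {}
    for k, f in feats.items():
        dim = HOP_FEATURE_DIMS[k]
        if f.shape[-1] != dim:
            raise ValueError(
                f"hop-{k} features must have length {dim}, got {f.shape[-1]}"
            )
        out[k] = linear(
            Tensor(f), params[f"energy.hop{k}.W"], params[f"energy.hop{k}.b"]
        )
    return out


def _heads(t: Tensor, n_heads: int, d_head: int) -> Tensor:
    return t.reshape(t.shape[0], n_heads, d_head)


def khop_attention(
    atom_states: Tensor,
    energy_embedding: Tensor,
    pairs: np.ndarray,
    params: ModelParameters,
    k: int,
    layer: int = 0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Multi-head attention of each atom over its hop-k neighbor set.

    logits_ij = [(W_q h_i) . (W_k h_j) + w_e . e_ij] / sqrt(d_head)
    message_ij = W_v h_j + W_m e_ij, softmax-weighted per source atom.

    Pre-norm residual: atoms with no hop-k neighbors are returned unchanged.
    """
    cfg = params.config
    p = f"ffi{layer}.hop{k}"
    n = atom_states.shape[0]
    if pairs.shape[0] == 0:
        return atom_states
    # canonicalize pair order so the update is bit-identical under any
    # permutation of the neighbor list
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    energy_embedding = energy_embedding.gather(order)
    h = layer_norm(atom_states, params[f"{p}.ln.g"], params[f"{p}.ln.b"])
    q = _heads(h @ params[f"{p}.Wq"], cfg.n_heads, cfg.d_head)
    key = _heads(h @ params[f"{p}.Wk"], cfg.n_heads, cfg.d_head)
    val = _heads(h @ params[f"{p}.Wv"], cfg.n_heads, cfg.d_head)
    src, dst = pairs[:, 0], pairs[:, 1]
    e_logit = energy_embedding @ params[f"{p}.we"]          # (P, H)
    e_msg = _heads(energy_embedding @ params[f"{p}.Wm"], cfg.n_heads, cfg.d_head)
    logits = ((q.gather(src) * key.gather(dst)).sum(axis=-1) + e_logit) * (
        1.0 / np.sqrt(cfg.d_head)
    )                                                        # (P, H)
    alpha = segment_softmax(logits, src, n)                  # (P, H)
    msg = (val.gather(dst) + e_msg) * alpha.reshape(len(src), cfg.n_heads, 1)
    agg = msg.segment_sum(src, n).reshape(n, cfg.d_model)
    out = dropout(agg @ params[f"{p}.Wo"], cfg.dropout, rng)
    return atom_states + out


def transformer_aggregate(
    hop_outputs: tuple[Tensor, Tensor, Tensor],
    params: ModelParameters,
    layer: int = 0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Mix the three hop representations through a Transformer encoder.

    Per atom, the 4-token sequence [output token; hop-1; hop-2; hop-3] runs
    through ``n_encoder_layers`` standard pre-norm self-attention layers and
    the state at the output-token slot is returned.  With positional encoding
    off (the default) the encoder is permutation-equivariant in the hop
    tokens, so the aggregated state does not depend on their order.
    """
    cfg = params.config
    n = hop_outputs[0].shape[0]
    d, H, dh = cfg.d_model, cfg.n_heads, cfg.d_head
    token = params["token"].reshape(1, 1, d) + Tensor(np.zeros((n, 1, d)))
    toks = [token] + [h.reshape(n, 1, d) for h in hop_outputs]
    # concatenate along the token axis
    t = _concat_tokens(toks)
    if cfg.use_positional_encoding:
        t = t + params["pos"].reshape(1, 4, d)
    for m in range(cfg.n_encoder_layers):
        p = f"ffi{layer}.enc{m}"
        hn = layer_norm(t, params[f"{p}.ln1.g"], params[f"{p}.ln1.b"])
        q = (hn @ params[f"{p}.Wq"]).reshape(n, 4, H, dh).transpose((0, 2, 1, 3))
        kk = (hn @ params[f"{p}.Wk"]).reshape(n, 4, H, dh).transpose((0, 2, 1, 3))
        v = (hn @ params[f"{p}.Wv"]).reshape(n, 4, H, dh).transpose((0, 2, 1, 3))
        scores = (q @ kk.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1) @ v                  # (n, H, 4, dh)
        attn = attn.transpose((0, 2, 1, 3)).reshape(n, 4, d)
        t = t + dropout(attn @ params[f"{p}.Wo"], cfg.dropout, rng)
        hn = layer_norm(t, params[f"{p}.ln2.g"], params[f"{p}.ln2.b"])
        ff = linear(
            linear(hn, params[f"{p}.ffn.W1"], params[f"{p}.ffn.b1"]).relu(),
            params[f"{p}.ffn.W2"],
            params[f"{p}.ffn.b2"],
        )
        t = t + dropout(ff, cfg.dropout, rng)
    return _slot0(t, n, d)


def _slot0(t: Tensor, n: int, d: int) -> Tensor:
    """Select token slot 0: (n, 4, d) -> (n, d)."""
    # reshape to (n*4, d) and gather every 4th row
    flat = t.reshape(n * 4, d)
    return flat.gather(np.arange(0, n * 4, 4))


def _concat_tokens(toks: list[Tensor]) -> Tensor:
    """Stack (n, 1, d) tensors into (n, len(toks), d) via scatter rows."""
    n, _, d = toks[0].shape
    m = len(toks)
    total = Tensor(np.zeros((n * m, d)))
    for j, tok in enumerate(toks):
        idx = np.arange(n) * m + j
        total = total + _scatter_rows(tok.reshape(n, d), idx, n * m)
    return total.reshape(n, m, d)


def _scatter_rows(t: Tensor, idx: np.ndarray, num_rows: int) -> Tensor:
    """Place rows of t at positions idx in a (num_rows, d) zero tensor."""
    return t.segment_sum(idx, num_rows)


def forward_batch(
    batch: GraphBatch,
    params: ModelParameters,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Predicted densities for a packed batch, shape (n_mols,)."""
    cfg = params.config
    h = linear(Tensor(batch.x), params["atom_embed.W"], params["atom_embed.b"])
    energy = embed_energy(batch.pair_feats, params)
    for l in range(cfg.n_ffi_layers):
        hops = tuple(
            khop_attention(h, energy[k], batch.pairs[k], params, k, layer=l, rng=rng)
            for k in (1, 2, 3)
        )
        h = transformer_aggregate(hops, params, layer=l, rng=rng)
    pooled = h.segment_sum(batch.mol_index, batch.n_mols)
    if cfg.readout == "mean":
        counts = np.bincount(batch.mol_index, minlength=batch.n_mols).astype(float)
        pooled = pooled / Tensor(counts.reshape(-1, 1))
    hidden = linear(pooled, params["head.W1"], params["head.b1"]).relu()
    out = linear(hidden, params["head.W2"], params["head.b2"])
    return out.reshape(batch.n_mols)


def predict(graph: MolecularGraph3D, params: ModelParameters) -> Prediction:
    """Scalar density prediction for one featurized graph (deterministic)."""
    batch = make_batch([graph])
    value = forward_batch(batch, params).data[0]
    return Prediction(mol_id=graph.mol_id, rho_pred=float(value))
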
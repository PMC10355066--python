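"""Dataset splitting, training loop, regression metrics, region-stratified
evaluation, error tiers and multi-seed reporting.

Metrics are the three standard regression measures on density (g/cm^3):

    MAE  = (1/N) sum |rho_true - rho_pred|
    RMSE = sqrt((1/N) sum (rho_true - rho_pred)^2)
    R^2  = 1 - SSE / SST,   SST about the mean of the true values

Evaluation is additionally stratified by *true* density into the four regions
used when screening energetic materials — [1.8, inf) (the high-density region
of interest), [1.6, 1.8), [1.4, 1.6) and (-inf, 1.4) — and each record's
absolute error is tiered by the accepted crystal-density standard:
< 0.03 excellent, [0.03, 0.05) informative, [0.05, 0.10) barely useful,
>= 0.10 deceptive (left-closed at the boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import hop_features
from .io import MolecularGraph3D, MoleculeRecord, prepare_graphs
from .model import (
    GraphBatch,
    ModelConfig,
    ModelParameters,
    forward_batch,
    make_batch,
)
from .nn.autodiff import Tensor

REGION_BOUNDS = (1.8, 1.6, 1.4)
REGION_LABELS = (
    "region1_ge1.8",
    "region2_1.6to1.8",
    "region3_1.4to1.6",
    "region4_lt1.4",
)

TIER_BOUNDS = (0.03, 0.05, 0.10)
TIER_LABELS = ("excellent", "informative", "barely_useful", "deceptive")


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class TrainSettings:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 3e-3
    weight_decay: float = 0.0
    patience: int = 10  # early stopping on validation MAE


@dataclass
class EvalReport:
    mae: float
    rmse: float
    r2: float | None
    n: int
    regions: dict[str, dict[str, float | None]]
    tiers: list[str]
    tier_counts: dict[str, int]
    per_record: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "n": self.n,
            "regions": self.regions,
            "tier_counts": self.tier_counts,
        }


def split(
    records: Sequence, spec: SplitSpec
) -> tuple[list, list, list]:
    """Seeded random 0.8:0.1:0.1 partition (sizes round(f1 N), round(f2 N),
    remainder); disjoint and exhaustive."""
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = round(spec.fractions[0] * n)
    n_val = round(spec.fractions[1] * n)
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    pick = lambda idx: [records[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics(true: Sequence[float], pred: Sequence[float]) -> tuple[float, float, float | None]:
    """(MAE, RMSE, R^2); R^2 is None with a warning if the true values have
    zero variance."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("true and pred must be equal-length and nonempty")
    err = t - p
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("zero-variance true values: R^2 undefined")
        return mae, rmse, None
    r2 = 1.0 - float(np.sum(err**2)) / sst
    return mae, rmse, r2


def region_of(density: float) -> str:
    """Region label by true density (left-closed bins at 1.4/1.6/1.8)."""
    if density >= REGION_BOUNDS[0]:
        return REGION_LABELS[0]
    if density >= REGION_BOUNDS[1]:
        return REGION_LABELS[1]
    if density >= REGION_BOUNDS[2]:
        return REGION_LABELS[2]
    return REGION_LABELS[3]


def region_eval(
    true: Sequence[float], pred: Sequence[float]
) -> dict[str, dict[str, float | None]]:
    """Metrics per true-density region; empty regions reported as missing."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    out: dict[str, dict[str, float | None]] = {}
    labels = np.array([region_of(x) for x in t])
    for lab in REGION_LABELS:
        mask = labels == lab
        if not mask.any():
            out[lab] = {"n": 0, "mae": None, "rmse": None, "r2": None}
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mae, rmse, r2 = metrics(t[mask], p[mask])
        out[lab] = {"n": int(mask.sum()), "mae": mae, "rmse": rmse, "r2": r2}
    return out


def tier(abs_error: float) -> str:
    """Prediction-quality tier of an absolute density error (g/cm^3)."""
    if abs_error < 0:
        raise ValueError("absolute error must be nonnegative")
    if abs_error < TIER_BOUNDS[0]:
        return TIER_LABELS[0]
    if abs_error < TIER_BOUNDS[1]:
        return TIER_LABELS[1]
    if abs_error < TIER_BOUNDS[2]:
        return TIER_LABELS[2]
    return TIER_LABELS[3]


def multi_seed_report(per_seed: dict[str, list[float]]) -> dict[str, dict[str, float | None]]:
    """mean +- sample standard deviation (n-1) per metric over seeds."""
    out = {}
    for name, values in per_seed.items():
        v = np.asarray(values, dtype=float)
        sd = float(np.std(v, ddof=1)) if v.size >= 2 else None
        out[name] = {"mean": float(np.mean(v)), "sd": sd, "n_seeds": int(v.size)}
    return out


def evaluate(
    true: Sequence[float], pred: Sequence[float], ids: Sequence[str] | None = None
) -> EvalReport:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mae, rmse, r2 = metrics(true, pred)
    tiers = [tier(abs(t - p)) for t, p in zip(true, pred)]
    counts = {lab: tiers.count(lab) for lab in TIER_LABELS}
    per_record = [
        {
            "id": ids[i] if ids is not None else str(i),
            "true": float(true[i]),
            "pred": float(pred[i]),
            "region": region_of(float(true[i])),
            "tier": tiers[i],
        }
        for i in range(len(tiers))
    ]
    return EvalReport(
        mae=mae,
        rmse=rmse,
        r2=r2,
        n=len(tiers),
        regions=region_eval(true, pred),
        tiers=tiers,
        tier_counts=counts,
        per_record=per_record,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment optimizer over a ModelParameters table."""

    def __init__(self, params: ModelParameters, lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, tensor in self.params.items():
            if tensor.grad is None:
                continue
            g = tensor.grad + self.wd * tensor.data
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            tensor.data -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


def _predictions(graphs: list[MolecularGraph3D], featsets, params) -> np.ndarray:
    batch = make_batch(graphs, featsets)
    return forward_batch(batch, params).data


def train(
    train_graphs: list[MolecularGraph3D],
    val_graphs: list[MolecularGraph3D],
    config: ModelConfig,
    seed: int = 0,
    settings: TrainSettings = TrainSettings(),
) -> tuple[ModelParameters, list[dict]]:
    """Minimize MSE on density; keep the weights with best validation MAE.

    Fully seeded: parameter init, minibatch shuffling and dropout masks all
    derive from ``seed``.  A non-finite loss aborts with a diagnostic.
    """
    rng = np.random.default_rng(seed)
    params = ModelParameters(config, seed=seed)
    opt = Adam(params, settings.learning_rate, settings.weight_decay)
    train_feats = [hop_features(g) for g in train_graphs]
    val_feats = [hop_features(g) for g in val_graphs]
    y_train = np.array([g.target for g in train_graphs], dtype=float)
    history: list[dict] = []
    best_state = params.copy_state()
    best_val = np.inf
    since_best = 0
    n = len(train_graphs)
    for epoch in range(settings.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            batch = make_batch(
                [train_graphs[i] for i in idx], [train_feats[i] for i in idx]
            )
            drop_rng = np.random.default_rng(rng.integers(2**31))
            pred = forward_batch(batch, params, rng=drop_rng)
            resid = pred - Tensor(y_train[idx])
            loss = (resid * resid).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: "
                    f"{loss.data!r}; lower the learning rate or inspect inputs"
                )
            params.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        val_pred = _predictions(val_graphs, val_feats, params)
        val_true = np.array([g.target for g in val_graphs], dtype=float)
        val_mae = float(np.mean(np.abs(val_true - val_pred)))
        history.append(
            {"epoch": epoch, "train_mse": epoch_loss / n, "val_mae": val_mae}
        )
        if val_mae < best_val:
            best_val = val_mae
            best_state = params.copy_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= settings.patience:
                break
    params.load_state(best_state)
    return params, history


def predict_graphs(
    graphs: list[MolecularGraph3D], params: ModelParameters
) -> np.ndarray:
    return _predictions(graphs, None, params)


def mean_baseline_mae(train_true: Sequence[float], test_true: Sequence[float]) -> float:
    """MAE of predicting the training-set mean for every test record."""
    mu = float(np.mean(np.asarray(train_true, dtype=float)))
    return float(np.mean(np.abs(np.asarray(test_true, dtype=float) - mu)))


def run_experiment(
    records: Sequence[MoleculeRecord],
    config: ModelConfig,
    split_spec: SplitSpec,
    settings: TrainSettings = TrainSettings(),
    seed: int = 0,
    conformer_seed: int = 0,
) -> dict:
    """Split -> featurize -> train -> evaluate on the held-out test set."""
    rec_train, rec_val, rec_test = split(list(records), split_spec)
    g_train = prepare_graphs(rec_train, conformer_seed)
    g_val = prepare_graphs(rec_val, conformer_seed)
    g_test = prepare_graphs(rec_test, conformer_seed)
    params, history = train(g_train, g_val, config, seed=seed, settings=settings)
    pred = predict_graphs(g_test, params)
    true = np.array([g.target for g in g_test], dtype=float)
    report = evaluate(true, pred, ids=[g.mol_id for g in g_test])
    baseline = mean_baseline_mae([g.target for g in g_train], true)
    return {
        "params": params,
        "history": history,
        "report": report,
        "baseline_mae": baseline,
        "split_sizes": (len(rec_train), len(rec_val), len(rec_test)),
        "true": true,
        "pred": pred,
    }
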
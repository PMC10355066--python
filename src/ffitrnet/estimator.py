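"""scikit-learn estimator interface to the force-field-inspired transformer.

``FFiTrNetRegressor`` takes SMILES strings as samples and crystal densities
(g/cm^3) as targets, so it composes with sklearn model selection and
pipelines operating on object arrays of SMILES.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .io import MoleculeRecord, prepare_graphs
from .model import ModelConfig
from .train import TrainSettings, train as _train, predict_graphs


class FFiTrNetRegressor(BaseEstimator, RegressorMixin):
    """Crystal-density regression from SMILES via k-hop energy attention.

    Parameters mirror the model configuration and training settings; all
    randomness (weight init, minibatch order, dropout, validation split)
    derives from ``random_state``.

    Attributes
    ----------
    params_ : ModelParameters
        Learned weight table after :meth:`fit`.
    config_ : ModelConfig
        The architecture actually built.
    history_ : list of dict
        Per-epoch training MSE and validation MAE.

    Examples
    --------
    >>> from ffitrnet.synthetic import SyntheticSpec, generate
    >>> recs = generate(SyntheticSpec(n=60, seed=0))
    >>> reg = FFiTrNetRegressor(d_model=16, n_ffi_layers=1, epochs=3)
    >>> reg.fit([r.smiles for r in recs], [r.target for r in recs])
    FFiTrNetRegressor(d_model=16, epochs=3, n_ffi_layers=1)
    """

    def __init__(
        self,
        d_model: int = 32,
        n_heads: int = 4,
        n_ffi_layers: int = 1,
        n_encoder_layers: int = 1,
        use_positional_encoding: bool = False,
        dropout: float = 0.0,
        readout: str = "mean",
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 3e-3,
        patience: int = 10,
        val_fraction: float = 0.1,
        conformer_seed: int = 0,
        random_state: int = 0,
    ):
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_ffi_layers = n_ffi_layers
        self.n_encoder_layers = n_encoder_layers
        self.use_positional_encoding = use_positional_encoding
        self.dropout = dropout
        self.readout = readout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.val_fraction = val_fraction
        self.conformer_seed = conformer_seed
        self.random_state = random_state

    def _records(self, X) -> list[MoleculeRecord]:
        return [
            MoleculeRecord(id=f"x{i}", smiles=str(s)) for i, s in enumerate(np.ravel(X))
        ]

    def fit(self, X, y):
        """Fit on SMILES ``X`` and densities ``y`` (g/cm^3).

        An internal seeded split holds out ``val_fraction`` of the data for
        early stopping / best-weight selection.
        """
        y = np.asarray(y, dtype=float).ravel()
        records = self._records(X)
        if len(records) != y.size:
            raise ValueError("X and y length mismatch")
        graphs = prepare_graphs(records, self.conformer_seed)
        for g, target in zip(graphs, y):
            g.target = float(target)
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(graphs))
        n_val = max(1, int(round(self.val_fraction * len(graphs))))
        val = [graphs[i] for i in order[:n_val]]
        trn = [graphs[i] for i in order[n_val:]]
        self.config_ = ModelConfig(
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_ffi_layers=self.n_ffi_layers,
            n_encoder_layers=self.n_encoder_layers,
            use_positional_encoding=self.use_positional_encoding,
            dropout=self.dropout,
            readout=self.readout,
        )
        settings = TrainSettings(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            patience=self.patience,
        )
        self.params_, self.history_ = _train(
            trn, val, self.config_, seed=self.random_state, settings=settings
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Predicted densities (g/cm^3) for SMILES ``X``."""
        check_is_fitted(self, "params_")
        graphs = prepare_graphs(self._records(X), self.conformer_seed)
        return predict_graphs(graphs, self.params_)
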
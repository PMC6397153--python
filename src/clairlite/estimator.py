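"""A scikit-learn style estimator wrapping the network and training loop.

``PileupTensorClassifier`` exposes fit/predict/predict_proba on batches of
site tensors (arrays of shape ``(n, 33, 4, 4)``) against the 16-column
label matrix (allele 4 | zygosity 2 | type 4 | indel length 6).  It
composes with sklearn model selection utilities via ``get_params`` /
``set_params``; the spec-level functions in :mod:`clairlite.training` and
:mod:`clairlite.network` remain the underlying implementation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import network as nw
from . import training as tr
from .network import ConvSpec, DEFAULT_CONVS, NetworkConfig
from .tensors import LABEL_WIDTH


class PileupTensorClassifier(BaseEstimator):
    """Multi-task CNN variant classifier.

    Parameters
    ----------
    mode : "fast" or "nonstop"
        Adaptive-decay training versus a fixed learning-rate schedule.
    learning_rate, decay_factor, plateau_rounds, max_decays, batch_size,
    max_epochs : fast-mode policy knobs; the L2 lambda always tracks the
        current learning rate.
    schedule : nonstop-mode (epoch bound, learning rate) pairs.
    validation_fraction : held-out fraction used for plateau detection.
    fc4, fc5, convs, dropout_fc4 : architecture hyper-parameters.
    random_state : master seed for initialisation, the split, shuffling
        and dropout.
    """

    def __init__(self, mode: str = "fast", learning_rate: float = 1e-3,
                 decay_factor: float = 0.1, plateau_rounds: int = 5,
                 min_rel_improvement: float = 0.01,
                 max_decays: int = 2, batch_size: int = 500,
                 max_epochs: int = 200,
                 schedule: tuple = tr.DEFAULT_NONSTOP_SCHEDULE,
                 validation_fraction: float = 0.1,
                 fc4: int = 336, fc5: int = 168,
                 convs: tuple[ConvSpec, ...] = DEFAULT_CONVS,
                 dropout_fc4: float = 0.5, random_state: int = 0):
        self.mode = mode
        self.learning_rate = learning_rate
        self.decay_factor = decay_factor
        self.plateau_rounds = plateau_rounds
        self.min_rel_improvement = min_rel_improvement
        self.max_decays = max_decays
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.schedule = schedule
        self.validation_fraction = validation_fraction
        self.fc4 = fc4
        self.fc5 = fc5
        self.convs = convs
        self.dropout_fc4 = dropout_fc4
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_xy(self, X, Y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError("X must have shape (n, positions, 4, 4)")
        if Y is not None:
            Y = np.asarray(Y, dtype=np.float64)
            if Y.shape != (len(X), LABEL_WIDTH):
                raise ValueError(
                    f"Y must have shape (n, {LABEL_WIDTH})")
        return X, Y

    def fit(self, X, Y):
        """Train on encoded site tensors ``X`` and label matrix ``Y``."""
        X, Y = self._validate_xy(X, Y)
        cfg = NetworkConfig(input_shape=X.shape[1:], convs=tuple(self.convs),
                            fc4=self.fc4, fc5=self.fc5,
                            dropout_fc4=self.dropout_fc4)
        model = nw.init_he(nw.build(cfg), seed=self.random_state)
        tr_idx, va_idx = tr.split_indices(
            len(X), 1.0 - self.validation_fraction, seed=self.random_state)
        train_data = (X[tr_idx], Y[tr_idx])
        val_data = (X[va_idx], Y[va_idx])
        if self.mode == "fast":
            policy = tr.TrainPolicy(
                initial_learning_rate=self.learning_rate,
                decay_factor=self.decay_factor,
                plateau_rounds=self.plateau_rounds,
                min_rel_improvement=self.min_rel_improvement,
                max_decays=self.max_decays, batch_size=self.batch_size,
                max_epochs=self.max_epochs)
            model, history = tr.train_fast(model, train_data, val_data,
                                           policy, seed=self.random_state)
            self.checkpoints_ = []
        elif self.mode == "nonstop":
            model, history, ckpts = tr.train_nonstop(
                model, train_data, val_data, schedule=tuple(self.schedule),
                seed=self.random_state, batch_size=self.batch_size)
            self.checkpoints_ = ckpts
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.model_ = model
        self.history_ = history
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Concatenated head probabilities, shape (n, 16)."""
        out = self.predict_outputs(X)
        return np.concatenate([out.a, out.z, out.t, out.l], axis=1)

    def predict_outputs(self, X) -> nw.NetworkOutputs:
        self._check_fitted()
        X, _ = self._validate_xy(X)
        return nw.forward(self.model_, X)

    def predict(self, X) -> np.ndarray:
        """Argmax of the variant-type head (the primary task)."""
        return np.argmax(self.predict_outputs(X).t, axis=1)

    def score(self, X, Y) -> float:
        """Negative multi-task cost (higher is better, sklearn-style)."""
        X, Y = self._validate_xy(X, Y)
        return -nw.cost(nw.forward(self.model_, X), Y)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
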
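"""Seven-layer 1-D CNN hypotension predictor on 20 s ABP segments.

Architecture: seven conv blocks (kernel 10, conv -> batch norm -> ReLU ->
stride-2 max pool -> dropout 0.01), global average pooling, a 64-unit ReLU
dense layer and a sigmoid output. Inputs are scaled by the fixed affine map
(x - 80)/40 rather than per-segment normalization, deliberately preserving
the absolute MAP level — the dominant predictive feature in ABP.

Training: weighted binary cross-entropy with balanced class weights
(w_c = n_total / (2 n_c)), Adam at learning rate 0.001, batch size 20, at
most 150 epochs, early stopping on validation ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import _nn
from .._validation import check_both_classes

INPUT_SCALE_CENTER = 80.0
INPUT_SCALE_WIDTH = 40.0


@dataclass
class CnnSpec:
    """Architecture parameters; the defaults are the reference model."""

    n_conv_layers: int = 7
    kernel_size: int = 10
    channels: tuple = (32, 32, 64, 64, 128, 128, 128)
    dropout_rate: float = 0.01
    dense_units: int = 64
    input_length: int = 2500

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_conv_layers:
            raise ValueError("channels must list one width per conv layer")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 20
    max_epochs: int = 150
    patience: int = 10           # epochs without validation-AUC improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def balanced_class_weights(labels: np.ndarray) -> dict:
    """w_c = n_total / (2 n_c); a constant model then incurs equal total
    loss from each class."""
    labels = np.asarray(labels)
    n = len(labels)
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for balanced weights")
    return {1: n / (2.0 * n_pos), 0: n / (2.0 * n_neg)}


def _build_network(spec: CnnSpec, rng: np.random.Generator) -> _nn.Sequential:
    layers = []
    c_prev = 1
    for c in spec.channels:
        layers += [_nn.Conv1d(c_prev, c, spec.kernel_size, rng),
                   _nn.BatchNorm1d(c), _nn.ReLU(), _nn.MaxPool2(),
                   _nn.Dropout(spec.dropout_rate, rng)]
        c_prev = c
    layers += [_nn.GlobalAvgPool(),
               _nn.Dense(c_prev, spec.dense_units, rng), _nn.ReLU(),
               _nn.Dense(spec.dense_units, 1, rng)]
    return _nn.Sequential(layers)


def _prepare(segments: np.ndarray, input_length: int) -> np.ndarray:
    x = np.asarray(segments, dtype=_nn.DTYPE)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != input_length:
        raise ValueError(f"segments must have length {input_length}, "
                         f"got {x.shape[1]}")
    return ((x - INPUT_SCALE_CENTER) / INPUT_SCALE_WIDTH)[:, None, :]


@dataclass
class TrainedCnn:
    """Weights of the best-validation-AUC epoch plus the training log."""

    spec: CnnSpec
    state: dict
    history: list = field(default_factory=list)   # per-epoch dicts
    best_epoch: int = -1
    best_val_auc: float = np.nan

    def predict_proba(self, segments, batch_size: int = 256) -> np.ndarray:
        """Event probabilities in (0, 1); order-preserving and independent
        of batching (inference uses running batch-norm statistics)."""
        net = _build_network(self.spec, np.random.default_rng(0))
        net.load_state_dict(self.state)
        x = _prepare(segments, self.spec.input_length)
        out = []
        for i in range(0, len(x), batch_size):
            z = net.forward(x[i:i + batch_size], train=False)[:, 0]
            out.append(1.0 / (1.0 + np.exp(-z.astype(np.float64))))
        return np.concatenate(out)


def train_cnn(train_segments, train_labels, val_segments, val_labels,
              spec: CnnSpec | None = None,
              config: TrainConfig | None = None,
              log_fn=None) -> TrainedCnn:
    """Train the CNN with early stopping on validation ROC-AUC.

    Both splits must contain both classes (checked before training); the
    returned model carries the weights of the epoch with the best validation
    AUC. Deterministic for a fixed seed under single-threaded execution.
    """
    spec = spec or CnnSpec()
    config = config or TrainConfig()
    y_tr = np.asarray(train_labels, dtype=_nn.DTYPE)
    y_va = np.asarray(val_labels, dtype=np.int64)
    check_both_classes(y_tr, "training split")
    check_both_classes(y_va, "validation split")

    rng = np.random.default_rng(config.seed)
    net = _build_network(spec, rng)
    opt = _nn.Adam(net.layers, lr=config.learning_rate)
    x_tr = _prepare(train_segments, spec.input_length)
    x_va = _prepare(val_segments, spec.input_length)
    cw = balanced_class_weights(train_labels)
    w_tr = np.where(y_tr > 0.5, cw[1], cw[0]).astype(np.float64)

    history = []
    best_auc, best_state, best_epoch = -np.inf, None, -1
    stall = 0
    n = len(x_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            z = net.forward(x_tr[idx], train=True)[:, 0]
            loss, dz = _nn.weighted_bce_with_logits(z, y_tr[idx].astype(np.float64),
                                                    w_tr[idx])
            net.backward(dz[:, None])
            opt.step()
            epoch_loss += loss * len(idx)
        # validation AUC in inference mode
        scores = []
        for i in range(0, len(x_va), 256):
            scores.append(net.forward(x_va[i:i + 256], train=False)[:, 0])
        val_auc = float(roc_auc_score(y_va, np.concatenate(scores)))
        entry = {"epoch": epoch, "train_loss": epoch_loss / n, "val_auc": val_auc}
        history.append(entry)
        if log_fn:
            log_fn(entry)
        if val_auc > best_auc + 1e-12:
            best_auc, best_state, best_epoch = val_auc, net.state_dict(), epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return TrainedCnn(spec=spec, state=best_state, history=history,
                      best_epoch=best_epoch, best_val_auc=best_auc)
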
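"""Hybrid CNN-LSTM decoder for windowed EEG/sEMG fusion inputs.

The architecture is four convolution -> ELU -> average-pooling blocks
along the time axis, a fold into a (time, channels) sequence, two
LSTM + dropout blocks, and a dense softmax head over the movement
classes.  :class:`MovementDecoder` wraps it statsmodels-style: build
the model from data, call :meth:`MovementDecoder.fit` for a single
train/test fit or :meth:`MovementDecoder.fit_kfold` for stratified,
group-aware k-fold cross-validation, and read the estimates off the
returned results object.

:func:`lstm_step` is a standalone reference implementation of the LSTM
gate equations; the training backend's cell (:mod:`lagfuse.nn`) is
tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import nn
from .exceptions import ConfigurationError, ShapeError, StratificationError

__all__ = ["LstmWeights", "lstm_step", "ModelSpec", "build_model",
           "MovementDecoder", "DecoderResults", "CrossValidationResults",
           "train_kfold"]


# ---------------------------------------------------------------------------
# LSTM gate-equation reference


@dataclass
class LstmWeights:
    """Unpacked LSTM weights: per-gate input maps W, recurrent maps U,
    and offsets b, for gates i (input), f (forget), o (output) and the
    candidate c."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self):
        H, D = self.W_i.shape
        for name in ("W_f", "W_o", "W_c"):
            if getattr(self, name).shape != (H, D):
                raise ShapeError(f"{name} must be {H}x{D}")
        for name in ("U_i", "U_f", "U_o", "U_c"):
            if getattr(self, name).shape != (H, H):
                raise ShapeError(f"{name} must be {H}x{H}")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            if getattr(self, name).shape != (H,):
                raise ShapeError(f"{name} must have length {H}")

    @classmethod
    def from_packed(cls, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray,
                    hidden: int) -> "LstmWeights":
        """Unpack the backend's (D, 4H)/(H, 4H)/(4H,) layout (gate order
        i, f, o, candidate)."""
        H = hidden
        blocks = [slice(0, H), slice(H, 2 * H), slice(2 * H, 3 * H),
                  slice(3 * H, 4 * H)]
        Wi, Wf, Wo, Wc = (Wx[:, s].T for s in blocks)
        Ui, Uf, Uo, Uc = (Wh[:, s].T for s in blocks)
        bi, bf, bo, bc = (b[s] for s in blocks)
        return cls(Wi, Wf, Wo, Wc, Ui, Uf, Uo, Uc, bi, bf, bo, bc)


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              w: LstmWeights):
    """One LSTM update: gates via the logistic function, candidate via
    tanh, ``c_t = f * c_prev + i * c~``, ``h_t = o * tanh(c_t)``."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    H, D = w.W_i.shape
    if x_t.shape != (D,) or h_prev.shape != (H,) or c_prev.shape != (H,):
        raise ShapeError("state/input shapes inconsistent with the weights")
    i = nn.sigmoid(w.W_i @ x_t + w.U_i @ h_prev + w.b_i)
    f = nn.sigmoid(w.W_f @ x_t + w.U_f @ h_prev + w.b_f)
    o = nn.sigmoid(w.W_o @ x_t + w.U_o @ h_prev + w.b_o)
    c_tilde = np.tanh(w.W_c @ x_t + w.U_c @ h_prev + w.b_c)
    c_t = f * c_prev + i * c_tilde
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# architecture


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters.

    The block structure is fixed (four conv/pool blocks with ELU, two
    LSTM/dropout blocks, dense softmax head); kernel widths, channel
    counts, pooling widths, hidden sizes, dropout, learning rate and
    the epoch budget are free hyperparameters sized for CPU training.
    """

    conv_blocks: tuple = ((5, 16, 2), (5, 32, 2), (5, 32, 2), (5, 64, 2))
    lstm_blocks: tuple = ((64, 0.5), (64, 0.5))
    n_classes: int = 8
    lr: float = 3e-3
    batch_size: int = 64
    epochs: int = 16

    def __post_init__(self):
        if len(self.conv_blocks) != 4:
            raise ConfigurationError("exactly 4 conv blocks are required")
        if len(self.lstm_blocks) != 2:
            raise ConfigurationError("exactly 2 LSTM blocks are required")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")

    def pooled_length(self, L: int) -> int:
        for _, _, pool in self.conv_blocks:
            L = L // pool
        return L


def build_model(spec: ModelSpec, input_shape, rng) -> nn.Sequential:
    """Assemble the network for a (channels, L) input window."""
    C, L = input_shape
    if spec.pooled_length(L) < 1:
        raise ConfigurationError(
            f"input length {L} collapses to zero after the pooling chain")
    layers = []
    c_in = C
    for k, c_out, pool in spec.conv_blocks:
        layers += [nn.Conv1d(c_in, c_out, k, rng), nn.ELU(),
                   nn.AvgPool1d(pool)]
        c_in = c_out
    layers.append(nn.Fold())
    d_in = c_in
    for hidden, dropout in spec.lstm_blocks:
        layers += [nn.LSTMLayer(d_in, hidden, rng), nn.Dropout(dropout, rng)]
        d_in = hidden
    layers += [nn.LastStep(), nn.Dense(d_in, spec.n_classes, rng)]
    return nn.Sequential(layers)


# ---------------------------------------------------------------------------
# results


@dataclass
class DecoderResults:
    """A fitted decoder: trained weights plus training diagnostics."""

    spec: ModelSpec
    network: nn.Sequential = field(repr=False)
    classes: np.ndarray
    loss_history: list
    input_shape: tuple
    _standardizer: tuple = field(repr=False, default=None)

    def _prep(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :]
        if self._standardizer is not None:
            mu, sd = self._standardizer
            X = (X - mu) / sd
        return X

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        X = self._prep(X)
        out = []
        for i in range(0, X.shape[0], batch_size):
            logits = self.network.forward(X[i:i + batch_size], train=False)
            out.append(nn.softmax(logits))
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def summary(self) -> str:
        n_par = sum(v.size for v in self.network.state_arrays())
        return (f"CNN-LSTM decoder: input {self.input_shape}, "
                f"{len(self.classes)} classes, {n_par} parameters\n"
                f"  final training loss {self.loss_history[-1]:.4f} "
                f"after {len(self.loss_history)} epoch(s)")


@dataclass
class CrossValidationResults:
    """Stratified k-fold evaluation of the decoder."""

    fold_accuracies: np.ndarray
    confusion: np.ndarray
    classes: np.ndarray
    spec: ModelSpec

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    def summary(self) -> str:
        folds = ", ".join(f"{a:.3f}" for a in self.fold_accuracies)
        return (f"{len(self.fold_accuracies)}-fold CV accuracy "
                f"{self.mean_accuracy:.3f} +/- {self.std_accuracy:.3f} "
                f"[{folds}]\nconfusion matrix (rows = true):\n"
                f"{self.confusion}")

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "confusion": self.confusion.tolist(),
            "classes": self.classes.tolist(),
        }


#: alias matching the domain vocabulary
EvalReport = CrossValidationResults


# ---------------------------------------------------------------------------
# model object


class MovementDecoder:
    """CNN-LSTM movement-intention decoder built from a windowed dataset.

    Parameters
    ----------
    X : ndarray
        (n, channels, L) fusion windows or (n, n_features) feature
        vectors (the latter are treated as single-channel sequences).
    y : ndarray
        Class label per window.
    groups : ndarray, optional
        Source-epoch id per window; when given, cross-validation keeps
        all windows of an epoch in the same fold (no leakage between
        overlapping windows of one trial).
    spec : ModelSpec, optional
    """

    def __init__(self, X, y, groups=None, spec: ModelSpec = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            self._feature_input = True
            X = X[:, None, :]
        elif X.ndim == 3:
            self._feature_input = False
        else:
            raise ShapeError("X must be 2-D (features) or 3-D (windows)")
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ShapeError("one label per sample required")
        self.X, self.y = X, y
        self.groups = None if groups is None else np.asarray(groups)
        self.classes = np.unique(y)
        if spec is None:
            spec = ModelSpec(n_classes=len(self.classes))
        elif spec.n_classes != len(self.classes):
            raise ConfigurationError("spec.n_classes disagrees with the labels")
        self.spec = spec

    @classmethod
    def from_dataset(cls, dataset, spec: ModelSpec = None) -> "MovementDecoder":
        """Build from a :class:`lagfuse.fusion.FusionDataset`."""
        return cls(dataset.X, dataset.y, groups=dataset.groups, spec=spec)

    # -- fitting ------------------------------------------------------------

    def _fit_arrays(self, X, y, seed, epochs):
        spec = self.spec
        rng = np.random.default_rng(seed)
        classes = self.classes
        y_idx = np.searchsorted(classes, y)
        # standardize inputs on training statistics: per feature for
        # feature vectors, per channel (over samples and time) for windows
        ax = (0,) if self._feature_input else (0, 2)
        mu = X.mean(axis=ax, keepdims=True)
        sd = X.std(axis=ax, keepdims=True)
        sd[sd == 0] = 1.0
        standardizer = (mu, sd)
        X = (X - mu) / sd
        net = build_model(spec, X.shape[1:], rng)
        opt = nn.Adam(net.params, lr=spec.lr)
        n = X.shape[0]
        losses = []
        n_epochs = spec.epochs if epochs is None else epochs
        for _ in range(n_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for i in range(0, n, spec.batch_size):
                idx = order[i:i + spec.batch_size]
                net.zero_grad()
                logits = net.forward(X[idx], train=True)
                loss, dlogits = nn.cross_entropy_grad(logits, y_idx[idx])
                net.backward(dlogits)
                opt.step()
                epoch_loss += loss * len(idx)
            losses.append(epoch_loss / n)
        return DecoderResults(spec, net, classes, losses, X.shape[1:],
                              _standardizer=standardizer)

    def fit(self, seed: int = 0, epochs: int = None) -> DecoderResults:
        """Train on all data; reproducible from ``seed``."""
        return self._fit_arrays(self.X, self.y, seed, epochs)

    def _splits(self, k, seed):
        if self.groups is not None:
            cv = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                      random_state=seed)
            return cv.split(self.X, self.y, self.groups)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return cv.split(self.X, self.y)

    def fit_kfold(self, k: int = 5, seed: int = 0,
                  epochs: int = None) -> CrossValidationResults:
        """Stratified (group-aware) k-fold cross-validation.

        Raises :class:`StratificationError` when any class is missing
        from a training or test fold.
        """
        if len(self.y) < k * len(self.classes):
            raise StratificationError(
                "dataset too small to stratify into the requested folds")
        n_cls = len(self.classes)
        confusion = np.zeros((n_cls, n_cls), dtype=int)
        accs = []
        for fold, (tr, te) in enumerate(self._splits(k, seed)):
            for part, name in ((tr, "training"), (te, "test")):
                if len(np.unique(self.y[part])) < n_cls:
                    raise StratificationError(
                        f"class missing from {name} fold {fold}")
            res = self._fit_arrays(self.X[tr], self.y[tr],
                                   seed + 1000 * (fold + 1), epochs)
            pred = res.predict(self.X[te])
            accs.append(float(np.mean(pred == self.y[te])))
            t_idx = np.searchsorted(self.classes, self.y[te])
            p_idx = np.searchsorted(self.classes, pred)
            np.add.at(confusion, (t_idx, p_idx), 1)
        return CrossValidationResults(np.asarray(accs), confusion,
                                      self.classes, self.spec)


def train_kfold(dataset, spec: ModelSpec = None, k: int = 5,
                seed: int = 0, epochs: int = None) -> CrossValidationResults:
    """Convenience wrapper: k-fold CV on a :class:`FusionDataset`."""
    return MovementDecoder.from_dataset(dataset, spec).fit_kfold(
        k=k, seed=seed, epochs=epochs)
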
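"""Time-series 1-D CNN wrist-angle classifier.

Classifies each stitched 200 ms Hall window into one of three wrist
angles (-90, 0, +90 degrees).  The stitched 1-D vector is reconstructed
to a (3 channels x W samples) array so convolution runs along time with
three input channels, preserving per-sensor temporal structure.

Architecture (all configurable): two 1-D convolution layers (8 then 16
filters, kernel 5, valid padding) each followed by ReLU and max-pooling
of size 2, then a dense softmax layer over the three classes, trained
with cross-entropy loss and seeded mini-batch SGD with momentum.  The
network is implemented directly in numpy (im2col convolutions with exact
backpropagation) and is bit-reproducible for a fixed seed on one thread.

Robustness to sensor disturbance (sample spikes, loss of 100 consecutive
samples in a window) is encouraged by light corruption augmentation of
the training batches.
"""

from __future__ import annotations

import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .synth import corrupt_values

__all__ = [
    "AngleCNNClassifier", "train_classifier", "predict_angle",
    "evaluate_classifier",
]

DEFAULT_CLASSES = (-90, 0, 90)


def _conv_forward(x, W, b):
    """Valid 1-D cross-correlation. x: (N,C,L), W: (F,C,K) -> (N,F,L-K+1)."""
    N, C, L = x.shape
    F, _, K = W.shape
    cols = sliding_window_view(x, K, axis=2)          # (N, C, Lo, K)
    cols = cols.transpose(0, 2, 1, 3).reshape(N, L - K + 1, C * K)
    out = cols @ W.reshape(F, C * K).T + b            # (N, Lo, F)
    return out.transpose(0, 2, 1), cols


def _conv_backward(dout, cols, W, x_shape):
    """Gradients of the valid 1-D convolution."""
    N, C, L = x_shape
    F, _, K = W.shape
    Lo = dout.shape[2]
    dflat = dout.transpose(0, 2, 1).reshape(N * Lo, F)       # (N*Lo, F)
    dW = (dflat.T @ cols.reshape(N * Lo, C * K)).reshape(F, C, K)
    db = dflat.sum(axis=0)
    dcols = (dflat @ W.reshape(F, C * K)).reshape(N, Lo, C, K)
    dcols = dcols.transpose(0, 2, 1, 3)                      # (N, C, Lo, K)
    dx = np.zeros(x_shape)
    for k in range(K):
        dx[:, :, k:k + Lo] += dcols[:, :, :, k]
    return dx, dW, db


def _pool_forward(x, p):
    """Non-overlapping max pool of size p along time; trims the remainder."""
    N, F, L = x.shape
    Lp = (L // p) * p
    blocks = x[:, :, :Lp].reshape(N, F, Lp // p, p)
    arg = blocks.argmax(axis=3)
    out = np.take_along_axis(blocks, arg[..., None], axis=3)[..., 0]
    return out, (arg, L, p)


def _pool_backward(dout, cache):
    arg, L, p = cache
    N, F, Lo = dout.shape
    dblocks = np.zeros((N, F, Lo, p))
    np.put_along_axis(dblocks, arg[..., None], dout[..., None], axis=3)
    dx = np.zeros((N, F, L))
    dx[:, :, :Lo * p] = dblocks.reshape(N, F, Lo * p)
    return dx


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class AngleCNNClassifier(ClassifierMixin, BaseEstimator):
    """1-D CNN over stitched Hall windows, three wrist-angle classes.

    Parameters
    ----------
    n_channels : number of Hall sensors stitched into each window (3).
    conv_filters : filters per convolution layer.
    kernel_size : odd convolution kernel length, shared across layers.
    pool_size : max-pooling factor after each convolution.
    epochs, batch_size, learning_rate, momentum : SGD schedule.
    augment_corruption : probability of corrupting a training window
        (dropout of 100 samples or full-scale spikes) each epoch; 0 disables.
    random_state : seed for initialization, shuffling and augmentation.

    Attributes
    ----------
    classes_ : class labels in fixed order.
    weights_ : list of layer weight arrays.
    history_ : per-epoch training loss and accuracy.
    """

    def __init__(self, n_channels: int = 3, conv_filters=(8, 16),
                 kernel_size: int = 5, pool_size: int = 2, epochs: int = 30,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 momentum: float = 0.9, augment_corruption: float = 0.25,
                 random_state: int = 0, classes=DEFAULT_CLASSES):
        self.n_channels = n_channels
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.augment_corruption = augment_corruption
        self.random_state = random_state
        self.classes = classes

    # ---- internals ----------------------------------------------------

    def _validate(self):
        if len(self.classes) != 3:
            raise ValueError("exactly 3 angle classes required")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def _reshape(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] % self.n_channels != 0:
            raise ValueError("window length not divisible by channel count")
        n, width = X.shape
        if hasattr(self, "width_") and width != self.width_:
            raise ValueError(
                f"window length {width} != training length {self.width_}")
        return X.reshape(n, self.n_channels, width // self.n_channels)

    def _forward(self, Xr, train=False):
        caches = []
        a = Xr
        for (W, b) in self.conv_params_:
            z, cols = _conv_forward(a, W, b)
            relu = z > 0
            a = z * relu
            a, pcache = _pool_forward(a, self.pool_size)
            caches.append((cols, relu, pcache, a.shape))
        flat = a.reshape(a.shape[0], -1)
        logits = flat @ self.Wd_ + self.bd_
        if train:
            return logits, flat, caches
        return logits

    def _init_weights(self, rng, width):
        L = width
        C = self.n_channels
        self.conv_params_ = []
        for F in self.conv_filters:
            K = self.kernel_size
            W = rng.normal(0.0, np.sqrt(2.0 / (C * K)), size=(F, C, K))
            b = np.zeros(F)
            self.conv_params_.append([W, b])
            L = (L - K + 1) // self.pool_size
            C = F
        self.flat_dim_ = C * L
        self.Wd_ = rng.normal(0.0, np.sqrt(2.0 / self.flat_dim_),
                              size=(self.flat_dim_, 3))
        self.bd_ = np.zeros(3)

    def _augment(self, Xb, rng):
        Xb = Xb.copy()
        for i in range(len(Xb)):
            if rng.random() < self.augment_corruption:
                mode = "dropout" if rng.random() < 0.5 else "spikes"
                if mode == "dropout" and Xb.shape[1] < 100:
                    mode = "spikes"
                Xb[i] = corrupt_values(Xb[i], mode,
                                       rng_seed=int(rng.integers(2 ** 31)))
        return Xb

    # ---- sklearn API ---------------------------------------------------

    def fit(self, X, y):
        self._validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty (n_windows, width) array")
        if len(y) != len(X):
            raise ValueError("y length must match X")
        self.classes_ = np.asarray(self.classes)
        unknown = set(np.unique(y)) - set(self.classes_.tolist())
        if unknown:
            raise ValueError(f"labels {unknown} outside classes {self.classes}")
        self.width_ = X.shape[1]
        class_to_idx = {int(c): i for i, c in enumerate(self.classes_.tolist())}
        yi = np.array([class_to_idx[int(v)] for v in y])

        rng = np.random.default_rng(self.random_state)
        self._init_weights(rng, self.width_ // self.n_channels)
        vel = [np.zeros_like(p) for layer in self.conv_params_ for p in layer]
        vel += [np.zeros_like(self.Wd_), np.zeros_like(self.bd_)]

        n = len(X)
        self.history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                Xb, yb = X[idx], yi[idx]
                if self.augment_corruption > 0:
                    Xb = self._augment(Xb, rng)
                Xr = self._reshape(Xb)
                logits, flat, caches = self._forward(Xr, train=True)
                prob = _softmax(logits)
                m = len(idx)
                losses.append(-np.log(prob[np.arange(m), yb] + 1e-12).mean())
                correct += int((logits.argmax(axis=1) == yb).sum())

                dlogits = prob
                dlogits[np.arange(m), yb] -= 1.0
                dlogits /= m
                grads = [flat.T @ dlogits, dlogits.sum(axis=0)]
                da = (dlogits @ self.Wd_.T).reshape(caches[-1][3])
                for li in range(len(self.conv_params_) - 1, -1, -1):
                    cols, relu, pcache, _ = caches[li]
                    dz = _pool_backward(da, pcache) * relu
                    xin_shape = (m, self.n_channels,
                                 self.width_ // self.n_channels) if li == 0 \
                        else caches[li - 1][3]
                    da, dW, db = _conv_backward(dz, cols,
                                                self.conv_params_[li][0],
                                                xin_shape)
                    grads = [dW, db] + grads
                # momentum SGD over [conv W/b ..., dense W, dense b]
                params = [p for layer in self.conv_params_ for p in layer]
                params += [self.Wd_, self.bd_]
                for v, p, g in zip(vel, params, grads):
                    v *= self.momentum
                    v -= self.learning_rate * g
                    p += v
            self.history_.append(
                {"loss": float(np.mean(losses)), "accuracy": correct / n})
        self.weights_ = [p for layer in self.conv_params_ for p in layer]
        self.weights_ += [self.Wd_, self.bd_]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        logits = self._forward(self._reshape(np.atleast_2d(X)))
        return _softmax(logits)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # ---- persistence ---------------------------------------------------

    def save(self, path) -> None:
        """Single-file serialization: config JSON + weight arrays (.npz)."""
        check_is_fitted(self, "weights_")
        cfg = json.dumps(self.get_params())
        arrays = {f"w{i}": w for i, w in enumerate(self.weights_)}
        np.savez(path, config=np.array(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "AngleCNNClassifier":
        data = np.load(path, allow_pickle=False)
        params = json.loads(str(data["config"]))
        for key in ("conv_filters", "classes"):
            params[key] = tuple(params[key])
        model = cls(**params)
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        model.conv_params_ = [[weights[2 * i], weights[2 * i + 1]]
                              for i in range(len(model.conv_filters))]
        model.Wd_, model.bd_ = weights[-2], weights[-1]
        model.weights_ = weights
        model.classes_ = np.asarray(model.classes)
        model.width_ = model.n_channels * _infer_width(model)
        return model


def _infer_width(model) -> int:
    # invert the flatten dimension: width/ch passes through each conv+pool
    # L -> (L - K + 1) // p; search the smallest consistent input length
    target = model.Wd_.shape[0] // model.conv_filters[-1]
    L = target
    for _ in model.conv_filters:
        L = L * model.pool_size + model.kernel_size - 1
    return L


def train_classifier(train_windows, **cfg) -> AngleCNNClassifier:
    """Fit the angle CNN on labeled HallWindows (thin wrapper)."""
    from .preprocess import windows_to_matrix

    if len(train_windows) == 0:
        raise ValueError("empty training set")
    if any(w.label is None for w in train_windows):
        raise ValueError("all training windows must be labeled")
    lengths = {len(w) for w in train_windows}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent window lengths {sorted(lengths)}")
    X, y = windows_to_matrix(train_windows)
    return AngleCNNClassifier(**cfg).fit(X, y)


def predict_angle(model: AngleCNNClassifier, window):
    """Predicted angle class and class probabilities for one window."""
    proba = model.predict_proba(window.values[None, :])[0]
    return int(model.classes_[int(proba.argmax())]), proba


def evaluate_classifier(model: AngleCNNClassifier, test_windows):
    """Confusion matrix (rows = true, cols = predicted) and accuracy."""
    from .evaluate import ConfusionMatrix
    from .preprocess import windows_to_matrix

    if len(test_windows) == 0:
        raise ValueError("empty test set")
    if any(w.label is None for w in test_windows):
        raise ValueError("all test windows must be labeled")
    X, y = windows_to_matrix(test_windows)
    pred = model.predict(X)
    cm = ConfusionMatrix.from_labels(y, pred, classes=model.classes_.tolist())
    return cm, cm.accuracy
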
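"""3D convolutional binary classifier for water-present/absent patterns.

The network follows the selected architecture of the hydration predictor:
a convolution block of ``n_conv_units`` convolution units — each unit is
``conv_layers_per_unit`` 3D convolutions (ReLU) followed by max-pooling
and dropout — and a fully connected block with one hidden layer, ending
in a single sigmoid output trained with binary cross-entropy under
adaptive-moment (Adam) updates.  The default configuration is the
selected model: two convolution units with 3x3x3 filters and 32 channels,
and a 32-node fully connected layer.

Everything is implemented in numpy (forward, backprop, Adam) so training
is deterministic on a fixed seed and single CPU thread.  A brute-force
triple-summation convolution (:func:`conv3d_reference`) serves as the
independent oracle for the vectorized convolution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .voxel import CHANNELS, BoxSpec

_F32 = np.float32

#: Probability clipping applied inside the cross-entropy.
DEFAULT_EPS_CLIP = 1e-7


class LabeledOutput(NamedTuple):
    """A sigmoid output y in [0, 1] paired with its binary label d."""

    y: float
    d: int


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the voxel classifier.

    ``input_edge`` is the voxel count per box edge; pooling must not
    reduce the spatial edge below one voxel.
    """

    n_conv_units: int = 2
    conv_layers_per_unit: int = 2
    channels: int = 32
    filter_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.25
    fcb_nodes: int = 32
    input_edge: int = 41
    padding_mode: str = "same"

    def __post_init__(self) -> None:
        for name in ("n_conv_units", "conv_layers_per_unit", "channels",
                     "filter_size", "pool_size", "fcb_nodes", "input_edge"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.filter_size % 2 == 0:
            raise ValueError("filter_size must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.padding_mode != "same":
            raise ValueError("only 'same' zero-padding is implemented")
        if self.filter_size > self.input_edge:
            raise ValueError("filter larger than input")
        self.edge_schedule()  # raises if pooling exhausts the grid

    def edge_schedule(self) -> list[int]:
        """Spatial edge after each convolution unit (pooling floors)."""
        edges = []
        e = self.input_edge
        for _ in range(self.n_conv_units):
            e = e // self.pool_size
            if e < 1:
                raise ValueError(
                    "pooling reduces the spatial edge below 1 voxel; "
                    "use fewer units or a larger input_edge"
                )
            edges.append(e)
        return edges

    def n_parameters(self, n_input_channels: int = len(CHANNELS)) -> int:
        """Total weight + bias count implied by the configuration."""
        F3 = self.filter_size ** 3
        count = 0
        c_in = n_input_channels
        for _ in range(self.n_conv_units):
            for _ in range(self.conv_layers_per_unit):
                count += F3 * c_in * self.channels + self.channels
                c_in = self.channels
        flat = self.channels * self.edge_schedule()[-1] ** 3
        count += flat * self.fcb_nodes + self.fcb_nodes
        count += self.fcb_nodes + 1
        return count


# ---------------------------------------------------------------------------
# reference convolution and loss
# ---------------------------------------------------------------------------

def conv3d_reference(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Direct triple-summation 3D convolution (valid region only).

    ``u[i,j,k] = sum_{p,q,r} x[i+p, j+q, k+r] * f[p,q,r]`` — the oracle
    the vectorized convolution layer must match.
    """
    x = np.asarray(x, dtype=float)
    filt = np.asarray(filt, dtype=float)
    F = filt.shape[0]
    if filt.shape != (F, F, F):
        raise ValueError("filter must be cubic")
    if any(s < F for s in x.shape):
        raise ValueError("filter larger than input")
    m = tuple(s - F + 1 for s in x.shape)
    out = np.zeros(m)
    for p in range(F):
        for q in range(F):
            for r in range(F):
                out += x[p:p + m[0], q:q + m[1], r:r + m[2]] * filt[p, q, r]
    return out


def bce_loss(batch, d=None, eps: float = DEFAULT_EPS_CLIP) -> float:
    """Mean binary cross-entropy (natural log) over a batch.

    Accepts either a sequence of ``(y, d)`` pairs (:class:`LabeledOutput`)
    or two arrays ``bce_loss(y, d)``.  Outputs are clipped to
    ``[eps, 1 - eps]`` before taking logarithms.
    """
    if d is None:
        pairs = list(batch)
        if not pairs:
            raise ValueError("empty batch")
        y = np.array([p[0] for p in pairs], dtype=float)
        d = np.array([p[1] for p in pairs], dtype=float)
    else:
        y = np.asarray(batch, dtype=float).ravel()
        d = np.asarray(d, dtype=float).ravel()
        if y.size == 0:
            raise ValueError("empty batch")
    y = np.clip(y, eps, 1.0 - eps)
    return float(-np.mean(d * np.log(y) + (1.0 - d) * np.log(1.0 - y)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv3D:
    """'same' zero-padded 3D convolution.

    Activations flow channels-last, shape (B, e, e, e, C); the output is
    accumulated per filter tap as a GEMM over the channel axis, which
    keeps every intermediate copy a cheap strided memcpy.  Weights are
    stored as (F, F, F, c_in, c_out).
    """

    def __init__(self, c_in: int, c_out: int, F: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (c_in * F ** 3))
        self.W = rng.uniform(-lim, lim, size=(F, F, F, c_in, c_out)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.F = F

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, e = x.shape[0], x.shape[1]
        F, pad = self.F, self.F // 2
        xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3 + ((0, 0),))
        out = np.zeros((B, e, e, e, self.W.shape[-1]), dtype=_F32)
        for p in range(F):
            for q in range(F):
                for r in range(F):
                    out += np.tensordot(
                        xp[:, p:p + e, q:q + e, r:r + e, :],
                        self.W[p, q, r], axes=([4], [0]))
        out += self.b
        if train:
            self._xp, self._e = xp, e
        return out

    def forward_sparse(self, x: np.ndarray) -> np.ndarray:
        """Inference fast path for sparse binary inputs (voxel patterns).

        Each nonzero input voxel scatters a reversed filter stamp into the
        padded output; equals :meth:`forward` on binary grids.
        """
        return self.forward_indices(np.nonzero(x), x.shape[0], x.shape[1])

    def forward_indices(self, nz, B: int, e: int) -> np.ndarray:
        """Scatter conv from nonzero indices (batch, ix, iy, iz, channel)."""
        F, pad = self.F, self.F // 2
        c_out = self.W.shape[-1]
        Wrev = np.ascontiguousarray(self.W[::-1, ::-1, ::-1])  # (F,F,F,c_in,c_out)
        out_pad = np.zeros((B, e + 2 * pad, e + 2 * pad, e + 2 * pad, c_out),
                           dtype=_F32)
        bb, ii, jj, kk, cc = nz
        for p in range(F):
            for q in range(F):
                for r in range(F):
                    np.add.at(out_pad, (bb, ii + p, jj + q, kk + r),
                              Wrev[p, q, r, cc])
        out = out_pad[:, pad:e + pad, pad:e + pad, pad:e + pad]
        return out + self.b

    def backward(self, du: np.ndarray) -> np.ndarray:
        xp, e = self._xp, self._e
        F, pad = self.F, self.F // 2
        self.db = du.sum(axis=(0, 1, 2, 3))
        self.dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        for p in range(F):
            for q in range(F):
                for r in range(F):
                    xs = xp[:, p:p + e, q:q + e, r:r + e, :]
                    self.dW[p, q, r] = np.tensordot(xs, du, axes=([0, 1, 2, 3],
                                                                  [0, 1, 2, 3]))
                    dxp[:, p:p + e, q:q + e, r:r + e, :] += np.tensordot(
                        du, self.W[p, q, r], axes=([4], [1]))
        del self._xp
        return dxp[:, pad:pad + e, pad:pad + e, pad:pad + e, :]

    @property
    def grads(self):
        return [self.dW, self.db]


class _SparseInputConv3D(_Conv3D):
    """First convolution specialized for sparse binary voxel inputs.

    Forward scatters filter stamps at the nonzero voxels; backward
    gathers the upstream gradient at those voxels to form the weight
    gradient (no input gradient is needed at the first layer).  Falls
    back to the dense path for non-binary inputs.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        nnz = np.count_nonzero(x)
        binary = nnz <= 0.05 * x.size and float(x.sum()) == float(nnz)
        if not binary:
            self._dense = True
            return super().forward(x, train)
        self._dense = False
        out = self.forward_sparse(x)
        if train:
            self._nz = np.nonzero(x)
            self._shape = x.shape
        return out

    def backward(self, du: np.ndarray) -> np.ndarray:
        if self._dense:
            return super().backward(du)
        F, pad = self.F, self.F // 2
        self.db = du.sum(axis=(0, 1, 2, 3))
        bb, ii, jj, kk, cc = self._nz
        w = ((0, 0), (F - 1 - pad, pad), (F - 1 - pad, pad), (F - 1 - pad, pad), (0, 0))
        du_pad = np.pad(du, w)
        self.dW = np.zeros_like(self.W)
        for p in range(F):
            for q in range(F):
                for r in range(F):
                    vals = du_pad[bb, ii + F - 1 - p, jj + F - 1 - q, kk + F - 1 - r]
                    np.add.at(self.dW[p, q, r], cc, vals)
        return np.zeros(self._shape, dtype=du.dtype)


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def forward_sparse(self, x):
        return np.maximum(x, 0)

    def backward(self, du):
        return du * self._mask


class _MaxPool3D:
    """Non-overlapping max pooling; a trailing remainder row is dropped."""

    params: list = []
    grads: list = []

    def __init__(self, P: int):
        self.P = P

    def _windows(self, x):
        P = self.P
        e = x.shape[1]
        m = (e // P) * P
        B, C = x.shape[0], x.shape[4]
        win = x[:, :m, :m, :m, :].reshape(B, m // P, P, m // P, P, m // P, P, C)
        return win, m

    def forward(self, x, train=False):
        if not train:
            # inference: sequential pairwise maxima (cheap strided reads)
            P = self.P
            m = (x.shape[1] // P) * P
            y = x[:, :m, :m, :m, :]
            for ax in (1, 2, 3):
                sl = [slice(None)] * 5
                sl[ax] = slice(0, None, P)
                acc = np.ascontiguousarray(y[tuple(sl)])
                for off in range(1, P):
                    sl[ax] = slice(off, None, P)
                    np.maximum(acc, y[tuple(sl)], out=acc)
                y = acc
            return y
        win, m = self._windows(x)
        out = win.max(axis=(2, 4, 6))
        mask = win == out[:, :, None, :, None, :, None, :]
        # split gradient equally among ties (valid max subgradient)
        self._mask = mask / mask.sum(axis=(2, 4, 6), keepdims=True)
        self._m, self._shape = m, x.shape
        return out

    forward_sparse = forward

    def backward(self, du):
        dx = np.zeros(self._shape, dtype=du.dtype)
        dwin = self._mask * du[:, :, None, :, None, :, None, :]
        m = self._m
        B, C = self._shape[0], self._shape[4]
        dx[:, :m, :m, :m, :] = dwin.reshape(B, m, m, m, C)
        return dx


class _Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(_F32) / _F32(keep)
        return x * self._mask

    def forward_sparse(self, x):
        return x

    def backward(self, du):
        if self.rate == 0.0:
            return du
        return du * self._mask


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def forward_sparse(self, x):
        return x.reshape(x.shape[0], -1)

    def backward(self, du):
        return du.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-lim, lim, size=(n_in, n_out)).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def forward_sparse(self, x):
        return x @ self.W + self.b

    def backward(self, du):
        self.dW = self._x.T @ du
        self.db = du.sum(axis=0)
        del self._x
        return du @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class _Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        a = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= a * m / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


class HydrationCNN(ClassifierMixin, BaseEstimator):
    """Scikit-learn style 3D-CNN classifier over voxel patterns.

    ``fit(X, y)`` takes grids of shape ``(n, 4, e, e, e)`` (element
    channels C/N/O/S) and binary labels (1 = water present).  Fitted
    attributes: ``layers_``, ``n_parameters_``, ``history_``, ``classes_``.

    Parameters mirror :class:`ModelConfig` plus training hyperparameters.
    ``box`` (a :class:`~hydrosite.voxel.BoxSpec`) and ``resolution_tag``
    ("fine"/"coarse") are metadata carried for the scanning stage.
    ``warm_start=True`` continues training from the current weights.
    """

    def __init__(self, n_conv_units=2, conv_layers_per_unit=2, channels=32,
                 filter_size=3, pool_size=2, dropout_rate=0.25, fcb_nodes=32,
                 input_edge=41, padding_mode="same", epochs=10, batch_size=256,
                 learning_rate=1e-3, eps_clip=DEFAULT_EPS_CLIP,
                 warm_start=False, random_state=None, box=None,
                 resolution_tag=None, verbose=0):
        self.n_conv_units = n_conv_units
        self.conv_layers_per_unit = conv_layers_per_unit
        self.channels = channels
        self.filter_size = filter_size
        self.pool_size = pool_size
        self.dropout_rate = dropout_rate
        self.fcb_nodes = fcb_nodes
        self.input_edge = input_edge
        self.padding_mode = padding_mode
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.eps_clip = eps_clip
        self.warm_start = warm_start
        self.random_state = random_state
        self.box = box
        self.resolution_tag = resolution_tag
        self.verbose = verbose

    # -- construction ------------------------------------------------------

    @property
    def config(self) -> ModelConfig:
        return ModelConfig(
            n_conv_units=self.n_conv_units,
            conv_layers_per_unit=self.conv_layers_per_unit,
            channels=self.channels,
            filter_size=self.filter_size,
            pool_size=self.pool_size,
            dropout_rate=self.dropout_rate,
            fcb_nodes=self.fcb_nodes,
            input_edge=self.input_edge,
            padding_mode=self.padding_mode,
        )

    def initialize(self) -> "HydrationCNN":
        """Build and seed the layer stack without training."""
        cfg = self.config
        rng = np.random.default_rng(self.random_state)
        layers: list = []
        c_in = len(CHANNELS)
        for _ in range(cfg.n_conv_units):
            for _ in range(cfg.conv_layers_per_unit):
                kind = _SparseInputConv3D if not layers else _Conv3D
                layers.append(kind(c_in, cfg.channels, cfg.filter_size, rng))
                layers.append(_ReLU())
                c_in = cfg.channels
            layers.append(_MaxPool3D(cfg.pool_size))
            layers.append(_Dropout(cfg.dropout_rate, rng))
        layers.append(_Flatten())
        flat = cfg.channels * cfg.edge_schedule()[-1] ** 3
        layers.append(_Dense(flat, cfg.fcb_nodes, rng))
        layers.append(_ReLU())
        layers.append(_Dense(cfg.fcb_nodes, 1, rng))
        self.layers_ = layers
        self.classes_ = np.array([0, 1])
        self.n_parameters_ = sum(p.size for l in layers for p in l.params)
        assert self.n_parameters_ == cfg.n_parameters()
        self.history_ = {"epoch": [], "train_loss": [], "train_accuracy": [],
                         "val_loss": [], "val_accuracy": []}
        self._opt = _Adam(self._params(), self.learning_rate)
        self._rng = rng
        return self

    def _params(self):
        return [p for l in self.layers_ for p in l.params]

    def _grads(self):
        return [g for l in self.layers_ for g in l.grads]

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=_F32)
        e = self.input_edge
        if X.ndim != 5 or X.shape[1:] != (len(CHANNELS), e, e, e):
            raise ValueError(
                f"X must have shape (n, {len(CHANNELS)}, {e}, {e}, {e}), got {X.shape}"
            )
        return X

    # -- training ----------------------------------------------------------

    def fit(self, X, y, validation: tuple | None = None) -> "HydrationCNN":
        X = self._check_X(X)
        y = np.asarray(y, dtype=_F32).ravel()
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if not (self.warm_start and hasattr(self, "layers_")):
            self.initialize()
        n = len(X)
        Xi = np.ascontiguousarray(X.transpose(0, 2, 3, 4, 1))  # channels-last
        for epoch in range(self.epochs):
            order = self._rng.permutation(n)
            losses, correct = [], 0
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                xb, db = Xi[idx], y[idx]
                z = xb
                for layer in self.layers_:
                    z = layer.forward(z, train=True)
                p = _sigmoid(z[:, 0].astype(np.float64))
                loss = bce_loss(p, db, eps=self.eps_clip)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
                losses.append(loss * len(idx))
                correct += int(np.sum((p >= 0.5) == (db == 1)))
                dz = ((p - db) / len(idx)).astype(_F32)[:, None]
                g = dz
                for layer in reversed(self.layers_):
                    g = layer.backward(g)
                self._opt.step(self._params(), self._grads())
            self.history_["epoch"].append(len(self.history_["epoch"]) + 1)
            self.history_["train_loss"].append(sum(losses) / n)
            self.history_["train_accuracy"].append(correct / n)
            if validation is not None:
                pv = self.predict_water_probability(validation[0])
                dv = np.asarray(validation[1], dtype=float).ravel()
                self.history_["val_loss"].append(bce_loss(pv, dv, eps=self.eps_clip))
                self.history_["val_accuracy"].append(float(np.mean((pv >= 0.5) == (dv == 1))))
            else:
                self.history_["val_loss"].append(np.nan)
                self.history_["val_accuracy"].append(np.nan)
            if self.verbose:
                print(f"epoch {self.history_['epoch'][-1]}: "
                      f"loss {self.history_['train_loss'][-1]:.4f} "
                      f"acc {self.history_['train_accuracy'][-1]:.4f}")
        return self

    # -- inference ---------------------------------------------------------

    def _forward_eval(self, X: np.ndarray) -> np.ndarray:
        """Dropout-free forward pass (the first conv layer auto-selects its
        sparse fast path on binary voxel grids)."""
        z = X
        for layer in self.layers_:
            z = layer.forward(z, train=False)
        return _sigmoid(z[:, 0].astype(np.float64))

    def _predict_sparse(self, nz, n_patterns: int) -> np.ndarray:
        """Prediction from nonzero voxel indices (scanning fast path)."""
        check_is_fitted(self, "layers_")
        if n_patterns == 0:
            return np.empty(0)
        z = self.layers_[0].forward_indices(nz, n_patterns, self.input_edge)
        for layer in self.layers_[1:]:
            z = layer.forward(z, train=False)
        return _sigmoid(z[:, 0].astype(np.float64))

    def _predict_channels_last(self, Xi: np.ndarray) -> np.ndarray:
        """Prediction over grids already in the internal (n,e,e,e,4) layout."""
        check_is_fitted(self, "layers_")
        out = np.empty(len(Xi))
        step = max(1, self.batch_size)
        for s in range(0, len(Xi), step):
            out[s:s + step] = self._forward_eval(Xi[s:s + step])
        return out

    def predict_water_probability(self, X) -> np.ndarray:
        """P(water present) for each pattern, in [0, 1]."""
        check_is_fitted(self, "layers_")
        X = self._check_X(X)
        out = np.empty(len(X))
        step = max(1, self.batch_size)
        for s in range(0, len(X), step):
            xb = np.ascontiguousarray(X[s:s + step].transpose(0, 2, 3, 4, 1))
            out[s:s + step] = self._forward_eval(xb)
        return out

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_water_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_water_probability(X) >= 0.5).astype(int)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file named-tensor checkpoint with an embedded manifest."""
        check_is_fitted(self, "layers_")
        manifest = {
            "format": "hydrosite-cnn/1",
            "params": {k: v for k, v in self.get_params().items() if k != "box"},
            "box": None if self.box is None else
                   {"n_voxels_per_edge": self.box.n_voxels_per_edge,
                    "voxel_size": self.box.voxel_size},
            "history": self.history_,
        }
        tensors = {f"param_{i:03d}": p for i, p in enumerate(self._params())}
        np.savez(path, manifest=np.array(json.dumps(manifest)), **tensors)

    @classmethod
    def load(cls, path) -> "HydrationCNN":
        with np.load(path, allow_pickle=False) as archive:
            manifest = json.loads(str(archive["manifest"]))
            if manifest.get("format") != "hydrosite-cnn/1":
                raise ValueError("not a hydrosite CNN checkpoint")
            params = manifest["params"]
            box = manifest["box"]
            model = cls(**params)
            if box is not None:
                model.box = BoxSpec(box["n_voxels_per_edge"], box["voxel_size"])
            model.initialize()
            for i, p in enumerate(model._params()):
                p[...] = archive[f"param_{i:03d}"]
            model.history_ = manifest["history"]
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig, seed: int | None = None,
                box: BoxSpec | None = None,
                resolution_tag: str | None = None) -> HydrationCNN:
    """Build a seeded, untrained classifier from a configuration."""
    model = HydrationCNN(random_state=seed, box=box, resolution_tag=resolution_tag,
                         **asdict(config))
    return model.initialize()


def train(model: HydrationCNN, split, epochs: int, batch_size: int = 256,
          learning_rate: float = 1e-3, seed: int | None = None) -> HydrationCNN:
    """Train (or continue training) a model on a train/validation split.

    ``split`` is a :class:`~hydrosite.dataset.SplitDataset`.  With
    ``epochs=0`` the parameters are left unchanged.
    """
    if epochs < 0 or batch_size < 1 or learning_rate <= 0:
        raise ValueError("hyperparameters must be positive")
    Xt, yt = split.train.to_arrays()
    validation = None
    if split.validation.patterns:
        validation = split.validation.to_arrays()
    if not hasattr(model, "layers_"):
        if seed is not None:
            model.set_params(random_state=seed)
        model.initialize()
    if epochs == 0:
        return model
    model.set_params(epochs=epochs, batch_size=batch_size,
                     learning_rate=learning_rate, warm_start=True)
    return model.fit(Xt, yt, validation=validation)


def predict_pattern(model: HydrationCNN, pattern) -> float:
    """Water probability of a single pattern (dropout disabled)."""
    grid = pattern.grid if hasattr(pattern, "grid") else np.asarray(pattern)
    return float(model.predict_water_probability(grid[None])[0])
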
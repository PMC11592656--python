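"""A compact, fully seeded numpy CNN for tabular classification.

Feature vectors are embedded row-major into a small single-channel 2-D grid
(zero-padded tail), then passed through the two-convolution template:
conv(32, 3x3) + ReLU -> max-pool -> conv(64, 3x3) + ReLU -> max-pool ->
flatten -> dropout(0.5) -> [optional dense hidden + ReLU] -> dense -> softmax.
Training minimises categorical cross-entropy with Adam (initial learning
rate 0.001), runs for up to 50 epochs and early-stops on validation loss
with a patience window, restoring the best weights.  Every source of
randomness (weight init, shuffling, dropout) is driven by explicit seeds,
so runs are bit-reproducible single-threaded.

Max-pooling is applied only where the spatial size is at least the pooling
window; on degenerate grids (e.g. a 1x1 embedding of a one-dimensional
discriminant feature) the pool stages become identities rather than
collapsing the tensor.
"""
from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

PERSISTENCE_VERSION = 1


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvLayerSpec:
    filters: int
    kernel: int = 3
    padding: int = 1
    stride: int = 1


@dataclass(frozen=True)
class PoolSpec:
    kind: str = "max"
    window: int = 2
    stride: int = 2


@dataclass(frozen=True)
class CNNSpec:
    """Architecture and training hyperparameters.

    Defaults: learning rate 0.001, 3x3 kernels, dropout 0.5, 50 epochs,
    Adam optimizer, categorical cross-entropy.
    """

    conv_layers: tuple[ConvLayerSpec, ...] = (ConvLayerSpec(32), ConvLayerSpec(64))
    pooling: PoolSpec = PoolSpec()
    dropout_rate: float = 0.5
    hidden_units: int = 0
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    grid_shape: tuple[int, int] | None = None
    n_classes: int = 2
    init_seed: int = 0
    patience: int | None = 5

    def to_dict(self) -> dict:
        return {
            "conv_layers": [vars(c).copy() for c in self.conv_layers],
            "pooling": vars(self.pooling).copy(),
            "dropout_rate": self.dropout_rate,
            "hidden_units": self.hidden_units,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "optimizer": self.optimizer,
            "loss": self.loss,
            "grid_shape": list(self.grid_shape) if self.grid_shape else None,
            "n_classes": self.n_classes,
            "init_seed": self.init_seed,
            "patience": self.patience,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CNNSpec":
        d = dict(d)
        d["conv_layers"] = tuple(ConvLayerSpec(**c) for c in d["conv_layers"])
        d["pooling"] = PoolSpec(**d["pooling"])
        if d.get("grid_shape"):
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def default_grid_shape(n_features: int) -> tuple[int, int]:
    """Smallest square grid holding ``n_features`` cells."""
    side = max(1, math.ceil(math.sqrt(n_features)))
    return side, side


def conv_output_size(N: int, PD: int, K: int, ST: int) -> int:
    """Spatial output size of a convolution: floor((N + 2 PD - K) / ST) + 1."""
    if ST < 1:
        raise ValueError("stride must be >= 1")
    if N + 2 * PD < K:
        raise ValueError(f"window {K} exceeds padded input {N + 2 * PD}")
    return (N + 2 * PD - K) // ST + 1


def grid_embed(x: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Row-major embedding of a feature vector into a 2-D grid, zero-padded."""
    x = np.asarray(x, dtype=float).ravel()
    H, W = grid_shape
    if H * W < x.size:
        raise ValueError(f"grid {H}x{W} too small for {x.size} features")
    out = np.zeros(H * W)
    out[: x.size] = x
    return out.reshape(H, W)


def embed_batch(X: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """(B, d) feature matrix -> (B, 1, H, W) single-channel tensor."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    H, W = grid_shape
    if H * W < X.shape[1]:
        raise ValueError(f"grid {H}x{W} too small for {X.shape[1]} features")
    out = np.zeros((X.shape[0], H * W))
    out[:, : X.shape[1]] = X
    return out.reshape(X.shape[0], 1, H, W)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, in_ch: int, spec: ConvLayerSpec, rng: np.random.Generator):
        k = spec.kernel
        scale = math.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0.0, scale, (spec.filters, in_ch, k, k))
        self.b = np.zeros(spec.filters)
        self.spec = spec
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        p, k, st = self.spec.padding, self.spec.kernel, self.spec.stride
        B, C, H, W = x.shape
        Ho = conv_output_size(H, p, k, st)
        Wo = conv_output_size(W, p, k, st)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((B, self.spec.filters, Ho, Wo))
        for u in range(k):
            for v in range(k):
                xs = xp[:, :, u:u + (Ho - 1) * st + 1:st, v:v + (Wo - 1) * st + 1:st]
                out += np.einsum("fc,bchw->bfhw", self.W[:, :, u, v], xs)
        out += self.b[None, :, None, None]
        self._xp = xp
        self._out_shape = (Ho, Wo)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p, k, st = self.spec.padding, self.spec.kernel, self.spec.stride
        Ho, Wo = self._out_shape
        xp = self._xp
        self.db = dout.sum(axis=(0, 2, 3))
        self.dW = np.zeros_like(self.W)
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                sl_h = slice(u, u + (Ho - 1) * st + 1, st)
                sl_w = slice(v, v + (Wo - 1) * st + 1, st)
                xs = xp[:, :, sl_h, sl_w]
                self.dW[:, :, u, v] = np.einsum("bfhw,bchw->fc", dout, xs)
                dxp[:, :, sl_h, sl_w] += np.einsum("fc,bfhw->bchw", self.W[:, :, u, v], dout)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _MaxPool:
    """Window pooling; identity when the spatial size is below the window."""

    def __init__(self, spec: PoolSpec):
        if spec.kind != "max":
            raise ValueError(f"unsupported pooling kind {spec.kind!r}")
        self.w = spec.window

    def forward(self, x, train, rng):
        B, C, H, W = x.shape
        w = self.w
        if H < w or W < w:
            self._identity = True
            return x
        self._identity = False
        Ho, Wo = H // w, W // w
        xc = x[:, :, : Ho * w, : Wo * w]
        r = xc.reshape(B, C, Ho, w, Wo, w).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(B, C, Ho, Wo, w * w)
        self._idx = np.argmax(flat, axis=-1)
        self._in_shape = (B, C, H, W)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        if self._identity:
            return dout
        B, C, H, W = self._in_shape
        w = self.w
        Ho, Wo = H // w, W // w
        flat = np.zeros((B, C, Ho, Wo, w * w))
        np.put_along_axis(flat, self._idx[..., None], dout[..., None], axis=-1)
        r = flat.reshape(B, C, Ho, Wo, w, w).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((B, C, H, W))
        dx[:, :, : Ho * w, : Wo * w] = r.reshape(B, C, Ho * w, Wo * w)
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dropout:
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self), ("b", self)]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CNNModel:
    """Layer stack with seeded initial weights; built by :func:`build`."""

    def __init__(self, spec: CNNSpec, layers: list):
        self.spec = spec
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, owner in layer.params():
                out.append((f"layer{i}_{name}", owner, name))
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {key: getattr(owner, name).copy() for key, owner, name in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, owner, name in self.parameters():
            setattr(owner, name, weights[key].copy())


def build(spec: CNNSpec) -> CNNModel:
    """Construct the untrained model, validating layer geometry.

    Raises if the softmax would cover fewer than two classes or if any
    convolution/pooling stage would collapse the spatial size below 1.
    """
    if spec.n_classes < 2:
        raise ValueError("softmax over a single class is degenerate; need n_classes >= 2")
    if spec.grid_shape is None:
        raise ValueError("spec.grid_shape must be set (see default_grid_shape)")
    if spec.loss != "categorical_crossentropy":
        raise ValueError(f"unsupported loss {spec.loss!r}")
    if spec.optimizer not in ("adam", "sgd"):
        raise ValueError(f"unsupported optimizer {spec.optimizer!r}")
    rng = np.random.default_rng(spec.init_seed)
    H, W = spec.grid_shape
    layers: list = []
    in_ch = 1
    for i, conv in enumerate(spec.conv_layers):
        try:
            Ho = conv_output_size(H, conv.padding, conv.kernel, conv.stride)
            Wo = conv_output_size(W, conv.padding, conv.kernel, conv.stride)
        except ValueError as exc:
            raise ValueError(f"conv layer {i} collapses the spatial size: {exc}") from None
        if Ho < 1 or Wo < 1:
            raise ValueError(f"conv layer {i} collapses the spatial size to {Ho}x{Wo}")
        layers.append(_Conv(in_ch, conv, rng))
        layers.append(_ReLU())
        H, W, in_ch = Ho, Wo, conv.filters
        if H >= spec.pooling.window and W >= spec.pooling.window:
            H, W = H // spec.pooling.window, W // spec.pooling.window
            if H < 1 or W < 1:
                raise ValueError(f"pooling after conv layer {i} collapses the spatial size")
        layers.append(_MaxPool(spec.pooling))
    layers.append(_Flatten())
    layers.append(_Dropout(spec.dropout_rate))
    n_flat = in_ch * H * W
    if spec.hidden_units > 0:
        layers.append(_Dense(n_flat, spec.hidden_units, rng))
        layers.append(_ReLU())
        n_flat = spec.hidden_units
    layers.append(_Dense(n_flat, spec.n_classes, rng))
    return CNNModel(spec, layers)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    spec: CNNSpec
    model: CNNModel
    training_history: dict[str, list[float]]
    stopped_epoch: int


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, model: CNNModel) -> None:
        self.t += 1
        for key, owner, name in model.parameters():
            g = getattr(owner, "d" + name)
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            w = getattr(owner, name)
            setattr(owner, name, w - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class _SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, model: CNNModel) -> None:
        for _, owner, name in model.parameters():
            w = getattr(owner, name)
            setattr(owner, name, w - self.lr * getattr(owner, "d" + name))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _prepare(X: np.ndarray, spec: CNNSpec) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        return embed_batch(X, spec.grid_shape)
    if X.ndim == 4:
        if X.shape[2:] != tuple(spec.grid_shape):
            raise ValueError(f"tensor spatial shape {X.shape[2:]} != grid {spec.grid_shape}")
        return X
    raise ValueError("X must be a (B, d) matrix or a (B, 1, H, W) tensor")


def _loss_and_grad(logits: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    P = _softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.sum(Y * np.log(P + eps), axis=1))
    return float(loss), (P - Y) / logits.shape[0]


def evaluate_loss(model: CNNModel, X4: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    logits = model.forward(X4, train=False)
    P = _softmax(logits)
    loss = float(-np.mean(np.sum(Y * np.log(P + 1e-12), axis=1)))
    acc = float(np.mean(P.argmax(axis=1) == Y.argmax(axis=1)))
    return loss, acc


def train(model: CNNModel, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray], spec: CNNSpec | None = None,
          seed: int = 0) -> TrainedClassifier:
    """Minimise categorical cross-entropy with Adam, early-stopping on
    validation loss.

    ``train_set``/``val_set`` are (features-or-tensor, integer labels).
    ``spec.patience = None`` disables early stopping; patience 0 stops after
    the first non-improving epoch.  The best-validation-loss weights are
    restored on return.  Deterministic for a fixed seed (single-threaded).
    """
    spec = spec or model.spec
    Xtr, ytr = train_set
    Xva, yva = val_set
    if len(np.asarray(yva)) == 0:
        raise ValueError("validation set must be non-empty")
    ytr = np.asarray(ytr, dtype=int)
    yva = np.asarray(yva, dtype=int)
    if ytr.max(initial=0) >= spec.n_classes or yva.max(initial=0) >= spec.n_classes:
        raise ValueError("labels exceed spec.n_classes")
    X4tr = _prepare(Xtr, spec)
    X4va = _prepare(Xva, spec)
    Ytr = np.eye(spec.n_classes)[ytr]
    Yva = np.eye(spec.n_classes)[yva]

    rng = np.random.default_rng(seed)
    opt = _Adam(spec.learning_rate) if spec.optimizer == "adam" else _SGD(spec.learning_rate)
    history: dict[str, list[float]] = {k: [] for k in
                                       ("loss", "accuracy", "val_loss", "val_accuracy")}
    best_val = np.inf
    best_weights = model.get_weights()
    bad = 0
    stopped = spec.epochs
    n = X4tr.shape[0]
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            logits = model.forward(X4tr[idx], train=True, rng=rng)
            loss, dlogits = _loss_and_grad(logits, Ytr[idx])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch start {start}: "
                    f"loss={loss}, lr={spec.learning_rate}")
            model.backward(dlogits)
            opt.step(model)
            losses.append(loss)
        tr_loss, tr_acc = evaluate_loss(model, X4tr, Ytr)
        va_loss, va_acc = evaluate_loss(model, X4va, Yva)
        history["loss"].append(tr_loss)
        history["accuracy"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_accuracy"].append(va_acc)
        if va_loss < best_val - 1e-12:
            best_val = va_loss
            best_weights = model.get_weights()
            bad = 0
        else:
            bad += 1
            if spec.patience is not None and bad > spec.patience:
                stopped = epoch + 1
                break
    model.set_weights(best_weights)
    return TrainedClassifier(spec, model, history, stopped)


def predict_proba(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities, one row per sample (rows sum to 1)."""
    X4 = _prepare(X, clf.spec)
    return _softmax(clf.model.forward(X4, train=False))


def predict(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    return predict_proba(clf, X).argmax(axis=1)


# ---------------------------------------------------------------------------
# Persistence: plain-text manifest + portable binary weight container
# ---------------------------------------------------------------------------

def save_classifier(clf: TrainedClassifier, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": PERSISTENCE_VERSION,
        "spec": clf.spec.to_dict(),
        "stopped_epoch": clf.stopped_epoch,
        "training_history": clf.training_history,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(d / "weights.npz", **clf.model.get_weights())


def load_classifier(directory: str | Path) -> TrainedClassifier:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if "version" not in manifest:
        raise ValueError("manifest lacks the mandatory version field")
    spec = CNNSpec.from_dict(manifest["spec"])
    model = build(spec)
    with np.load(d / "weights.npz") as npz:
        model.set_weights({k: npz[k] for k in npz.files})
    return TrainedClassifier(spec, model, manifest["training_history"],
                             manifest["stopped_epoch"])
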
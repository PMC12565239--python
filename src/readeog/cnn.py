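"""A small NumPy CNN engine and the lightweight scalogram classifier spec.

The network ("DyslexiaNet"-style) is four convolution blocks — 4×4
kernels, stride 1, 'same' padding, 16/32/64/64 filters, each followed by
batch normalisation and ReLU — with two max-pooling stages (4×4 stride 4
after block 1, 2×2 stride 2 after block 2) that reduce the 28×28×3 input
to a 3×3×64 map, then 50% dropout, a 2-unit fully connected layer and a
softmax.  Per-layer learnable counts are computable from the spec alone:
conv = kh·kw·c_in·n_filters + n_filters, batchnorm = 2·channels,
fc = units·in_features + units.

No deep-learning framework is assumed: convolution is im2col + matmul,
gradients are hand-derived, and optimisation is Adam.  Everything runs
in float32 on a CPU; the network is small enough (~109k parameters) that
this is fast at the scales used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "dyslexianet",
    "build_model",
    "count_learnables",
    "NeuralNet",
    "AdamOptimizer",
    "softmax",
]


# ---------------------------------------------------------------------------
# Architecture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer."""

    name: str
    kind: str  # input|conv|batchnorm|relu|maxpool|dropout|fully_connected|softmax|classification
    filter_size: tuple[int, int] | None = None  # conv kernel or pool window
    n_filters: int | None = None
    stride: int = 1
    padding: str = "same"
    dropout_p: float = 0.5
    units: int | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer list plus the input/output contract."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (28, 28, 3)
    n_classes: int = 2


def dyslexianet() -> ModelSpec:
    """The lightweight 4-conv-block scalogram classifier."""
    L = LayerSpec
    layers = (
        L("imageinput", "input"),
        L("conv_1", "conv", filter_size=(4, 4), n_filters=16),
        L("batchnorm_1", "batchnorm"),
        L("relu_1", "relu"),
        L("maxpool_1", "maxpool", filter_size=(4, 4), stride=4),
        L("conv_2", "conv", filter_size=(4, 4), n_filters=32),
        L("batchnorm_2", "batchnorm"),
        L("relu_2", "relu"),
        L("maxpool_2", "maxpool", filter_size=(2, 2), stride=2),
        L("conv_3", "conv", filter_size=(4, 4), n_filters=64),
        L("batchnorm_3", "batchnorm"),
        L("relu_3", "relu"),
        L("conv_4", "conv", filter_size=(4, 4), n_filters=64),
        L("batchnorm_4", "batchnorm"),
        L("relu_4", "relu"),
        L("dropout", "dropout", dropout_p=0.5),
        L("fc", "fully_connected", units=2),
        L("softmax", "softmax"),
        L("classoutput", "classification"),
    )
    return ModelSpec(layers=layers)


def spec_learnables(spec: ModelSpec) -> dict[str, int]:
    """Per-layer learnable counts by shape inference over the spec."""
    h, w, c = spec.input_shape
    counts: dict[str, int] = {}
    for layer in spec.layers:
        k = layer.kind
        if k == "conv":
            kh, kw = layer.filter_size
            if layer.padding != "same" or layer.stride != 1:
                raise ValueError(f"{layer.name}: only stride-1 'same' convolutions supported")
            counts[layer.name] = kh * kw * c * layer.n_filters + layer.n_filters
            c = layer.n_filters
        elif k == "batchnorm":
            counts[layer.name] = 2 * c
        elif k == "maxpool":
            kh, kw = layer.filter_size
            s = layer.stride
            if h < kh or w < kw:
                raise ValueError(f"{layer.name}: pool window {kh}x{kw} exceeds map {h}x{w}")
            h = (h - kh) // s + 1
            w = (w - kw) // s + 1
            counts[layer.name] = 0
        elif k == "fully_connected":
            counts[layer.name] = layer.units * (h * w * c) + layer.units
            h, w, c = 1, 1, layer.units
        else:
            counts[layer.name] = 0
    return counts


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(_Layer):
    """Stride-1 'same' 2-D convolution via im2col (NHWC layout)."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        fan_in = kh * kw * c_in
        self.kernel = kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (kh, kw, c_in, c_out)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        # 'same' for even kernels: pad (k-1)//2 before, remainder after
        self.pad = ((kh - 1) // 2, kh - 1 - (kh - 1) // 2,
                    (kw - 1) // 2, kw - 1 - (kw - 1) // 2)

    def forward(self, x, train):
        kh, kw = self.kernel
        pt, pb, pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        n, hp, wp, c = xp.shape
        h, w = hp - kh + 1, wp - kw + 1
        cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # n,h,w,c,kh,kw
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
        self._cols = cols.reshape(n * h * w, kh * kw * c)
        self._xshape = x.shape
        wmat = self.params["W"].reshape(kh * kw * c, -1)
        out = self._cols @ wmat + self.params["b"]
        return out.reshape(n, h, w, -1)

    def backward(self, dout):
        kh, kw = self.kernel
        pt, pb, pl, pr = self.pad
        n, h, w, c_out = dout.shape
        dmat = dout.reshape(n * h * w, c_out)
        wmat = self.params["W"].reshape(-1, c_out)
        self.grads["W"] = (self._cols.T @ dmat).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        dcols = (dmat @ wmat.T).reshape(n, h, w, kh, kw, -1)
        hp, wp = h + kh - 1, w + kw - 1
        dxp = np.zeros((n, hp, wp, dcols.shape[-1]), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pt:hp - pb, pl:wp - pr, :]


class BatchNorm(_Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=axes)
                - xhat * (dxhat * xhat).mean(axis=axes)) / std


class ReLU(_Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class MaxPool(_Layer):
    """k×k pooling with stride k (window == stride); floor semantics."""

    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x, train):
        k = self.k
        n, h, w, c = x.shape
        ho, wo = h // k, w // k
        self._inshape = x.shape
        xc = x[:, :ho * k, :wo * k, :]
        r = xc.reshape(n, ho, k, wo, k, c).transpose(0, 1, 3, 2, 4, 5)
        r = r.reshape(n, ho, wo, k * k, c)
        self._argmax = r.argmax(axis=3)
        return np.take_along_axis(r, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        k = self.k
        n, h, w, c = self._inshape
        ho, wo = h // k, w // k
        dr = np.zeros((n, ho, wo, k * k, c), dtype=np.float32)
        np.put_along_axis(dr, self._argmax[:, :, :, None, :],
                          dout[:, :, :, None, :], axis=3)
        dxc = dr.reshape(n, ho, wo, k, k, c).transpose(0, 1, 3, 2, 4, 5)
        dxc = dxc.reshape(n, ho * k, wo * k, c)
        dx = np.zeros(self._inshape, dtype=np.float32)
        dx[:, :ho * k, :wo * k, :] = dxc
        return dx


class Dropout(_Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(_Layer):
    """Fully connected layer; flattens its input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in),
                                      (n_in, n_out)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train):
        self._inshape = x.shape
        self._x = x.reshape(x.shape[0], -1)
        return self._x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return (dout @ self.params["W"].T).reshape(self._inshape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss over the batch and the gradient wrt logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


# ---------------------------------------------------------------------------
# Model assembly and training
# ---------------------------------------------------------------------------

class NeuralNet:
    """A feed-forward stack built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, layers: list[_Layer],
                 names: list[str], learnables: dict[str, int]):
        self.spec = spec
        self.layers = layers
        self.layer_names = names
        self.learnables = learnables

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of NHWC images."""
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self):
        """Iterate (layer, key) pairs of trainable parameters."""
        for layer in self.layers:
            for key in layer.params:
                yield layer, key


def build_model(spec: ModelSpec, seed: int | None = None) -> NeuralNet:
    """Instantiate trainable layers from a spec, validating shapes.

    Raises ``ValueError`` naming the first offending layer if the shape
    arithmetic does not work out.
    """
    rng = np.random.default_rng(seed)
    h, w, c = spec.input_shape
    layers: list[_Layer] = []
    names: list[str] = []
    for ls in spec.layers:
        k = ls.kind
        if k in ("input", "softmax", "classification"):
            continue  # shape bookkeeping only; softmax applied in predict_proba
        if k == "conv":
            layers.append(Conv2D(c, ls.n_filters, ls.filter_size, rng))
            c = ls.n_filters
        elif k == "batchnorm":
            layers.append(BatchNorm(c))
        elif k == "relu":
            layers.append(ReLU())
        elif k == "maxpool":
            kh, kw = ls.filter_size
            if kh != kw or kh != ls.stride:
                raise ValueError(f"{ls.name}: only square window==stride pooling supported")
            if h < kh or w < kw:
                raise ValueError(f"{ls.name}: pool window {kh} exceeds map {h}x{w}")
            layers.append(MaxPool(kh))
            h, w = h // kh, w // kw
        elif k == "dropout":
            layers.append(Dropout(ls.dropout_p, rng))
        elif k == "fully_connected":
            layers.append(Dense(h * w * c, ls.units, rng))
            h, w, c = 1, 1, ls.units
        else:
            raise ValueError(f"{ls.name}: unknown layer kind {k!r}")
        names.append(ls.name)
    if c != spec.n_classes:
        raise ValueError(f"final layer produces {c} outputs, expected {spec.n_classes}")
    return NeuralNet(spec, layers, names, spec_learnables(spec))


def count_learnables(model: NeuralNet | ModelSpec, layer_name: str) -> int:
    """Learnable-parameter count (weights + biases / offsets + scales)."""
    table = model.learnables if isinstance(model, NeuralNet) else spec_learnables(model)
    key = layer_name.lower()
    for name, count in table.items():
        if name.lower() == key:
            return count
    raise KeyError(f"unknown layer {layer_name!r}")


@dataclass
class AdamOptimizer:
    """Adam with the standard bias-corrected moment estimates."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _state: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, model: NeuralNet) -> None:
        self._t += 1
        lr_t = self.learning_rate * (np.sqrt(1 - self.beta2 ** self._t)
                                     / (1 - self.beta1 ** self._t))
        for layer, key in model.parameters():
            g = layer.grads[key]
            sid = (id(layer), key)
            if sid not in self._state:
                self._state[sid] = (np.zeros_like(g), np.zeros_like(g))
            m, v = self._state[sid]
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self._state[sid] = (m, v)
            layer.params[key] -= lr_t * m / (np.sqrt(v) + self.eps)


def train_model(
    model: NeuralNet,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int = 20,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    seed: int | None = None,
    verbose: int = 0,
) -> list[float]:
    """Minibatch Adam training; returns the per-epoch mean loss."""
    rng = np.random.default_rng(seed)
    opt = AdamOptimizer(learning_rate=learning_rate)
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    n = len(x)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step(model)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: loss {history[-1]:.4f}")
    return history
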
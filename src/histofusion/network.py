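"""The coding network: a six-convolution CNN for 140x140x3 RGB patches.

Architecture (spatial size / channels after each stage, zero padding,
floor-convention pooling)::

    input 140x140x3
    conv 7x7/1  -> 134x134x32   (ReLU + local response normalization)
    conv 7x7/1  -> 128x128x32   (ReLU + local response normalization)
    pool 5x5/2  ->  62x 62x32
    conv 9x9/1  ->  54x 54x64
    pool 5x5/2  ->  25x 25x64
    conv 7x7/1  ->  19x 19x64
    conv 7x7/1  ->  13x 13x128
    pool 6x6/2  ->   4x  4x128
    conv 4x4/1  ->   1x  1x256
    full-connection -> 256      (ReLU, dropout 0.5)
    softmax     -> n_classes

Everything (convolution via im2col, max-pooling, cross-channel local
response normalization, dropout, backpropagation, momentum SGD with a
divide-by-10 plateau learning-rate schedule) is implemented in numpy; the
network is small enough to train on one CPU at reduced scale.

Conventions: batches are ``(N, H, W, C)`` float32 arrays; convolution uses
no partial windows and zero padding by default (the only convention under
which the architecture's published shape arithmetic is self-consistent).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic import ConfigurationError, DimensionError, ImageDataset

#: cross-channel normalization defaults: (depth_radius, k, alpha, beta)
DEFAULT_LRN_PARAMS = (5, 2.0, 1e-4, 0.75)


# ---------------------------------------------------------------------------
# shape arithmetic


def conv_output_size(n: int, kernel: int, stride: int, padding: int = 0) -> int:
    """Spatial output size of a convolution: floor((n - k + 2p)/s) + 1."""
    if n + 2 * padding < kernel:
        raise DimensionError(
            f"convolution window {kernel} larger than padded input {n + 2 * padding}"
        )
    return (n - kernel + 2 * padding) // stride + 1


def pool_output_size(n: int, window: int, stride: int) -> int:
    """Spatial output size of max pooling with no partial windows."""
    if window > n:
        raise DimensionError(f"pool window {window} larger than input {n}")
    return (n - window) // stride + 1


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass(frozen=True)
class LayerSpec:
    kind: str  # convolution | max_pool | full_connection | softmax
    kernel: int = 1
    stride: int = 1
    out_channels: int | None = None
    padding: int = 0
    lrn: bool = False  # apply local response normalization after activation

    def __post_init__(self):
        if self.kind not in {"convolution", "max_pool", "full_connection", "softmax"}:
            raise ConfigurationError(f"unknown layer kind {self.kind!r}")
        if self.kernel < 1 or self.stride < 1 or self.padding < 0:
            raise ConfigurationError("kernel/stride must be >= 1, padding >= 0")


def default_layers(n_classes: int = 6) -> tuple[LayerSpec, ...]:
    """The published layer stack of the coding network."""
    C = LayerSpec
    return (
        C("convolution", kernel=7, out_channels=32, lrn=True),
        C("convolution", kernel=7, out_channels=32, lrn=True),
        C("max_pool", kernel=5, stride=2),
        C("convolution", kernel=9, out_channels=64),
        C("max_pool", kernel=5, stride=2),
        C("convolution", kernel=7, out_channels=64),
        C("convolution", kernel=7, out_channels=128),
        C("max_pool", kernel=6, stride=2),
        C("convolution", kernel=4, out_channels=256),
        C("full_connection", out_channels=256),
        C("softmax", out_channels=n_classes),
    )


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    input_size: int = 140
    input_channels: int = 3
    layers: tuple[LayerSpec, ...] = dataclasses.field(default_factory=default_layers)
    lrn_params: tuple = DEFAULT_LRN_PARAMS
    dropout_rate: float = 0.5
    n_classes: int = 6

    def __post_init__(self):
        if not self.layers or self.layers[-1].kind != "softmax":
            raise ConfigurationError("last layer must be softmax")
        if self.layers[-1].out_channels != self.n_classes:
            raise ConfigurationError("softmax width must equal n_classes")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        self.shape_trace()  # raises if any spatial size is non-positive

    def shape_trace(self) -> list[tuple[int, int, int]]:
        """(H, W, C) after each layer; must match the published table for
        the default configuration."""
        h = w = self.input_size
        c = self.input_channels
        trace = []
        for spec in self.layers:
            try:
                if spec.kind == "convolution":
                    h = conv_output_size(h, spec.kernel, spec.stride, spec.padding)
                    w = conv_output_size(w, spec.kernel, spec.stride, spec.padding)
                    c = spec.out_channels
                elif spec.kind == "max_pool":
                    h = pool_output_size(h, spec.kernel, spec.stride)
                    w = pool_output_size(w, spec.kernel, spec.stride)
                else:  # full_connection / softmax collapse to 1x1xC
                    h = w = 1
                    c = spec.out_channels
            except DimensionError as exc:
                raise ConfigurationError(
                    f"shape propagation failed at {spec}: {exc}"
                ) from exc
            if h < 1 or w < 1 or (c is not None and c < 1):
                raise ConfigurationError(
                    f"shape propagation reached non-positive size at {spec}"
                )
            trace.append((h, w, c))
        return trace


def scaled_network_config(
    input_size: int = 32,
    n_classes: int = 6,
    channels: Sequence[int] = (8, 8, 16, 16, 32),
    fc_width: int = 64,
) -> NetworkConfig:
    """A proportionally shrunk network with the same layer pattern
    (conv, conv, pool, conv, pool, conv, conv, pool, conv, fc, softmax)
    for desk-scale experiments.  The sixth convolution's kernel consumes
    whatever spatial extent remains, mirroring the full-size design where
    conv6 reduces 4x4 to 1x1."""
    C = LayerSpec
    h = input_size
    stack = [
        C("convolution", kernel=3, out_channels=channels[0], lrn=True),
        C("convolution", kernel=3, out_channels=channels[1], lrn=True),
        C("max_pool", kernel=2, stride=2),
        C("convolution", kernel=3, out_channels=channels[2]),
        C("max_pool", kernel=2, stride=2),
        C("convolution", kernel=3, out_channels=channels[3]),
        C("convolution", kernel=3, out_channels=channels[4]),
        C("max_pool", kernel=2, stride=2),
    ]
    for spec in stack:
        f = conv_output_size if spec.kind == "convolution" else pool_output_size
        h = f(h, spec.kernel, spec.stride)
    stack += [
        C("convolution", kernel=h, out_channels=2 * channels[4]),
        C("full_connection", out_channels=fc_width),
        C("softmax", out_channels=n_classes),
    ]
    return NetworkConfig(
        input_size=input_size, layers=tuple(stack), n_classes=n_classes
    )


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 100
    momentum: float = 0.9
    initial_lr: float = 0.01
    epochs: int = 45
    lr_drop_factor: float = 10.0
    plateau_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.initial_lr, self.epochs) <= 0:
            raise ConfigurationError("batch_size, initial_lr, epochs must be positive")
        if self.lr_drop_factor <= 1:
            raise ConfigurationError("lr_drop_factor must exceed 1")


# ---------------------------------------------------------------------------
# primitive ops


def _lrn_forward(x: np.ndarray, params: tuple):
    """y_i = x_i / (k + alpha * sum_{j in window(i)} x_j^2)^beta across the
    channel axis (last); window(i) spans depth_radius channels centred on i,
    clipped at the edges."""
    depth_radius, k, alpha, beta = params
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite activations entering LRN")
    half = depth_radius // 2
    sq = x * x
    S = sq.copy()
    C = x.shape[-1]
    for off in range(1, half + 1):
        S[..., off:] += sq[..., : C - off]
        S[..., : C - off] += sq[..., off:]
    den_base = k + alpha * S
    den = den_base**beta
    return x / den, (x, S, den_base, den)


def _lrn_backward(dy: np.ndarray, cache, params: tuple) -> np.ndarray:
    depth_radius, k, alpha, beta = params
    half = depth_radius // 2
    x, S, den_base, den = cache
    g = dy * x / (den * den_base)  # dy * x * den_base^{-beta-1}
    gsum = g.copy()
    C = x.shape[-1]
    for off in range(1, half + 1):
        gsum[..., off:] += g[..., : C - off]
        gsum[..., : C - off] += g[..., off:]
    return dy / den - 2.0 * alpha * beta * x * gsum


def local_response_normalization(
    activations: np.ndarray, params: tuple = DEFAULT_LRN_PARAMS
) -> np.ndarray:
    """Cross-channel local response normalization of one H x W x C map."""
    out, _ = _lrn_forward(activations[None] if activations.ndim == 3 else activations,
                          params)
    return out[0] if activations.ndim == 3 else out


def apply_dropout(
    activations: np.ndarray, rate: float, seed: int, training: bool
) -> np.ndarray:
    """Inverted dropout: zero each unit with probability ``rate`` and scale
    survivors by 1/(1-rate) during training; identity at inference."""
    if not 0 <= rate < 1:
        raise ConfigurationError("dropout rate must be in [0, 1)")
    if not training or rate == 0:
        return activations
    rng = np.random.default_rng(seed)
    mask = rng.random(activations.shape) >= rate
    return activations * mask / (1.0 - rate)


def _im2col(x: np.ndarray, k: int, stride: int):
    """(N,H,W,C) -> (N, oh, ow, k*k*C) patch matrix (ki, kj, c ordering)."""
    view = sliding_window_view(x, (k, k), axis=(1, 2))  # N,oh',ow',C,k,k
    view = view[:, ::stride, ::stride]
    view = view.transpose(0, 1, 2, 4, 5, 3)  # N,oh,ow,k,k,C
    n, oh, ow = view.shape[:3]
    return np.ascontiguousarray(view).reshape(n, oh, ow, -1)


class _ConvLayer:
    """Convolution + ReLU (+ optional LRN). Weights (k,k,Cin,Cout)."""

    def __init__(self, spec: LayerSpec, in_ch: int, lrn_params, rng):
        k, c_out = spec.kernel, spec.out_channels
        fan_in = k * k * in_ch
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, in_ch, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.spec = spec
        self.lrn_params = lrn_params
        self.dW = self.db = None

    def forward(self, x, training=False, rng=None):
        s = self.spec
        if s.padding:
            x = np.pad(x, ((0, 0), (s.padding,) * 2, (s.padding,) * 2, (0, 0)))
        cols = _im2col(x, s.kernel, s.stride)
        Wm = self.W.reshape(-1, self.W.shape[-1])
        z = cols @ Wm + self.b
        a = np.maximum(z, 0.0)
        if s.lrn:
            out, lrn_cache = _lrn_forward(a, self.lrn_params)
        else:
            out, lrn_cache = a, None
        self._cache = (x.shape, cols, z > 0, lrn_cache)
        return out

    def backward(self, dy):
        s = self.spec
        x_shape, cols, relu_mask, lrn_cache = self._cache
        if s.lrn:
            dy = _lrn_backward(dy, lrn_cache, self.lrn_params)
        dz = dy * relu_mask
        n, oh, ow, _ = dz.shape
        dz_flat = dz.reshape(-1, dz.shape[-1])
        cols_flat = cols.reshape(-1, cols.shape[-1])
        self.dW = (cols_flat.T @ dz_flat).reshape(self.W.shape)
        self.db = dz_flat.sum(axis=0)
        # col2im: scatter gradients back through the patch extraction
        k, st = s.kernel, s.stride
        Wm = self.W.reshape(-1, self.W.shape[-1])
        dcols = (dz_flat @ Wm.T).reshape(n, oh, ow, k, k, -1)
        dx = np.zeros(x_shape, dtype=dcols.dtype)
        for ki in range(k):
            for kj in range(k):
                dx[:, ki : ki + st * oh : st, kj : kj + st * ow : st] += dcols[
                    :, :, :, ki, kj
                ]
        if s.padding:
            p = s.padding
            dx = dx[:, p:-p, p:-p]
        return dx

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]


class _PoolLayer:
    def __init__(self, spec: LayerSpec):
        self.spec = spec

    def forward(self, x, training=False, rng=None):
        w, s = self.spec.kernel, self.spec.stride
        view = sliding_window_view(x, (w, w), axis=(1, 2))[:, ::s, ::s]
        n, oh, ow, c = view.shape[:4]
        flat = view.reshape(n, oh, ow, c, w * w)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return np.ascontiguousarray(out)

    def backward(self, dy):
        w, s = self.spec.kernel, self.spec.stride
        x_shape, idx = self._cache
        n, oh, ow, c = idx.shape
        dx = np.zeros(x_shape, dtype=dy.dtype)
        ii = (np.arange(oh) * s)[None, :, None, None] + idx // w
        jj = (np.arange(ow) * s)[None, None, :, None] + idx % w
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, None, None, :]
        np.add.at(dx, (nn, ii, jj, cc), dy)
        return dx

    @property
    def params(self):
        return []


class _DenseLayer:
    """Flattens its input; ReLU + dropout for the hidden full-connection,
    plain logits for the softmax head."""

    def __init__(self, in_dim, out_dim, relu, dropout_rate, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim)).astype(
            np.float32
        )
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.relu = relu
        self.dropout_rate = dropout_rate if relu else 0.0

    def forward(self, x, training=False, rng=None):
        x_shape = x.shape
        x2 = x.reshape(x.shape[0], -1)
        z = x2 @ self.W + self.b
        a = np.maximum(z, 0.0) if self.relu else z
        self.pre_dropout = a
        mask = None
        if training and self.dropout_rate > 0:
            mask = (rng.random(a.shape) >= self.dropout_rate) / (
                1.0 - self.dropout_rate
            )
            a = a * mask
        self._cache = (x_shape, x2, z > 0 if self.relu else None, mask)
        return a

    def backward(self, dy):
        x_shape, x2, relu_mask, mask = self._cache
        if mask is not None:
            dy = dy * mask
        dz = dy * relu_mask if self.relu else dy
        self.dW = x2.T @ dz
        self.db = dz.sum(axis=0)
        return (dz @ self.W.T).reshape(x_shape)

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]


# ---------------------------------------------------------------------------
# the network


@dataclasses.dataclass
class TrainedNetwork:
    config: NetworkConfig
    layers: list
    input_mean: np.ndarray | None = None  # per-channel, from the training split
    history: dict = dataclasses.field(default_factory=dict)

    @property
    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(l.W, l.b) for l in self.layers if hasattr(l, "W")]

    def shape_trace(self):
        return self.config.shape_trace()


def build_network(config: NetworkConfig, seed: int = 0) -> TrainedNetwork:
    """Instantiate the network with fan-in-scaled zero-mean Gaussian weights."""
    rng = np.random.default_rng(seed)
    trace = config.shape_trace()
    layers = []
    h, w, c = config.input_size, config.input_size, config.input_channels
    for spec, (nh, nw, nc) in zip(config.layers, trace):
        if spec.kind == "convolution":
            layers.append(_ConvLayer(spec, c, config.lrn_params, rng))
        elif spec.kind == "max_pool":
            layers.append(_PoolLayer(spec))
        elif spec.kind == "full_connection":
            layers.append(
                _DenseLayer(h * w * c, nc, True, config.dropout_rate, rng)
            )
        else:  # softmax head: plain logits, softmax applied in the loss
            layers.append(_DenseLayer(h * w * c, nc, False, 0.0, rng))
        h, w, c = nh, nw, nc
    return TrainedNetwork(config=config, layers=layers)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _prepare(net: TrainedNetwork, images) -> np.ndarray:
    X = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    expected = (net.config.input_size, net.config.input_size, net.config.input_channels)
    if X.shape[1:] != expected:
        raise DimensionError(f"images have shape {X.shape[1:]}, expected {expected}")
    if net.input_mean is not None:
        X = X - net.input_mean
    return X


def forward(
    net: TrainedNetwork,
    X: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
    capture: dict | None = None,
) -> np.ndarray:
    """Run the network, returning class probabilities.  ``capture`` may
    collect intermediate activations under keys 'last_pool' (final
    max-pool output) and 'fc' (full-connection activations, pre-dropout)."""
    a = X
    last_pool_i = max(
        (i for i, s in enumerate(net.config.layers) if s.kind == "max_pool"),
        default=None,
    )
    for i, layer in enumerate(net.layers):
        a = layer.forward(a, training=training, rng=rng)
        if capture is not None:
            if i == last_pool_i:
                capture["last_pool"] = a
            if net.config.layers[i].kind == "full_connection":
                capture["fc"] = layer.pre_dropout
    return _softmax(a)


def predict_proba(net: TrainedNetwork, images) -> np.ndarray:
    """Class-probability matrix; rows are non-negative and sum to 1."""
    X = _prepare(net, images)
    out = []
    for start in range(0, len(X), 128):
        out.append(forward(net, X[start : start + 128]))
    return np.vstack(out)


def _loss_and_grad(net, X, y_onehot, rng):
    probs = forward(net, X, training=True, rng=rng)
    n = X.shape[0]
    eps = 1e-12
    loss = -np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1))
    d = (probs - y_onehot) / n
    for layer in reversed(net.layers):
        d = layer.backward(d)
    return loss


def loss_gradients(net, X, y_onehot, rng=None):
    """Cross-entropy loss and its parameter gradients (for verification)."""
    if rng is None:
        rng = np.random.default_rng(0)
    loss = _loss_and_grad(net, X, y_onehot, rng)
    grads = [(l.dW, l.db) for l in net.layers if hasattr(l, "W")]
    return loss, grads


def cross_entropy(net, X, labels) -> float:
    probs = forward(net, X)
    idx = np.asarray(labels) - 1
    return float(-np.mean(np.log(probs[np.arange(len(X)), idx] + 1e-12)))


def error_rate(net, X, labels) -> float:
    probs = []
    for start in range(0, len(X), 128):
        probs.append(forward(net, X[start : start + 128]))
    pred = np.vstack(probs).argmax(axis=1) + 1
    return float(np.mean(pred != np.asarray(labels)))


def train_network(
    net: TrainedNetwork, data: ImageDataset, cfg: TrainConfig
) -> TrainedNetwork:
    """Momentum SGD on the cross-entropy loss with a plateau learning-rate
    schedule: the rate is divided by ``lr_drop_factor`` whenever the
    validation error rate fails to improve for ``plateau_patience``
    consecutive epochs.  Per-channel mean of the training split is
    subtracted from every input (stored on the network)."""
    if data.split is None:
        raise ConfigurationError("dataset has no split assignment")
    train = data.subset(data.split == "train")
    val = data.subset(data.split == "validation")
    if len(train) == 0 or len(val) == 0:
        raise ConfigurationError("empty train or validation split")

    Xtr = np.stack(train.images).astype(np.float32)
    net.input_mean = Xtr.mean(axis=(0, 1, 2), dtype=np.float64).astype(np.float32)
    Xtr -= net.input_mean
    ytr = train.labels
    Xval = _prepare(net, val.images)

    C = net.config.n_classes
    onehot = np.eye(C, dtype=np.float32)[ytr - 1]

    rng = np.random.default_rng(cfg.seed)
    velocities = [
        [np.zeros_like(l.W), np.zeros_like(l.b)]
        for l in net.layers
        if hasattr(l, "W")
    ]
    lr = cfg.initial_lr
    best_val = np.inf
    stall = 0
    hist = {"train_loss": [], "val_loss": [], "val_error": [], "lr": []}
    n = len(Xtr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            losses.append(_loss_and_grad(net, Xtr[idx], onehot[idx], rng))
            pl = 0
            for layer in net.layers:
                if not hasattr(layer, "W"):
                    continue
                vW, vb = velocities[pl]
                vW *= cfg.momentum
                vW -= lr * layer.dW
                vb *= cfg.momentum
                vb -= lr * layer.db
                layer.W += vW
                layer.b += vb
                pl += 1
        verr = error_rate(net, Xval, val.labels)
        hist["train_loss"].append(float(np.mean(losses)))
        hist["val_loss"].append(cross_entropy(net, Xval, val.labels))
        hist["val_error"].append(verr)
        hist["lr"].append(lr)
        if verr < best_val - 1e-12:
            best_val = verr
            stall = 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                lr /= cfg.lr_drop_factor
                stall = 0
    net.history = hist
    return net


def plateau_lr(initial_lr: float, n_plateau_events: int, drop_factor: float = 10.0):
    """Learning rate after a number of plateau events (schedule arithmetic)."""
    return initial_lr / drop_factor**n_plateau_events


# ---------------------------------------------------------------------------
# serialization: parameter archive + JSON sidecar (config, shapes, history)


def config_to_dict(config: NetworkConfig) -> dict:
    return {
        "input_size": config.input_size,
        "input_channels": config.input_channels,
        "layers": [dataclasses.asdict(s) for s in config.layers],
        "lrn_params": list(config.lrn_params),
        "dropout_rate": config.dropout_rate,
        "n_classes": config.n_classes,
    }


def config_from_dict(d: dict) -> NetworkConfig:
    return NetworkConfig(
        input_size=d["input_size"],
        input_channels=d["input_channels"],
        layers=tuple(LayerSpec(**s) for s in d["layers"]),
        lrn_params=tuple(d["lrn_params"]),
        dropout_rate=d["dropout_rate"],
        n_classes=d["n_classes"],
    )


def save_network(net: TrainedNetwork, path) -> None:
    import json
    from pathlib import Path

    arrays = {}
    for i, layer in enumerate(net.layers):
        if hasattr(layer, "W"):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
    if net.input_mean is not None:
        arrays["input_mean"] = net.input_mean
    np.savez(path, **arrays)
    sidecar = Path(str(path)).with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "config": config_to_dict(net.config),
                "shape_trace": [list(t) for t in net.shape_trace()],
                "history": net.history,
            },
            fh,
            indent=1,
        )


def load_network(path) -> TrainedNetwork:
    import json
    from pathlib import Path

    sidecar = Path(str(path)).with_suffix(".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    net = build_network(config_from_dict(meta["config"]), seed=0)
    z = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    for i, layer in enumerate(net.layers):
        if hasattr(layer, "W"):
            layer.W = z[f"W{i}"]
            layer.b = z[f"b{i}"]
    if "input_mean" in z:
        net.input_mean = z["input_mean"]
    net.history = meta["history"]
    return net
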
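"""Sparse autoencoder with a KL-divergence sparsity penalty.

A three-layer network trained to reconstruct its input: hidden layer
``h = sigma(W_enc x + b_enc)`` of size s2 < d, reconstruction
``x_hat = sigma(W_dec h + b_dec)``.  The cost is

    J_sparse = J + beta * sum_j KL(rho || rho_hat_j)

where J = (1/m) sum_i ||x_hat_i - x_i||^2 is the mean squared
reconstruction error over the m samples,
rho_hat_j = (1/m) sum_i h_j(x_i) is the observed mean activation of hidden
unit j, rho in (0,1) is the sparsity target and

    KL(rho || q) = rho log(rho/q) + (1-rho) log((1-rho)/(1-q)).

The penalty pushes every hidden unit's mean activation toward rho, giving a
sparse low-dimensional code.  Both layers use the logistic sigmoid (the KL
term requires hidden activations in (0,1); sigmoid output pairs with inputs
min-max scaled to [0,1]).  Encoder and decoder weights are untied.

The analytic gradient includes the penalty's coupling through rho_hat
(which ties all samples together); it is verified against central
differences in the test suite.  Training is full-batch gradient descent
with momentum — simple and exactly reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .synthetic import ConfigurationError, DimensionError

_CLIP = 1e-10  # rho_hat clipped to [_CLIP, 1-_CLIP] before the logs


class NumericError(FloatingPointError):
    pass


@dataclasses.dataclass
class SAEModel:
    W_enc: np.ndarray  # s2 x d
    b_enc: np.ndarray  # s2
    W_dec: np.ndarray  # d x s2
    b_dec: np.ndarray  # d
    s2: int
    rho: float = 0.05
    beta: float = 3.0
    weight_decay: float = 0.0  # optional, 0 keeps the cost equation-faithful
    scale_min: np.ndarray | None = None  # stored min-max scaling (train split)
    scale_range: np.ndarray | None = None

    def __post_init__(self):
        d = self.W_enc.shape[1]
        if self.s2 >= d:
            raise ConfigurationError(
                f"hidden size s2={self.s2} must be below input width d={d}"
            )
        if not 0 < self.rho < 1:
            raise ConfigurationError("rho must lie strictly inside (0, 1)")
        if self.beta < 0:
            raise ConfigurationError("beta must be non-negative")


@dataclasses.dataclass
class SAEState:
    hidden: np.ndarray  # m x s2
    reconstruction: np.ndarray  # m x d
    rho_hat: np.ndarray  # s2
    m: int


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sae_forward(model: SAEModel, X: np.ndarray) -> SAEState:
    """Hidden code, reconstruction and mean hidden activations rho_hat."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W_enc.shape[1]:
        raise DimensionError(
            f"X has {X.shape[1]} columns, model expects {model.W_enc.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise NumericError("non-finite values in input")
    hidden = _sigmoid(X @ model.W_enc.T + model.b_enc)
    reconstruction = _sigmoid(hidden @ model.W_dec.T + model.b_dec)
    return SAEState(
        hidden=hidden,
        reconstruction=reconstruction,
        rho_hat=hidden.mean(axis=0),
        m=X.shape[0],
    )


def kl_divergence(rho: float, rho_hat_j: float) -> float:
    """Bernoulli KL divergence KL(rho || rho_hat_j); >= 0, zero iff equal."""
    if not (0 < rho < 1 and 0 < rho_hat_j < 1):
        raise ValueError("both arguments must lie strictly inside (0, 1)")
    return rho * np.log(rho / rho_hat_j) + (1 - rho) * np.log(
        (1 - rho) / (1 - rho_hat_j)
    )


def sae_cost(model: SAEModel, X: np.ndarray, state: SAEState | None = None):
    """(J_sparse, J, penalty): total cost, mean squared reconstruction
    error, and the summed KL sparsity penalty."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if state is None:
        state = sae_forward(model, X)
    diff = state.reconstruction - X
    J = float(np.sum(diff * diff) / state.m)
    q = np.clip(state.rho_hat, _CLIP, 1 - _CLIP)
    penalty = float(
        np.sum(
            model.rho * np.log(model.rho / q)
            + (1 - model.rho) * np.log((1 - model.rho) / (1 - q))
        )
    )
    J_sparse = J + model.beta * penalty
    if model.weight_decay:
        J_sparse += (
            model.weight_decay
            / 2.0
            * (np.sum(model.W_enc**2) + np.sum(model.W_dec**2))
        )
    return J_sparse, J, penalty


def sae_gradient(model: SAEModel, X: np.ndarray, state: SAEState | None = None):
    """Analytic gradient of J_sparse w.r.t. (W_enc, b_enc, W_dec, b_dec).

    The KL term back-propagates through rho_hat_j = mean_i h_ij, adding
    beta/m * (-rho/rho_hat + (1-rho)/(1-rho_hat)) to every sample's hidden
    gradient."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if state is None:
        state = sae_forward(model, X)
    m = state.m
    H, R = state.hidden, state.reconstruction
    dR = (2.0 / m) * (R - X)
    dZ2 = dR * R * (1 - R)
    gW_dec = dZ2.T @ H
    gb_dec = dZ2.sum(axis=0)
    q = np.clip(state.rho_hat, _CLIP, 1 - _CLIP)
    dkl = model.beta * (-model.rho / q + (1 - model.rho) / (1 - q)) / m
    dH = dZ2 @ model.W_dec + dkl[None, :]
    dZ1 = dH * H * (1 - H)
    gW_enc = dZ1.T @ X
    gb_enc = dZ1.sum(axis=0)
    if model.weight_decay:
        gW_enc += model.weight_decay * model.W_enc
        gW_dec += model.weight_decay * model.W_dec
    return gW_enc, gb_enc, gW_dec, gb_dec


@dataclasses.dataclass(frozen=True)
class SAEOptConfig:
    learning_rate: float = 0.5
    momentum: float = 0.9
    epochs: int = 400


def train_sae(
    X: np.ndarray,
    s2: int,
    rho: float = 0.05,
    beta: float = 3.0,
    opt: SAEOptConfig | None = None,
    seed: int = 0,
    weight_decay: float = 0.0,
) -> SAEModel:
    """Fit by full-batch momentum gradient descent; deterministic given seed.

    X must be scaled to [0,1].  The final J_sparse never exceeds the initial
    one: if an update would increase the cost, the step is rolled back, the
    learning rate halved and momentum reset (simple backtracking keeps the
    trajectory monotone without hand-tuning the rate)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    if s2 >= d:
        raise ConfigurationError(f"s2={s2} must be below input width d={d}")
    opt = opt or SAEOptConfig()
    rng = np.random.default_rng(seed)
    r = np.sqrt(6.0 / (d + s2 + 1))
    model = SAEModel(
        W_enc=rng.uniform(-r, r, (s2, d)),
        b_enc=np.zeros(s2),
        W_dec=rng.uniform(-r, r, (d, s2)),
        b_dec=np.zeros(d),
        s2=s2,
        rho=rho,
        beta=beta,
        weight_decay=weight_decay,
    )
    params = [model.W_enc, model.b_enc, model.W_dec, model.b_dec]
    vel = [np.zeros_like(p) for p in params]
    lr = opt.learning_rate
    cost, _, _ = sae_cost(model, X)
    history = [cost]
    for _ in range(opt.epochs):
        grads = sae_gradient(model, X)
        backup = [p.copy() for p in params]
        for p, v, g in zip(params, vel, grads):
            v *= opt.momentum
            v -= lr * g
            p += v
        new_cost, _, _ = sae_cost(model, X)
        if new_cost > cost + 1e-15:
            for p, b, v in zip(params, backup, vel):
                p[...] = b
                v[...] = 0.0
            lr *= 0.5
            new_cost = cost
        cost = new_cost
        history.append(cost)
    model.history = np.asarray(history)
    return model


def encode(model: SAEModel, X: np.ndarray) -> np.ndarray:
    """The sparse hidden representation (width s2 < d)."""
    return sae_forward(model, X).hidden


def fit_minmax(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column min and range on the training split (range 1 where
    constant, so scaling maps constants to 0)."""
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return lo, rng


def apply_minmax(X: np.ndarray, lo: np.ndarray, rng: np.ndarray) -> np.ndarray:
    return np.clip((X - lo) / rng, 0.0, 1.0)


def save_sae(model: SAEModel, path) -> None:
    np.savez(
        path,
        W_enc=model.W_enc,
        b_enc=model.b_enc,
        W_dec=model.W_dec,
        b_dec=model.b_dec,
        meta=np.array(
            [model.s2, model.rho, model.beta, model.weight_decay], dtype=float
        ),
        scale_min=model.scale_min if model.scale_min is not None else np.array([]),
        scale_range=model.scale_range
        if model.scale_range is not None
        else np.array([]),
    )


def load_sae(path) -> SAEModel:
    z = np.load(path)
    s2, rho, beta, wd = z["meta"]
    return SAEModel(
        W_enc=z["W_enc"],
        b_enc=z["b_enc"],
        W_dec=z["W_dec"],
        b_dec=z["b_dec"],
        s2=int(s2),
        rho=float(rho),
        beta=float(beta),
        weight_decay=float(wd),
        scale_min=z["scale_min"] if z["scale_min"].size else None,
        scale_range=z["scale_range"] if z["scale_range"].size else None,
    )
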
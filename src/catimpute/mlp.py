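"""From-scratch dense multilayer perceptron with momentum gradient descent.

The network is the standard fully-connected architecture: rectifier hidden
layers, logistic-sigmoid output units, and an independent-per-unit binary
cross-entropy loss — the natural pairing when targets are concatenated
one-hot blocks treated as multi-label indicators.  Training is mini-batch
stochastic gradient descent with momentum:

    v  <-  beta * v + (1 - beta) * grad
    w  <-  w - alpha * v

with velocity ``v`` starting at zero.  ``beta = 0`` recovers plain SGD
exactly.  Everything is deterministic given the seed.

This module is deliberately self-contained (numpy only): the optimizer and
backpropagation are the checkable core of the package, verified against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DivergenceError, ShapeError

_EPS = 1e-12  # loss clipping only; gradients use unclipped predictions


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the common setup for this scheme: learning rate 0.001,
    momentum 0.9, batch size 256, 1000 epochs, three hidden layers of 32
    units.  Tests and small fixtures override ``epochs`` downward.
    """

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 256
    epochs: int = 1000
    hidden: tuple[int, ...] = (32, 32, 32)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ConfigError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        self.hidden = tuple(int(h) for h in self.hidden)
        if any(h < 1 for h in self.hidden):
            raise ConfigError("hidden layer sizes must be >= 1")


class MLPModel:
    """Layer weights and biases; rectifier hidden, sigmoid output."""

    def __init__(self, layer_dims: list[int], weights: list[np.ndarray], biases: list[np.ndarray]):
        self.layer_dims = [int(d) for d in layer_dims]
        self.weights = weights
        self.biases = biases

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "MLPModel":
        return MLPModel(
            list(self.layer_dims),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
        )

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "layer_dims": self.layer_dims,
                "hidden_activation": "relu",
                "output_activation": "sigmoid",
                "weights": [w.tolist() for w in self.weights],
                "biases": [b.tolist() for b in self.biases],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(
            d["layer_dims"],
            [np.asarray(w, dtype=np.float64) for w in d["weights"]],
            [np.asarray(b, dtype=np.float64) for b in d["biases"]],
        )


@dataclass
class MomentumState:
    """Velocity tensors, shape-congruent with the model, zero at step 0."""

    v_weights: list[np.ndarray]
    v_biases: list[np.ndarray]

    @classmethod
    def zeros_like(cls, model: MLPModel) -> "MomentumState":
        return cls(
            [np.zeros_like(w) for w in model.weights],
            [np.zeros_like(b) for b in model.biases],
        )


def init_model(layer_dims: list[int], seed: int = 0) -> MLPModel:
    """Glorot-uniform weights (+-sqrt(6/(fan_in+fan_out))), zero biases."""
    dims = [int(d) for d in layer_dims]
    if len(dims) < 2 or any(d < 1 for d in dims):
        raise ConfigError(f"layer dims must be >= 1 with at least 2 layers, got {dims}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(dims, weights, biases)


def forward(model: MLPModel, X: np.ndarray) -> list[np.ndarray]:
    """All layer activations [X, h_1, ..., output]; output is sigmoid in (0,1)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.layer_dims[0]:
        raise ShapeError(
            f"input width {X.shape} does not match model input dim {model.layer_dims[0]}"
        )
    activations = [X]
    a = X
    last = model.n_layers - 1
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ w + b
        if l == last:
            a = 1.0 / (1.0 + np.exp(-z))  # sigmoid output
        else:
            a = np.maximum(z, 0.0)  # rectifier hidden
        activations.append(a)
    return activations


def bce_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over all units, clipped at 1e-12."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ShapeError(f"prediction shape {p.shape} != target shape {t.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def backprop(
    model: MLPModel, X: np.ndarray, Y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact gradients of ``bce_loss(forward(X)[-1], Y)`` w.r.t. parameters.

    With sigmoid outputs and per-unit BCE the output-layer error simplifies
    to ``(p - t) / (n * out_dim)``; hidden layers propagate through the
    rectifier mask.
    """
    activations = forward(model, X)
    return _backprop_from_activations(model, activations, Y)


def _backprop_from_activations(
    model: MLPModel, activations: list[np.ndarray], Y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    p = activations[-1]
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape != p.shape:
        raise ShapeError(f"target shape {Y.shape} != output shape {p.shape}")
    n, out_dim = p.shape
    delta = (p - Y) / (n * out_dim)
    grad_w: list[np.ndarray] = [np.empty(0)] * model.n_layers
    grad_b: list[np.ndarray] = [np.empty(0)] * model.n_layers
    for l in range(model.n_layers - 1, -1, -1):
        grad_w[l] = activations[l].T @ delta
        grad_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ model.weights[l].T) * (activations[l] > 0)
    return grad_w, grad_b


def momentum_step(
    model: MLPModel,
    state: MomentumState,
    grads: tuple[list[np.ndarray], list[np.ndarray]],
    learning_rate: float,
    momentum: float,
) -> tuple[MLPModel, MomentumState]:
    """One in-place momentum update; returns the mutated (model, state)."""
    grad_w, grad_b = grads
    for l in range(model.n_layers):
        if not (np.isfinite(grad_w[l]).all() and np.isfinite(grad_b[l]).all()):
            raise DivergenceError(f"non-finite gradient in layer {l + 1}")
        state.v_weights[l] = momentum * state.v_weights[l] + (1.0 - momentum) * grad_w[l]
        state.v_biases[l] = momentum * state.v_biases[l] + (1.0 - momentum) * grad_b[l]
        model.weights[l] -= learning_rate * state.v_weights[l]
        model.biases[l] -= learning_rate * state.v_biases[l]
    return model, state


def train(
    X: np.ndarray, Y: np.ndarray, config: TrainConfig
) -> tuple[MLPModel, list[float]]:
    """Mini-batch momentum SGD; returns the model and per-epoch mean loss.

    Batches are re-shuffled each epoch from a seeded stream; the last short
    batch is kept; with fewer rows than the batch size, training is
    full-batch.  ``epochs = 0`` returns the freshly initialized model.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if len(X) != len(Y) or len(X) < 1:
        raise ShapeError(f"need equal, non-zero sample counts; got {len(X)} and {len(Y)}")
    ss = np.random.SeedSequence(config.seed)
    init_seed, shuffle_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    dims = [X.shape[1], *config.hidden, Y.shape[1]]
    model = init_model(dims, seed=init_seed)
    state = MomentumState.zeros_like(model)
    rng = np.random.default_rng(shuffle_seed)
    n = len(X)
    batch = min(config.batch_size, n)
    trace: list[float] = []
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, batch):
            idx = perm[start:start + batch]
            xb, yb = X[idx], Y[idx]
            acts = forward(model, xb)
            loss = bce_loss(acts[-1], yb)
            if not np.isfinite(loss):
                raise DivergenceError("training loss became non-finite")
            grads = _backprop_from_activations(model, acts, yb)
            momentum_step(model, state, grads, config.learning_rate, config.momentum)
            total += loss * len(idx)
            seen += len(idx)
        trace.append(total / seen)
    return model, trace
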
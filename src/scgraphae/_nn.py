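"""Minimal dense neural-network primitives on NumPy.

Full-batch multilayer perceptrons with ReLU hidden units, explicit
backpropagation, and an Adam optimizer. Problem sizes in this package
(hundreds of cells, a few thousand genes, two-layer graph encoders) are
small enough that dense full-batch NumPy training is fast and keeps every
run bit-reproducible from its seed.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam with bias correction over a flat dict of parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLP:
    """Fully connected net; ReLU on all layers except the last (linear)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.dims = list(dims)
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            self.params[f"W{i}"] = glorot(rng, dims[i], dims[i + 1])
            self.params[f"b{i}"] = np.zeros(dims[i + 1])
        self._cache: list[np.ndarray] = []

    @property
    def n_layers(self) -> int:
        return len(self.dims) - 1

    def forward(self, x: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        acts = [x]
        h = x
        for i in range(self.n_layers):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            h = z if i == self.n_layers - 1 else np.maximum(z, 0.0)
            acts.append(h)
        if keep_cache:
            self._cache = acts
        return h

    def backward(self, d_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given dL/d(output); uses last forward cache."""
        acts = self._cache
        grads: dict[str, np.ndarray] = {}
        delta = d_out
        for i in range(self.n_layers - 1, -1, -1):
            if i != self.n_layers - 1:
                delta = delta * (acts[i + 1] > 0)  # ReLU mask
            grads[f"W{i}"] = acts[i].T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.params[f"W{i}"].T
        return grads

    def activation(self, layer_index: int) -> np.ndarray:
        """Post-activation output of a given layer from the last forward pass."""
        return self._cache[layer_index + 1]

    def weight_l1(self) -> float:
        return float(sum(np.abs(v).sum() for k, v in self.params.items() if k.startswith("W")))


def train_autoencoder(
    x: np.ndarray,
    dims_hidden: list[int],
    weight: np.ndarray | float,
    lr: float,
    epochs: int,
    seed: int,
    l1_beta: float = 0.0,
    embed_layer: int | None = None,
) -> tuple[MLP, np.ndarray, np.ndarray, np.ndarray]:
    """Train an MLP autoencoder under element-weighted squared error.

    Loss = Σ weight ∘ (x − x̂)² + l1_beta · Σ|W|. ``dims_hidden`` is the
    bottleneck path, e.g. [512, 128] builds G→512→128→512→G. Returns
    (model, embedding, reconstruction, loss trace). ``embed_layer`` picks
    which layer's activation is the embedding (default: the bottleneck).
    """
    x = np.asarray(x, dtype=float)
    n, g = x.shape
    dims = [g, *dims_hidden, *dims_hidden[-2::-1], g]
    if embed_layer is None:
        embed_layer = len(dims_hidden) - 1
    rng = np.random.default_rng(seed)
    model = MLP(dims, rng)
    opt = Adam(lr=lr)
    w = np.broadcast_to(np.asarray(weight, dtype=float), x.shape)

    def loss_of(xhat: np.ndarray) -> float:
        base = float((w * (x - xhat) ** 2).sum())
        return base + (l1_beta * model.weight_l1() if l1_beta else 0.0)

    xhat = model.forward(x)
    trace = [loss_of(xhat)]
    for _ in range(epochs):
        d_out = -2.0 * w * (x - xhat)
        grads = model.backward(d_out)
        if l1_beta:
            for k in list(grads):
                if k.startswith("W"):
                    grads[k] = grads[k] + l1_beta * np.sign(model.params[k])
        opt.step(model.params, grads)
        xhat = model.forward(x)
        trace.append(loss_of(xhat))
        if not np.isfinite(trace[-1]):
            raise FloatingPointError("autoencoder loss diverged to non-finite value")
    embedding = model.activation(embed_layer)
    return model, embedding, xhat, np.asarray(trace)
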
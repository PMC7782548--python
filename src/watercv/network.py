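"""Minimal feed-forward network in numpy with reverse-mode gradients.

The discriminant CV only needs a compact multilayer perceptron: forward
evaluation of the hidden features h(d), backpropagation of an externally
supplied dL/dh (the Fisher-ratio loss gradient has a closed form in the
features, see :mod:`watercv.deeplda`), and gradients of a scalar projection
with respect to the inputs (for descriptor ranking and for biasing forces).
Weights use He/Xavier-style initialisation from a seeded generator, and a
small hand-rolled Adam optimiser updates them.
"""

from __future__ import annotations

import numpy as np

_ACTIVATIONS = ("elu", "tanh", "linear")


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(z > 0, z, np.expm1(z))
    if kind == "tanh":
        return np.tanh(z)
    if kind == "linear":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def _act_prime(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(z > 0, 1.0, np.exp(z))
    if kind == "tanh":
        t = np.tanh(z)
        return 1.0 - t * t
    if kind == "linear":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {kind!r}")


class MLP:
    """Fully connected net mapping inputs to the last hidden layer h.

    ``sizes`` runs from the input width to the last hidden width, e.g.
    ``[20, 32, 16, 8]``; the same activation follows every affine layer
    (``"linear"`` turns the net into a plain affine map).
    """

    def __init__(self, sizes: list[int], activation: str = "elu", seed: int = 0):
        if len(sizes) < 2:
            raise ValueError("need at least input and one hidden layer width")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        self.sizes = list(sizes)
        self.activation = activation
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(scale=scale, size=(fan_out, fan_in)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_inputs(self) -> int:
        return self.sizes[0]

    @property
    def n_hidden(self) -> int:
        return self.sizes[-1]

    def forward(self, x: np.ndarray, cache: bool = False):
        """h for a batch x of shape (n, n_inputs); optionally keep the
        per-layer pre-activations for a subsequent backward pass."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {x.shape[1]}")
        pre, post = [], [x]
        a = x
        for W, b in zip(self.weights, self.biases):
            z = a @ W.T + b
            a = _act(z, self.activation)
            if cache:
                pre.append(z)
                post.append(a)
        if cache:
            self._cache = (pre, post)
        return a

    def backward(self, dL_dh: np.ndarray):
        """Weight/bias gradients given dL/dh for the cached batch."""
        pre, post = self._cache
        delta = np.atleast_2d(dL_dh)
        grads_W, grads_b = [], []
        for layer in reversed(range(len(self.weights))):
            delta = delta * _act_prime(pre[layer], self.activation)
            grads_W.append(delta.T @ post[layer])
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = delta @ self.weights[layer]
        return grads_W[::-1], grads_b[::-1]

    def input_gradient(self, x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """d(w^T h)/dx for each row of x; shape (n, n_inputs)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self.forward(x, cache=True)
        pre, _ = self._cache
        delta = np.broadcast_to(np.asarray(w, dtype=float), (len(x), self.n_hidden)).copy()
        for layer in reversed(range(len(self.weights))):
            delta = delta * _act_prime(pre[layer], self.activation)
            delta = delta @ self.weights[layer]
        return delta

    def get_params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [np.asarray(p, dtype=float) for p in params[:n]]
        self.biases = [np.asarray(p, dtype=float) for p in params[n:]]


class Adam:
    """Standard Adam updates over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
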
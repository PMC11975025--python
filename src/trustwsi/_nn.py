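"""Minimal NumPy neural-network primitives.

The models in this package are small MLPs and attention-MIL networks over
low-dimensional tile embeddings, so the forward/backward passes are written
directly in NumPy: dense layers with ReLU, inverted dropout, an Adam
optimizer, softmax cross-entropy, and power-iteration spectral normalization
applied as a projection after each optimizer step.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "Adam",
    "Dense",
    "MLP",
    "SpectralState",
    "power_iteration",
    "spectral_normalize",
    "softmax",
    "softmax_xent_grad",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return float(loss), g / n


class SpectralState:
    """Persistent power-iteration state: unit left-singular vector estimate
    ``u`` and the last spectral-norm estimate ``lam``."""

    def __init__(self, u: np.ndarray | None = None):
        self.u = u
        self.lam: float = 0.0


def power_iteration(
    W: np.ndarray, state: SpectralState | None = None, n_iter: int = 50
) -> tuple[float, SpectralState]:
    """Estimate the spectral norm (largest singular value) of ``W``.

    With a persistent ``state`` a single iteration per call suffices during
    training; standalone calls should use the default 50 iterations.
    """
    W = np.asarray(W, dtype=float)
    if state is None:
        state = SpectralState()
    if not np.any(W):
        warnings.warn("spectral norm of a zero matrix is 0", stacklevel=2)
        state.lam = 0.0
        return 0.0, state
    m = W.shape[0]
    u = state.u
    if u is None or u.shape != (m,):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(m)
        u /= np.linalg.norm(u)
    v = None
    for _ in range(max(1, n_iter)):
        v = W.T @ u
        nv = np.linalg.norm(v)
        if nv == 0:  # u happened to lie in the left null space; restart
            u = np.ones(m) / np.sqrt(m)
            v = W.T @ u
            nv = np.linalg.norm(v)
        v /= nv
        u = W @ v
        u /= np.linalg.norm(u)
    lam = float(u @ W @ v)
    state.u = u
    state.lam = lam
    return lam, state


def spectral_normalize(
    W: np.ndarray,
    c: float,
    state: SpectralState | None = None,
    n_iter: int = 50,
) -> tuple[np.ndarray, float]:
    """Spectral normalization: return ``c * W / λ̂`` when ``λ̂ > c``, else ``W``.

    ``λ̂`` is the power-iteration spectral-norm estimate, so the returned
    matrix satisfies ‖W‖₂ ≤ c (up to estimation error).
    """
    if c <= 0:
        raise ValueError("spectral-norm bound c must be positive")
    W = np.asarray(W, dtype=float)
    lam, _ = power_iteration(W, state, n_iter=n_iter)
    if lam > c:
        return c * W / lam, lam
    return W, lam


class Dense:
    """Fully-connected layer ``x @ W.T + b`` with cached input for backprop."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.sn_state = SpectralState()
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW = g.T @ self._x
        self.db = g.sum(axis=0)
        return g @ self.W

    def project_spectral(self, c: float, n_iter: int = 1) -> None:
        """Clip the layer's spectral norm to ``c`` in place (one persistent
        power iteration per training step).

        In place so that optimizer references to ``W`` stay valid."""
        Wn, _ = spectral_normalize(self.W, c, self.sn_state, n_iter=n_iter)
        if Wn is not self.W:
            self.W[...] = Wn

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def set_params(self, params):
        self.W, self.b = params[0].copy(), params[1].copy()


class MLP:
    """ReLU feature extractor with optional inverted dropout.

    With ``residual=True`` (the distance-preserving configuration) the first
    layer maps the input to a fixed width and every further layer is a
    residual block ``h <- h + relu(Dense(h))``; bounding each block's
    spectral norm then keeps the whole map approximately bi-Lipschitz, which
    a plain feedforward stack cannot guarantee.  ``residual=False`` gives the
    ordinary feedforward MLP (used by the MC-dropout baseline).

    ``forward`` caches intermediates; ``backward`` fills per-layer gradients
    and returns the gradient w.r.t. the input.
    """

    def __init__(
        self,
        n_in: int,
        hidden_sizes: tuple[int, ...],
        rng: np.random.Generator,
        dropout: float = 0.0,
        residual: bool = False,
    ):
        if residual and len(set(hidden_sizes)) > 1:
            raise ValueError("residual blocks require equal hidden sizes")
        self.layers: list[Dense] = []
        self.dropout = dropout
        self.residual = residual
        d = n_in
        for h in hidden_sizes:
            self.layers.append(Dense(d, h, rng))
            d = h
        self.out_dim = d
        self._caches: list[tuple] = []
        self.n_forward_calls = 0

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        self.n_forward_calls += 1
        self._caches = []
        h = x
        drop = self.dropout if (train or rng is not None) else 0.0
        for li, layer in enumerate(self.layers):
            z = layer.forward(h)
            relu_mask = z > 0
            a = z * relu_mask
            skip = self.residual and li > 0
            h = h + a if skip else a
            if drop > 0.0:
                if rng is None:
                    raise ValueError("dropout requires an rng")
                keep = rng.random(h.shape) >= drop
                h = h * keep / (1.0 - drop)
                self._caches.append((relu_mask, keep, skip))
            else:
                self._caches.append((relu_mask, None, skip))
        return h

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer, (relu_mask, keep, skip) in zip(
            reversed(self.layers), reversed(self._caches)
        ):
            if keep is not None:
                g = g * keep / (1.0 - self.dropout)
            gb = layer.backward(g * relu_mask)
            g = g + gb if skip else gb
        return g

    def project_spectral(self, c: float, n_iter: int = 1) -> None:
        for layer in self.layers:
            layer.project_spectral(c, n_iter=n_iter)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def get_state(self):
        return [p.copy() for p in self.params()]

    def set_state(self, state):
        for layer, i in zip(self.layers, range(0, len(state), 2)):
            layer.set_params(state[i : i + 2])

    def spectral_norms(self) -> list[float]:
        return [power_iteration(layer.W, n_iter=100)[0] for layer in self.layers]


class Adam:
    """Adam over a fixed list of parameter arrays, updated in place."""

    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
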
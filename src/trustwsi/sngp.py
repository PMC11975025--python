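"""Spectral-normalized neural Gaussian process (SNGP) tile classifier.

A regular deep classifier gives no usable notion of "how far is this input
from everything I was trained on".  SNGP restores that notion with two
modifications:

1. **Spectral normalization** of every dense layer bounds each layer's
   spectral norm by ``c``; combined with residual blocks in the extractor
   this keeps h(·) approximately bi-Lipschitz, so latent distances reflect
   input distances and out-of-distribution points cannot collapse onto the
   training manifold.

2. **A Gaussian-process output layer**, approximated with random Fourier
   features: Φ(h) = √(2/D) · cos(−W_L h + b_L) with W_L ~ N(0,1) and
   b_L ~ U(0, 2π) fixed at construction, so that Φ(h_i)·Φ(h_j) ≈
   exp(−‖h_i−h_j‖²/2), the RBF kernel.  The only learnable output
   parameters are the coefficients β (a Bayesian linear model), whose MAP
   estimate is found under a standard-normal prior.  For a query Φ*, the
   logit mean is μ_k = Φ*ᵀβ̂_k and the predictive uncertainty is the ridge
   form τ·Φ*ᵀ(ΦᵀΦ + τI)⁻¹Φ*: ≈1 far from training data, small near it,
   available in a single forward pass.

Class probabilities integrate the softmax over the Gaussian logit
distribution (Monte-Carlo by default, mean-field as a fast mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import optimize

from trustwsi._nn import (
    MLP,
    Adam,
    Dense,
    SpectralState,
    power_iteration,
    softmax,
    softmax_xent_grad,
    spectral_normalize,
)
from trustwsi.synthetic import TileTable

__all__ = [
    "DegenerateFitError",
    "PredictiveOutput",
    "RFFHead",
    "SNGPConfig",
    "SNGPModel",
    "DropoutModel",
    "fit_head",
    "mc_dropout_predict",
    "predict",
    "rff_features",
    "spectral_normalize",
    "power_iteration",
    "SpectralState",
    "train_tile_classifier",
    "train_dropout_classifier",
]


class DegenerateFitError(ValueError):
    """Raised when the training labels contain a single class."""


@dataclass(frozen=True)
class SNGPConfig:
    """Hyperparameters of the SNGP tile classifier.

    ``c`` is the spectral-norm bound on hidden layers; ``D_L`` the
    random-feature dimension; ``tau`` the ridge factor of the GP posterior;
    ``n_mc_softmax`` the number of Gaussian logit samples used to average
    the softmax (0 selects the mean-field approximation).  Defaults c=1,
    D_L=1024, tau=1 follow common SNGP practice and keep the precision
    matrix well conditioned.
    """

    c: float = 1.0
    n_power_iter: int = 1
    D_L: int = 1024
    tau: float = 1.0
    n_mc_softmax: int = 100
    hidden_sizes: tuple[int, ...] = (64, 64, 64)
    dropout: float = 0.0
    spectral_norm: bool = True
    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 128
    val_fraction: float = 0.15
    seed: int = 0
    # attention-MIL (bag-level) settings
    abmil_hidden: tuple[int, int] = (512, 384)
    attn_dim: int = 256
    dropout_input: float = 0.1
    dropout_hidden: float = 0.25
    abmil_epochs: int = 20
    abmil_lr: float = 1e-4
    # MC-dropout baseline
    n_mc_passes: int = 5

    def __post_init__(self):
        if self.c <= 0 or self.D_L < 1 or self.tau <= 0:
            raise ValueError("require c > 0, D_L >= 1, tau > 0")


class RFFHead:
    """Random-Fourier-feature GP output layer.

    The projection (``W_L``, ``b_L``) is drawn once at construction and never
    updated.  ``beta`` holds the MAP coefficients after fitting and
    ``precision`` the accumulated ΦᵀΦ + τI.
    """

    def __init__(
        self,
        feature_dim: int,
        D_L: int = 1024,
        K: int = 2,
        tau: float = 1.0,
        rng: np.random.Generator | None = None,
    ):
        if D_L < 1 or tau <= 0:
            raise ValueError("require D_L >= 1 and tau > 0")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.feature_dim = feature_dim
        self.D_L = D_L
        self.K = K
        self.tau = float(tau)
        self.W_L = rng.standard_normal((D_L, feature_dim))
        self.W_L.flags.writeable = False
        self.b_L = rng.uniform(0.0, 2.0 * np.pi, size=D_L)
        self.b_L.flags.writeable = False
        self.beta = np.zeros((D_L, K))
        self.precision = self.tau * np.eye(D_L)
        self._cho = sla.cho_factor(self.precision, lower=True)
        self.fitted = False

    def features(self, h: np.ndarray) -> np.ndarray:
        """Φ(h) = √(2/D_L) · cos(−h W_Lᵀ + b_L)."""
        h = np.atleast_2d(np.asarray(h, dtype=float))
        if h.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature dimension mismatch: expected {self.feature_dim}, got {h.shape[1]}"
            )
        return np.sqrt(2.0 / self.D_L) * np.cos(-(h @ self.W_L.T) + self.b_L)

    def set_posterior(self, beta: np.ndarray, precision: np.ndarray) -> None:
        try:
            cho = sla.cho_factor(precision, lower=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover - diagnostic path
            raise np.linalg.LinAlgError(
                "precision matrix is not positive definite; check tau and the "
                "accumulated features"
            ) from e
        self.beta = beta
        self.precision = precision
        self._cho = cho
        self.fitted = True


def rff_features(h: np.ndarray, head: RFFHead) -> np.ndarray:
    """Random Fourier features of latent vectors ``h`` under ``head``."""
    return head.features(h)


@dataclass
class PredictiveOutput:
    """Per-unit GP outputs: logit means ``mu``, shared per-logit variance
    ``var``, integrated class probabilities ``probs`` and the ridge-form
    ``uncertainty`` (equal to ``var``; ≈1 far from the training cloud)."""

    mu: np.ndarray
    var: np.ndarray
    probs: np.ndarray
    uncertainty: np.ndarray

    @property
    def sigma2(self) -> np.ndarray:
        """Predictive variance broadcast per class (shared across logits)."""
        return np.repeat(self.var[:, None], self.mu.shape[1], axis=1)


def _map_objective(beta_flat, Phi, Y, K):
    D = Phi.shape[1]
    beta = beta_flat.reshape(D, K)
    logits = Phi @ beta
    logits -= logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(logits).sum(axis=1))
    ll = (logits * Y).sum() - logZ.sum()
    loss = -ll + 0.5 * (beta**2).sum()
    P = softmax(logits)
    grad = Phi.T @ (P - Y) + beta
    return loss, grad.ravel()


def fit_head(
    Phi_train: np.ndarray,
    labels: np.ndarray,
    tau: float = 1.0,
    head: RFFHead | None = None,
    max_iter: int = 500,
) -> RFFHead:
    """MAP-fit the GP output layer on precomputed random features.

    Minimizes cross-entropy with a standard-normal prior on β (i.e. weight
    decay 1 on the summed loss) by L-BFGS, and accumulates the exact
    precision ΦᵀΦ + τI over the training rows.  With zero training rows the
    precision is the prior τI.
    """
    Phi = np.atleast_2d(np.asarray(Phi_train, dtype=float))
    labels = np.asarray(labels, dtype=int)
    D = Phi.shape[1]
    if head is None:
        head = RFFHead(feature_dim=D, D_L=D, K=max(2, len(np.unique(labels)) or 2), tau=tau)
        # features were supplied directly; disable the internal projection
        head.features = lambda h: np.atleast_2d(np.asarray(h, dtype=float))  # type: ignore
    K = head.K
    if len(labels):
        classes = np.unique(labels)
        if len(classes) < 2:
            raise DegenerateFitError("training labels contain a single class")
        Y = np.zeros((len(labels), K))
        Y[np.arange(len(labels)), labels] = 1.0
        res = optimize.minimize(
            _map_objective,
            head.beta.ravel(),
            args=(Phi, Y, K),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter},
        )
        beta = res.x.reshape(D, K)
    else:
        beta = np.zeros((D, K))
    precision = Phi.T @ Phi + head.tau * np.eye(D)
    head.set_posterior(beta, precision)
    return head


def predict(
    head: RFFHead,
    Phi_star: np.ndarray,
    n_mc_softmax: int = 100,
    rng: np.random.Generator | None = None,
) -> PredictiveOutput:
    """GP prediction for query features Φ*.

    μ = Φ*ᵀβ̂; predictive variance σ² = τ·Φ*ᵀ(ΦᵀΦ + τI)⁻¹Φ* (shared across
    logits); probabilities are the softmax averaged over ``n_mc_softmax``
    Gaussian logit draws, or the mean-field approximation
    softmax(μ/√(1 + π/8·σ²)) when ``n_mc_softmax`` is 0.
    """
    Phi = np.atleast_2d(np.asarray(Phi_star, dtype=float))
    mu = Phi @ head.beta
    sol = sla.cho_solve(head._cho, Phi.T)
    var = head.tau * np.einsum("ij,ji->i", Phi, sol)
    var = np.clip(var, 0.0, None)
    if n_mc_softmax <= 0:
        adj = mu / np.sqrt(1.0 + (np.pi / 8.0) * var[:, None])
        probs = softmax(adj)
    else:
        rng = rng if rng is not None else np.random.default_rng(0)
        sd = np.sqrt(var)[:, None]
        probs = np.zeros_like(mu)
        chunk = max(1, int(2_000_000 / (max(1, len(mu)) * mu.shape[1])))
        done = 0
        while done < n_mc_softmax:
            m = min(chunk, n_mc_softmax - done)
            z = rng.standard_normal((m,) + mu.shape)
            probs += softmax(mu[None] + sd[None] * z).sum(axis=0)
            done += m
        probs /= n_mc_softmax
    return PredictiveOutput(mu=mu, var=var, probs=probs, uncertainty=var.copy())


class SNGPModel:
    """Trained SNGP tile classifier: spectral-normalized MLP extractor plus
    a fitted RFF-GP head.  ``predict`` needs exactly one extractor forward
    pass per batch of tiles."""

    def __init__(self, extractor: MLP, head: RFFHead, config: SNGPConfig):
        self.extractor = extractor
        self.head = head
        self.config = config

    def latent(self, X: np.ndarray) -> np.ndarray:
        return self.extractor.forward(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray, n_mc_softmax: int | None = None) -> PredictiveOutput:
        n_mc = self.config.n_mc_softmax if n_mc_softmax is None else n_mc_softmax
        Phi = self.head.features(self.latent(X))
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 2**16]))
        return predict(self.head, Phi, n_mc_softmax=n_mc, rng=rng)


def _patient_split(tiles: TileTable, val_fraction: float, rng: np.random.Generator):
    patients = tiles.patients()
    if val_fraction <= 0.0:
        raise ValueError("a validation split is required (val_fraction > 0)")
    order = rng.permutation(len(patients))
    n_val = max(1, int(round(val_fraction * len(patients))))
    val_p = set(patients[order[:n_val]])
    val_mask = tiles.manifest["patient_id"].isin(val_p).to_numpy()
    return ~val_mask, val_mask


def train_tile_classifier(tiles: TileTable, config: SNGPConfig) -> SNGPModel:
    """Train the SNGP tile classifier on a cohort of weakly labelled tiles.

    The MLP extractor and the GP coefficients β are optimized jointly by
    Adam on cross-entropy (β under its standard-normal prior); every hidden
    layer is re-projected to spectral norm ≤ c after each step.  The state
    with the best validation accuracy (patient-level split) is retained;
    finally β is re-solved to its exact MAP on the frozen features and the
    precision ΦᵀΦ + τI accumulated over the training tiles.
    """
    y = tiles.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("need at least two classes to train")
    ss = np.random.SeedSequence([config.seed, 11])
    rng_init, rng_split, rng_batch = (np.random.default_rng(s) for s in ss.spawn(3))

    train_mask, val_mask = _patient_split(tiles, config.val_fraction, rng_split)
    X = np.asarray(tiles.embeddings, dtype=float)
    Xtr, ytr = X[train_mask], y[train_mask]
    Xva, yva = X[val_mask], y[val_mask]
    n_train = len(Xtr)
    K = int(y.max()) + 1

    mlp = MLP(X.shape[1], config.hidden_sizes, rng_init, dropout=config.dropout, residual=True)
    head = RFFHead(mlp.out_dim, D_L=config.D_L, K=K, tau=config.tau, rng=rng_init)
    s = np.sqrt(2.0 / config.D_L)

    params = mlp.params() + [head.beta]
    opt = Adam(params, lr=config.lr)
    if config.spectral_norm:
        mlp.project_spectral(config.c, n_iter=50)

    best = (-np.inf, mlp.get_state(), head.beta.copy())
    for epoch in range(config.epochs):
        order = rng_batch.permutation(n_train)
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            H = mlp.forward(Xtr[idx], train=True, rng=rng_batch if config.dropout > 0 else None)
            z = -(H @ head.W_L.T) + head.b_L
            Phi = s * np.cos(z)
            logits = Phi @ head.beta
            _, glog = softmax_xent_grad(logits, ytr[idx])
            gbeta = Phi.T @ glog + head.beta / n_train
            gPhi = glog @ head.beta.T
            gz = -s * np.sin(z) * gPhi
            gH = -(gz @ head.W_L)
            mlp.backward(gH)
            opt.step(mlp.grads() + [gbeta])
            if config.spectral_norm:
                mlp.project_spectral(config.c, n_iter=config.n_power_iter)
        Hva = mlp.forward(Xva)
        acc = float((np.argmax(head.features(Hva) @ head.beta, axis=1) == yva).mean())
        if acc > best[0]:
            best = (acc, mlp.get_state(), head.beta.copy())

    mlp.set_state(best[1])
    head.beta = best[2]
    Phi_train = head.features(mlp.forward(Xtr))
    fit_head(Phi_train, ytr, tau=config.tau, head=head)
    model = SNGPModel(extractor=mlp, head=head, config=config)
    model.val_accuracy = best[0]
    return model


class DropoutModel:
    """MLP classifier with a dense softmax output and stochastic dropout,
    the MC-dropout uncertainty baseline."""

    def __init__(self, extractor: MLP, out: Dense, config: SNGPConfig):
        self.extractor = extractor
        self.out = out
        self.config = config

    def forward_probs(self, X, train=False, rng=None):
        H = self.extractor.forward(np.asarray(X, dtype=float), train=train, rng=rng)
        return softmax(self.out.forward(H))


def train_dropout_classifier(tiles: TileTable, config: SNGPConfig) -> DropoutModel:
    """Train the MC-dropout baseline (no GP head; dropout stays active at
    inference for uncertainty)."""
    y = tiles.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("need at least two classes to train")
    ss = np.random.SeedSequence([config.seed, 13])
    rng_init, rng_split, rng_batch = (np.random.default_rng(s) for s in ss.spawn(3))
    train_mask, val_mask = _patient_split(tiles, config.val_fraction, rng_split)
    X = np.asarray(tiles.embeddings, dtype=float)
    Xtr, ytr = X[train_mask], y[train_mask]
    Xva, yva = X[val_mask], y[val_mask]
    K = int(y.max()) + 1

    mlp = MLP(X.shape[1], config.hidden_sizes, rng_init, dropout=config.dropout)
    out = Dense(mlp.out_dim, K, rng_init)
    params = mlp.params() + out.params()
    opt = Adam(params, lr=config.lr)
    best = (-np.inf, mlp.get_state(), [p.copy() for p in out.params()])
    for epoch in range(config.epochs):
        order = rng_batch.permutation(len(Xtr))
        for start in range(0, len(Xtr), config.batch_size):
            idx = order[start : start + config.batch_size]
            H = mlp.forward(Xtr[idx], train=True, rng=rng_batch if config.dropout > 0 else None)
            logits = out.forward(H)
            _, glog = softmax_xent_grad(logits, ytr[idx])
            gH = out.backward(glog)
            mlp.backward(gH)
            opt.step(mlp.grads() + out.grads())
        Hva = mlp.forward(Xva)
        acc = float((np.argmax(out.forward(Hva), axis=1) == yva).mean())
        if acc > best[0]:
            best = (acc, mlp.get_state(), [p.copy() for p in out.params()])
    mlp.set_state(best[1])
    out.set_params(best[2])
    model = DropoutModel(mlp, out, config)
    model.val_accuracy = best[0]
    return model


def mc_dropout_predict(
    model: DropoutModel,
    X: np.ndarray,
    n_passes: int = 5,
    rng: np.random.Generator | None = None,
) -> PredictiveOutput:
    """MC-dropout prediction: mean class probabilities over ``n_passes``
    stochastic forward passes; uncertainty is the across-pass standard
    deviation of the predicted probability."""
    if n_passes < 2:
        raise ValueError("n_passes must be >= 2 for a standard deviation")
    rng = rng if rng is not None else np.random.default_rng(0)
    use_rng = rng if model.extractor.dropout > 0 else None
    all_probs = np.stack(
        [model.forward_probs(X, train=True, rng=use_rng) for _ in range(n_passes)]
    )
    probs = all_probs.mean(axis=0)
    std = all_probs.std(axis=0, ddof=0)
    uncertainty = std[:, 1] if probs.shape[1] == 2 else std.mean(axis=1)
    mu = np.log(np.clip(probs, 1e-12, None))
    return PredictiveOutput(mu=mu, var=uncertainty**2, probs=probs, uncertainty=uncertainty)
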
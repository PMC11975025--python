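"""Attention-based multiple-instance learning (ABMIL) with a GP output.

For foundation-model-style pipelines the slide is classified directly from
its bag of tile embeddings: each tile is transformed by two spectral-
normalized dense layers (512 then 384 units, ReLU), an attention network
scores every tile, and the attention-weighted sum of tile features forms the
bag representation fed to the random-Fourier-feature GP head.  Dropout is
applied to the input features (rate 0.1) and after each intermediate layer
(rate 0.25); training runs for at most 20 epochs of Adam with a cosine
learning-rate schedule starting at 1e-4.

The attention weights (softmax over the slide's tiles) are returned per bag
and sum to one; they are the model's interpretability layer.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from trustwsi._nn import Adam, SpectralState, softmax, softmax_xent_grad, spectral_normalize
from trustwsi.sngp import PredictiveOutput, RFFHead, SNGPConfig, fit_head, predict
from trustwsi.synthetic import TileTable

__all__ = ["ABMILModel", "train_abmil_classifier"]


class _ABMILNet:
    """Tile transform + gated-free attention pooling, NumPy backprop."""

    def __init__(self, n_in: int, hidden: tuple[int, int], attn_dim: int, rng):
        h1, h2 = hidden
        self.W1 = rng.standard_normal((h1, n_in)) * np.sqrt(2.0 / n_in)
        self.b1 = np.zeros(h1)
        self.W2 = rng.standard_normal((h2, h1)) * np.sqrt(2.0 / h1)
        self.b2 = np.zeros(h2)
        self.V = rng.standard_normal((attn_dim, h2)) * np.sqrt(2.0 / h2)
        self.bv = np.zeros(attn_dim)
        self.w = rng.standard_normal(attn_dim) * np.sqrt(1.0 / attn_dim)
        self.out_dim = h2
        self._sn = {name: SpectralState() for name in ("W1", "W2", "V")}
        self._cache = None

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2, self.V, self.bv, self.w]

    def forward(self, X, train=False, rng=None, p_in=0.0, p_hid=0.0):
        """One bag (n_tiles, d) -> (bag representation, attention weights)."""
        masks = []
        x0 = X
        if train and p_in > 0:
            m = rng.random(X.shape) >= p_in
            x0 = X * m / (1 - p_in)
            masks.append(m)
        else:
            masks.append(None)
        z1 = x0 @ self.W1.T + self.b1
        r1 = z1 > 0
        h1 = z1 * r1
        if train and p_hid > 0:
            m = rng.random(h1.shape) >= p_hid
            h1 = h1 * m / (1 - p_hid)
            masks.append(m)
        else:
            masks.append(None)
        z2 = h1 @ self.W2.T + self.b2
        r2 = z2 > 0
        h2 = z2 * r2
        if train and p_hid > 0:
            m = rng.random(h2.shape) >= p_hid
            h2 = h2 * m / (1 - p_hid)
            masks.append(m)
        else:
            masks.append(None)
        e = np.tanh(h2 @ self.V.T + self.bv)
        s = e @ self.w
        a = softmax(s[None, :])[0]
        zbag = a @ h2
        self._cache = (X, x0, r1, h1, r2, h2, e, a, masks)
        return zbag, a

    def backward(self, gz, p_in=0.0, p_hid=0.0):
        """Gradient of the loss w.r.t. all parameters given d loss / d bag-rep."""
        X, x0, r1, h1, r2, h2, e, a, masks = self._cache
        ga = h2 @ gz
        gh2 = a[:, None] * gz[None, :]
        gs = a * (ga - a @ ga)
        ge = gs[:, None] * self.w[None, :]
        gw = e.T @ gs
        gze = ge * (1.0 - e**2)
        gV = gze.T @ h2
        gbv = gze.sum(axis=0)
        gh2 = gh2 + gze @ self.V
        if masks[2] is not None:
            gh2 = gh2 * masks[2] / (1 - p_hid)
        gz2 = gh2 * r2
        gW2 = gz2.T @ h1
        gb2 = gz2.sum(axis=0)
        gh1 = gz2 @ self.W2
        if masks[1] is not None:
            gh1 = gh1 * masks[1] / (1 - p_hid)
        gz1 = gh1 * r1
        gW1 = gz1.T @ x0
        gb1 = gz1.sum(axis=0)
        return [gW1, gb1, gW2, gb2, gV, gbv, gw]

    def project_spectral(self, c: float, n_iter: int = 1):
        for name in ("W1", "W2", "V"):
            W = getattr(self, name)
            Wn, _ = spectral_normalize(W, c, self._sn[name], n_iter=n_iter)
            if Wn is not W:
                W[...] = Wn

    def get_state(self):
        return [p.copy() for p in self.params()]

    def set_state(self, state):
        for p, s in zip(self.params(), state):
            p[...] = s


class ABMILModel:
    """Trained bag-level classifier: attention pooling plus RFF-GP head."""

    def __init__(self, net: _ABMILNet, head: RFFHead, config: SNGPConfig):
        self.net = net
        self.head = head
        self.config = config

    def bag_representation(self, X: np.ndarray):
        return self.net.forward(np.asarray(X, dtype=float))

    def predict_bags(self, bags) -> tuple[list, PredictiveOutput, dict]:
        """Predict a sequence of ``(bag_id, embeddings, label)`` bags.

        Returns bag ids, a ``PredictiveOutput`` over bags, and the per-bag
        attention weights (each summing to 1).  Empty bags are skipped with
        a warning.
        """
        ids, reps, attn = [], [], {}
        for bag_id, X, _ in bags:
            if len(X) == 0:
                warnings.warn(f"bag {bag_id!r} is empty; skipped", stacklevel=2)
                continue
            z, a = self.bag_representation(X)
            ids.append(bag_id)
            reps.append(z)
            attn[bag_id] = a
        Phi = self.head.features(np.asarray(reps))
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 2**17]))
        out = predict(self.head, Phi, n_mc_softmax=self.config.n_mc_softmax, rng=rng)
        return ids, out, attn

    def predict_tiles(self, tiles: TileTable):
        return self.predict_bags(tiles.bags())


def train_abmil_classifier(tiles: TileTable, config: SNGPConfig) -> ABMILModel:
    """Train the spectral-normalized ABMIL classifier on slide bags.

    Bags are the slides of ``tiles`` with their weak labels; a patient-level
    validation split selects the best epoch.  After training, the GP head's
    β is re-solved to its MAP on the frozen bag representations and the
    precision accumulated over training bags.
    """
    bags = [(sid, X, y) for sid, X, y in tiles.bags()]
    bags = [b for b in bags if len(b[1]) > 0]
    if not bags:
        raise ValueError("no nonempty bags to train on")
    labels = np.array([y for _, _, y in bags])
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes among bag labels")

    ss = np.random.SeedSequence([config.seed, 17])
    rng_init, rng_split, rng_batch = (np.random.default_rng(s) for s in ss.spawn(3))

    slide_patient = tiles.manifest.groupby("slide_id", sort=False)["patient_id"].first()
    patients = slide_patient.unique()
    if config.val_fraction <= 0:
        raise ValueError("a validation split is required (val_fraction > 0)")
    order = rng_split.permutation(len(patients))
    n_val = max(1, int(round(config.val_fraction * len(patients))))
    val_p = set(patients[order[:n_val]])
    is_val = np.array([slide_patient[sid] in val_p for sid, _, _ in bags])
    train_idx = np.flatnonzero(~is_val)
    val_idx = np.flatnonzero(is_val)

    d = tiles.embeddings.shape[1]
    K = int(labels.max()) + 1
    net = _ABMILNet(d, config.abmil_hidden, config.attn_dim, rng_init)
    head = RFFHead(net.out_dim, D_L=config.D_L, K=K, tau=config.tau, rng=rng_init)
    s = np.sqrt(2.0 / config.D_L)
    opt = Adam(net.params() + [head.beta], lr=config.abmil_lr)
    net.project_spectral(config.c, n_iter=50)

    def val_accuracy():
        if len(val_idx) == 0:
            return 0.0
        correct = 0
        for i in val_idx:
            z, _ = net.forward(np.asarray(bags[i][1], dtype=float))
            mu = head.features(z[None]) @ head.beta
            correct += int(mu.argmax() == labels[i])
        return correct / len(val_idx)

    n_train = len(train_idx)
    best = (-np.inf, net.get_state(), head.beta.copy())
    for epoch in range(config.abmil_epochs):
        lr = config.abmil_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / config.abmil_epochs))
        for i in rng_batch.permutation(train_idx):
            X = np.asarray(bags[i][1], dtype=float)
            z, _ = net.forward(
                X,
                train=True,
                rng=rng_batch,
                p_in=config.dropout_input,
                p_hid=config.dropout_hidden,
            )
            zz = -(z[None] @ head.W_L.T) + head.b_L
            Phi = s * np.cos(zz)
            logits = Phi @ head.beta
            _, glog = softmax_xent_grad(logits, labels[i : i + 1])
            gbeta = Phi.T @ glog + head.beta / n_train
            gPhi = glog @ head.beta.T
            gzz = -s * np.sin(zz) * gPhi
            gzbag = -(gzz @ head.W_L)[0]
            grads = net.backward(gzbag, p_in=config.dropout_input, p_hid=config.dropout_hidden)
            opt.step(grads + [gbeta], lr=lr)
            net.project_spectral(config.c, n_iter=config.n_power_iter)
        acc = val_accuracy()
        if acc > best[0]:
            best = (acc, net.get_state(), head.beta.copy())

    net.set_state(best[1])
    head.beta = best[2]
    reps = np.asarray(
        [net.forward(np.asarray(bags[i][1], dtype=float))[0] for i in train_idx]
    )
    fit_head(head.features(reps), labels[train_idx], tau=config.tau, head=head)
    model = ABMILModel(net, head, config)
    model.val_accuracy = best[0]
    return model
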
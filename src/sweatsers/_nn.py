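"""Dense-network numerics for the semi-supervised autoencoder.

Minimal NumPy feed-forward machinery: a symmetric encoder/decoder pair of
fully connected ReLU layers with a linear latent layer and sigmoid
reconstruction output, plus per-analyte logistic prediction heads on the
latent code. Provides forward evaluation, analytic gradients of the
combined reconstruction + prediction objective (verified against finite
differences in the test suite), encoder input-gradients for attribution,
and an Adam optimizer with L2-style weight decay folded into the gradient.
"""

from __future__ import annotations

import numpy as np


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AENet:
    """Parameter container + forward/backward passes.

    Layers
    ------
    encoder : ``n_hidden`` ReLU layers of ``width`` units, then a linear
        map to ``latent_dim``.
    decoder : mirror image — ``n_hidden`` ReLU layers from the latent code,
        then a sigmoid output layer back to ``input_dim``.
    head : one logistic unit per output analyte on the latent code.
    """

    def __init__(
        self,
        input_dim: int,
        width: int,
        n_hidden: int,
        latent_dim: int,
        n_outputs: int,
        rng: np.random.Generator,
    ):
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        self.n_outputs = n_outputs

        def he(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))

        enc_dims = [input_dim] + [width] * n_hidden + [latent_dim]
        dec_dims = [latent_dim] + [width] * n_hidden + [input_dim]
        self.enc_W = [
            he(a, b) if i < n_hidden else glorot(a, b)
            for i, (a, b) in enumerate(zip(enc_dims[:-1], enc_dims[1:]))
        ]
        self.enc_b = [np.zeros(b) for b in enc_dims[1:]]
        self.dec_W = [
            he(a, b) if i < n_hidden else glorot(a, b)
            for i, (a, b) in enumerate(zip(dec_dims[:-1], dec_dims[1:]))
        ]
        self.dec_b = [np.zeros(b) for b in dec_dims[1:]]
        self.head_W = glorot(latent_dim, n_outputs)
        self.head_b = np.zeros(n_outputs)

    # ------------------------------------------------------------------
    # parameter flattening (optimizer state, checkpoints)
    # ------------------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return (
            self.enc_W + self.enc_b + self.dec_W + self.dec_b
            + [self.head_W, self.head_b]
        )

    def set_parameters(self, params: list[np.ndarray]) -> None:
        ne = len(self.enc_W)
        nd = len(self.dec_W)
        it = iter(params)
        self.enc_W = [next(it).copy() for _ in range(ne)]
        self.enc_b = [next(it).copy() for _ in range(ne)]
        self.dec_W = [next(it).copy() for _ in range(nd)]
        self.dec_b = [next(it).copy() for _ in range(nd)]
        self.head_W = next(it).copy()
        self.head_b = next(it).copy()

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    # ------------------------------------------------------------------
    # forward passes
    # ------------------------------------------------------------------
    def encode(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = X
        for i, (W, b) in enumerate(zip(self.enc_W, self.enc_b)):
            pre = a @ W + b
            last = i == len(self.enc_W) - 1
            out = pre if last else _relu(pre)
            if cache is not None:
                cache.append((a, pre))
            a = out
        return a  # latent z

    def decode(self, Z: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = Z
        for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
            pre = a @ W + b
            last = i == len(self.dec_W) - 1
            out = _sigmoid(pre) if last else _relu(pre)
            if cache is not None:
                cache.append((a, pre))
            a = out
        return a  # x-hat

    def head(self, Z: np.ndarray) -> np.ndarray:
        return _sigmoid(Z @ self.head_W + self.head_b)

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        Z = self.encode(X)
        return Z, self.decode(Z), self.head(Z)

    # ------------------------------------------------------------------
    # losses and gradients
    # ------------------------------------------------------------------
    def losses(
        self, X: np.ndarray, Y: np.ndarray, lam: float
    ) -> tuple[float, float, float]:
        """(reconstruction MSE, prediction MSE, total = recon + lam*pred)."""
        _, Xhat, Yhat = self.forward(X)
        recon = float(np.mean((Xhat - X) ** 2))
        pred = float(np.mean((Yhat - Y) ** 2))
        return recon, pred, recon + lam * pred

    def loss_and_grads(
        self, X: np.ndarray, Y: np.ndarray, lam: float
    ) -> tuple[tuple[float, float, float], list[np.ndarray]]:
        """Losses plus gradients of the total loss, ordered as
        :meth:`parameters`."""
        B = X.shape[0]
        enc_cache: list = []
        dec_cache: list = []
        Z = self.encode(X, enc_cache)
        Xhat = self.decode(Z, dec_cache)
        head_pre = Z @ self.head_W + self.head_b
        Yhat = _sigmoid(head_pre)

        recon = float(np.mean((Xhat - X) ** 2))
        pred = float(np.mean((Yhat - Y) ** 2))
        total = recon + lam * pred

        # --- decoder backward (reconstruction term) ---
        d_out = 2.0 * (Xhat - X) / (B * self.input_dim)
        d_pre = d_out * Xhat * (1.0 - Xhat)  # sigmoid output layer
        dec_gW = [None] * len(self.dec_W)
        dec_gb = [None] * len(self.dec_b)
        for i in range(len(self.dec_W) - 1, -1, -1):
            a_prev, pre = dec_cache[i]
            dec_gW[i] = a_prev.T @ d_pre
            dec_gb[i] = d_pre.sum(axis=0)
            d_prev = d_pre @ self.dec_W[i].T
            if i > 0:
                d_pre = d_prev * (dec_cache[i][0] > 0)  # a_prev = relu(pre_{i-1})
        dZ = d_prev  # gradient into latent from decoder

        # --- head backward (prediction term) ---
        d_yhat = 2.0 * lam * (Yhat - Y) / (B * max(self.n_outputs, 1))
        d_hpre = d_yhat * Yhat * (1.0 - Yhat)
        head_gW = Z.T @ d_hpre
        head_gb = d_hpre.sum(axis=0)
        dZ = dZ + d_hpre @ self.head_W.T

        # --- encoder backward ---
        enc_gW = [None] * len(self.enc_W)
        enc_gb = [None] * len(self.enc_b)
        d_pre = dZ  # latent layer is linear
        for i in range(len(self.enc_W) - 1, -1, -1):
            a_prev, pre = enc_cache[i]
            enc_gW[i] = a_prev.T @ d_pre
            enc_gb[i] = d_pre.sum(axis=0)
            if i > 0:
                d_prev = d_pre @ self.enc_W[i].T
                d_pre = d_prev * (enc_cache[i - 1][1] > 0)

        grads = enc_gW + enc_gb + dec_gW + dec_gb + [head_gW, head_gb]
        return (recon, pred, total), grads

    # ------------------------------------------------------------------
    # input gradients (attribution)
    # ------------------------------------------------------------------
    def input_gradient(self, X: np.ndarray, target: tuple[str, int]) -> np.ndarray:
        """d(target output)/d(input), row-wise, via encoder backprop.

        ``target`` is ``("latent", k)`` for latent coordinate k or
        ``("head", m)`` for the m-th analyte head output.
        """
        kind, idx = target
        cache: list = []
        Z = self.encode(X, cache)
        if kind == "latent":
            dZ = np.zeros_like(Z)
            dZ[:, idx] = 1.0
        elif kind == "head":
            y = _sigmoid(Z @ self.head_W + self.head_b)[:, idx]
            dZ = (y * (1.0 - y))[:, None] * self.head_W[None, :, idx]
        else:
            raise ValueError(f"unknown attribution target kind {kind!r}")
        d_pre = dZ
        for i in range(len(self.enc_W) - 1, -1, -1):
            d_prev = d_pre @ self.enc_W[i].T
            if i > 0:
                d_pre = d_prev * (cache[i - 1][1] > 0)
        return d_prev


class Adam:
    """Adam with L2 weight decay folded into the gradient (the classic
    regularized variant). Learning rate and decay are read at each step so
    a schedule can adjust them between epochs."""

    def __init__(self, shapes: list[tuple], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float,
        weight_decay: float,
    ) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            if weight_decay:
                g = g + weight_decay * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
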
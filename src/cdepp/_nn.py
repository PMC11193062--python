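"""Compact numpy neural network used by the embedders and the classifier.

The trunk mirrors the sequence-embedder design used for metric-learning
placement: a single site-wise convolution (kernel width 1 over the 4 one-hot
channels), a residual block of two such convolutions whose input is added to
their output, and a final fully connected layer.  Forward and backward passes
are written out explicitly; parameters are updated with Adam.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrunkNet", "Adam", "pairwise_distance_loss", "softmax_cross_entropy"]

_DTYPE = np.float32


class TrunkNet:
    """conv(4->C) -> residual block (two conv C->C) -> FC to ``out_dim``.

    Input: one-hot array of shape (B, L, 4).  Kernel width is 1, so each
    convolution is a per-site channel-mixing matrix; gap columns (all-zero
    input) only contribute the biases.
    """

    def __init__(self, seq_len: int, out_dim: int, channels: int = 32, seed: int = 0):
        self.seq_len = int(seq_len)
        self.out_dim = int(out_dim)
        self.channels = int(channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        C, L, d = self.channels, self.seq_len, self.out_dim

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)

        self.params = {
            "W1": he((4, C), 4),
            "b1": np.zeros(C, dtype=_DTYPE),
            "W2": he((C, C), C),
            "b2": np.zeros(C, dtype=_DTYPE),
            "W3": he((C, C), C),
            "b3": np.zeros(C, dtype=_DTYPE),
            "Wf": he((L * C, d), L * C),
            "bf": np.zeros(d, dtype=_DTYPE),
        }

    # -- forward --------------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        p = self.params
        X = np.ascontiguousarray(X, dtype=_DTYPE)
        H0 = np.maximum(X @ p["W1"] + p["b1"], 0.0)
        R1 = np.maximum(H0 @ p["W2"] + p["b2"], 0.0)
        R2 = R1 @ p["W3"] + p["b3"]
        H3 = np.maximum(R2 + H0, 0.0)
        B = X.shape[0]
        F = H3.reshape(B, -1)
        out = F @ p["Wf"] + p["bf"]
        if cache:
            return out, (X, H0, R1, R2, H3, F)
        return out

    # -- backward -------------------------------------------------------
    def backward(self, dOut: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        X, H0, R1, R2, H3, F = cache
        B, L, _ = X.shape
        C = self.channels
        dOut = dOut.astype(_DTYPE)
        grads = {}
        grads["Wf"] = F.T @ dOut
        grads["bf"] = dOut.sum(axis=0)
        dF = dOut @ p["Wf"].T
        dH3 = dF.reshape(B, L, C)
        dZ = dH3 * (H3 > 0)
        # residual: gradient flows both into the block and straight to H0
        dZr = dZ.reshape(-1, C)
        R1r = R1.reshape(-1, C)
        grads["W3"] = R1r.T @ dZr
        grads["b3"] = dZr.sum(axis=0)
        dR1 = (dZ @ p["W3"].T) * (R1 > 0)
        dR1r = dR1.reshape(-1, C)
        H0r = H0.reshape(-1, C)
        grads["W2"] = H0r.T @ dR1r
        grads["b2"] = dR1r.sum(axis=0)
        dH0 = dZ + dR1 @ p["W2"].T
        dZ1 = dH0 * (H0 > 0)
        dZ1r = dZ1.reshape(-1, C)
        Xr = X.reshape(-1, 4)
        grads["W1"] = Xr.T @ dZ1r
        grads["b1"] = dZ1r.sum(axis=0)
        return grads

    # -- (de)serialization ---------------------------------------------
    def get_state(self) -> dict:
        return {
            "seq_len": self.seq_len,
            "out_dim": self.out_dim,
            "channels": self.channels,
            "seed": self.seed,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_state(cls, state: dict) -> "TrunkNet":
        net = cls(state["seq_len"], state["out_dim"], state["channels"], state["seed"])
        net.params = {k: np.asarray(v, dtype=_DTYPE) for k, v in state["params"].items()}
        return net

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


class Adam:
    """Adam optimizer over a TrunkNet's parameter dict."""

    def __init__(self, net: TrunkNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            g = g.astype(_DTYPE)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            self.net.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DTYPE)


# ---------------------------------------------------------------------------
# Loss heads
# ---------------------------------------------------------------------------

def pairwise_distance_loss(E: np.ndarray, D: np.ndarray, return_grad: bool = False):
    """Weighted metric-matching loss over unordered pairs.

    loss = sum_{i<j, d_ij>0} (1/d_ij) * (||E_i - E_j|| - d_ij)^2

    Pairs with d_ij == 0 are excluded; the number of excluded pairs is
    returned as a diagnostic.
    """
    E = np.asarray(E, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    B = E.shape[0]
    if D.shape != (B, B):
        raise ValueError(f"distance matrix shape {D.shape} does not match {B} points")
    iu = ~np.eye(B, dtype=bool)
    pos = iu & (D > 0)
    n_excluded = int(np.count_nonzero(iu & (D <= 0)) // 2)
    diff = E[:, None, :] - E[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    resid = np.where(pos, r - D, 0.0)
    w = np.where(pos, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    loss = 0.5 * float((w * resid ** 2).sum())  # each unordered pair counted once
    if not return_grad:
        return loss, n_excluded
    r_safe = np.where(r > 0, r, 1.0)
    Cf = 2.0 * w * resid / r_safe  # symmetric coefficient matrix
    dE = Cf.sum(axis=1)[:, None] * E - Cf @ E
    return loss, n_excluded, dE


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray, return_grad: bool = False):
    """Mean cross-entropy of softmax(logits) against integer labels."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    P = ez / ez.sum(axis=1, keepdims=True)
    B = logits.shape[0]
    eps = 1e-300
    loss = float(-np.log(P[np.arange(B), y] + eps).mean())
    if not return_grad:
        return loss
    G = P.copy()
    G[np.arange(B), y] -= 1.0
    return loss, G / B


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)
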
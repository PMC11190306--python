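"""Adam optimizer, softmax cross-entropy, and the mini-batch training loop."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Module, Parameter

__all__ = ["TrainConfig", "Adam", "softmax", "cross_entropy", "train_network"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adam, lr 0.01, weight decay 1e-4, 100 epochs,
    batch size 256, multi-class cross-entropy."""

    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")


class Adam:
    def __init__(self, params: list[Parameter], lr=0.01, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y_idx: np.ndarray):
    """Mean loss and the gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), y_idx], 1e-30)))
    grad = p
    grad[np.arange(n), y_idx] -= 1.0
    return loss, grad / n


def train_network(
    net: Module,
    X: np.ndarray,
    y_idx: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Train in place; returns the per-epoch mean calibration loss.

    Deterministic given ``cfg.seed`` (it drives the shuffling stream; the
    network's own seed fixed its initialization). Zero epochs leave the
    network untouched and return an empty history.
    """
    X = np.asarray(X, dtype=getattr(net, "dtype", np.float64))
    if X.ndim == 2:
        X = X[:, None, :]
    y_idx = np.asarray(y_idx, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("calibration set is empty")
    if X.shape[0] != y_idx.shape[0]:
        raise ValueError("X and y length mismatch")
    if cfg.epochs == 0:
        return []
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    net.train(True)
    history = []
    n = X.shape[0]
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            logits = net.forward(X[idx])
            loss, dlogits = cross_entropy(logits, y_idx[idx])
            net.zero_grad()
            net.backward_to(dlogits) if hasattr(net, "backward_to") else net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
        history.append(float(np.sum(losses) / n))
    net.eval()
    return history
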
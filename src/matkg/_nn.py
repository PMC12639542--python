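"""Minimal seed-deterministic neural-net primitives (numpy).

Both classifier heads in this package are small enough that explicit
forward/backward passes are clearer and lighter than a framework
dependency.  Everything here is deterministic given the seed: fixed
initialisation, fixed shuffling, seeded dropout.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    n = probs.shape[0]
    return float(-np.log(probs[np.arange(n), y] + 1e-12).mean())


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class AdamW:
    """AdamW optimizer over a flat dict of named numpy parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                            + self.weight_decay * p)


class MLPClassifier:
    """Two fully connected layers with dropout; softmax cross-entropy.

    ``fit`` runs minibatch AdamW; all randomness flows from ``seed``.
    """

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 dropout: float = 0.1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": glorot(rng, n_in, n_hidden),
            "b1": np.zeros(n_hidden),
            "W2": glorot(rng, n_hidden, n_out),
            "b2": np.zeros(n_out),
        }
        self.dropout = dropout
        self.seed = seed
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        p = self.params
        Z1 = X @ p["W1"] + p["b1"]
        A1 = relu(Z1)
        mask = None
        if rng is not None and self.dropout > 0:
            mask = (rng.random(A1.shape) >= self.dropout) / (1 - self.dropout)
            A1 = A1 * mask
        logits = A1 @ p["W2"] + p["b2"]
        return Z1, A1, mask, logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, _, _, logits = self._forward(np.asarray(X, dtype=np.float64))
        return softmax(logits)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 50,
            lr: float = 1e-3, batch_size: int = 64,
            weight_decay: float = 0.01) -> list[float]:
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(self.seed + 1)
        opt = AdamW(self.params, lr=lr, weight_decay=weight_decay)
        n = X.shape[0]
        losses = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                Xb, yb = X[idx], y[idx]
                Z1, A1, mask, logits = self._forward(Xb, rng)
                probs = softmax(logits)
                epoch_loss += cross_entropy(probs, yb) * len(idx)
                d_logits = probs.copy()
                d_logits[np.arange(len(yb)), yb] -= 1.0
                d_logits /= len(yb)
                grads = {
                    "W2": A1.T @ d_logits,
                    "b2": d_logits.sum(axis=0),
                }
                dA1 = d_logits @ self.params["W2"].T
                if mask is not None:
                    dA1 = dA1 * mask
                dZ1 = dA1 * (Z1 > 0)
                grads["W1"] = Xb.T @ dZ1
                grads["b1"] = dZ1.sum(axis=0)
                opt.step(grads)
            losses.append(epoch_loss / n)
        return losses

    def to_json(self) -> dict:
        return {
            "n_in": self.n_in, "n_hidden": self.n_hidden, "n_out": self.n_out,
            "dropout": self.dropout, "seed": self.seed,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "MLPClassifier":
        model = cls(obj["n_in"], obj["n_hidden"], obj["n_out"],
                    dropout=obj["dropout"], seed=obj["seed"])
        model.params = {k: np.array(v) for k, v in obj["params"].items()}
        return model
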
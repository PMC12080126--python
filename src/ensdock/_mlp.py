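"""Minimal seeded feed-forward network for multilabel classification.

ReLU hidden layers with inverted dropout on the first and last hidden
layers, sigmoid outputs, binary cross-entropy loss, Adam updates.  All
randomness flows through one PCG64 generator so training is reproducible
bit-for-bit under a fixed seed on a fixed platform.
"""

from __future__ import annotations

import numpy as np


class MLP:
    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        n_out: int,
        dropout: float = 0.2,
        seed: int = 0,
    ):
        if not hidden:
            raise ValueError("at least one hidden layer required")
        self.rng = np.random.default_rng(seed)
        self.dropout = float(dropout)
        sizes = [n_in, *hidden, n_out]
        self.W = [
            self.rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam_m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._adam_t = 0
        #: indices of hidden layers that get dropout (first and last)
        n_hidden = len(hidden)
        self._drop_layers = {0, n_hidden - 1}

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, list]:
        cache = []
        a = x
        n_layers = len(self.W)
        for li in range(n_layers - 1):
            z = a @ self.W[li] + self.b[li]
            h = np.maximum(z, 0.0)
            mask = None
            if train and self.dropout > 0.0 and li in self._drop_layers:
                mask = (self.rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
            cache.append((a, z, mask))
            a = h
        z = a @ self.W[-1] + self.b[-1]
        cache.append((a, z, None))
        p = 1.0 / (1.0 + np.exp(-z))
        return p, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self._forward(x[i : i + batch_size], train=False)[0])
        return np.vstack(out)

    # -- training ----------------------------------------------------------
    def _adam_step(self, grads: list[np.ndarray], lr: float) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        params = self.W + self.b
        for k, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def train_batch(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        p, cache = self._forward(x, train=True)
        n = len(x)
        eps = 1e-7
        pc = np.clip(p, eps, 1 - eps)
        loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
        # gradient of mean BCE wrt logits: (p - y) / (n * n_out)
        delta = (p - y) / (n * y.shape[1])
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for li in range(len(self.W) - 1, -1, -1):
            a, z, mask = cache[li]
            gW[li] = a.T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.W[li].T
                a_prev, z_prev, mask_prev = cache[li - 1]
                if mask_prev is not None:
                    delta = delta * mask_prev
                delta = delta * (z_prev > 0.0)
        self._adam_step(gW + gb, lr)
        return loss

    def get_params(self) -> dict:
        return {
            "W": [w.copy() for w in self.W],
            "b": [b.copy() for b in self.b],
        }

    def set_params(self, params: dict) -> None:
        self.W = [w.copy() for w in params["W"]]
        self.b = [b.copy() for b in params["b"]]
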
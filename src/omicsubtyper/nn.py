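"""Minimal fully-connected network engine (numpy, CPU, seed-deterministic).

Supports ReLU hidden layers, linear or softmax output, inverted dropout,
L1 weight penalty, L2 activity penalty on hidden activations, and the Adam
optimizer. Deliberately small: just what the integration and fusion stages
need, with bit-reproducible behaviour under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ADAM_BETA1, ADAM_BETA2, ADAM_EPS = 0.9, 0.999, 1e-8


def init_layers(widths: list[int], rng: np.random.Generator):
    """Uniform fan-in initialization: W ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    params = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MLP:
    """Feed-forward net: ReLU on all hidden layers, configurable head."""

    widths: list[int]
    output: str = "linear"  # or "softmax"
    dropout: float = 0.0
    l1_weight: float = 0.0
    l2_activity: float = 0.0

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.widths):
            raise ValueError("all layer widths must be >= 1")
        if self.output not in ("linear", "softmax"):
            raise ValueError("output must be 'linear' or 'softmax'")
        self.params: list[tuple[np.ndarray, np.ndarray]] = []

    def initialize(self, rng: np.random.Generator) -> None:
        self.params = init_layers(self.widths, rng)
        self._m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.params]
        self._v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.params]
        self._t = 0

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Return (output, cache). Pass ``rng`` to enable dropout (training)."""
        acts = [x]
        drop_masks = []
        h = x
        n_layers = len(self.params)
        for i, (W, b) in enumerate(self.params):
            z = h @ W + b
            if i < n_layers - 1:
                h = relu(z)
                if rng is not None and self.dropout > 0:
                    keep = 1.0 - self.dropout
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                    drop_masks.append(mask)
                else:
                    drop_masks.append(None)
            else:
                h = softmax(z) if self.output == "softmax" else z
            acts.append(h)
        return h, (acts, drop_masks)

    def predict(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.forward(x)
        return out

    def hidden(self, x: np.ndarray, upto: int) -> np.ndarray:
        """Activations of hidden layer ``upto`` (1-based), no dropout."""
        h = x
        for i, (W, b) in enumerate(self.params[:upto]):
            h = relu(h @ W + b)
        return h

    # -- training -----------------------------------------------------------

    def _loss_and_grads(self, x, target, rng):
        out, (acts, drop_masks) = self.forward(x, rng=rng)
        n = x.shape[0]
        if self.output == "softmax":
            loss = -np.mean(np.sum(target * np.log(out + 1e-12), axis=1))
            delta = (out - target) / n
        else:
            diff = out - target
            loss = float(np.mean(diff**2))
            delta = 2.0 * diff / diff.size

        if self.l2_activity > 0:
            for h in acts[1:-1]:
                loss += self.l2_activity * float(np.sum(h**2)) / n
        if self.l1_weight > 0:
            for W, _ in self.params:
                loss += self.l1_weight * float(np.abs(W).sum())

        grads = [None] * len(self.params)
        for i in range(len(self.params) - 1, -1, -1):
            W, b = self.params[i]
            h_prev = acts[i]
            gW = h_prev.T @ delta
            gb = delta.sum(axis=0)
            if self.l1_weight > 0:
                gW = gW + self.l1_weight * np.sign(W)
            grads[i] = (gW, gb)
            if i > 0:
                delta = delta @ W.T
                h = acts[i]
                if drop_masks[i - 1] is not None:
                    # dropout was applied after ReLU; gradient flows through mask
                    delta = delta * drop_masks[i - 1]
                if self.l2_activity > 0:
                    delta = delta + 2.0 * self.l2_activity * h / n
                delta = delta * (h > 0)
        return loss, grads

    def _adam_step(self, grads, lr):
        self._t += 1
        t = self._t
        for i, ((gW, gb), (W, b)) in enumerate(zip(grads, self.params)):
            mW, mb = self._m[i]
            vW, vb = self._v[i]
            mW = ADAM_BETA1 * mW + (1 - ADAM_BETA1) * gW
            mb = ADAM_BETA1 * mb + (1 - ADAM_BETA1) * gb
            vW = ADAM_BETA2 * vW + (1 - ADAM_BETA2) * gW**2
            vb = ADAM_BETA2 * vb + (1 - ADAM_BETA2) * gb**2
            self._m[i] = (mW, mb)
            self._v[i] = (vW, vb)
            corr1 = 1 - ADAM_BETA1**t
            corr2 = 1 - ADAM_BETA2**t
            W_new = W - lr * (mW / corr1) / (np.sqrt(vW / corr2) + ADAM_EPS)
            b_new = b - lr * (mb / corr1) / (np.sqrt(vb / corr2) + ADAM_EPS)
            self.params[i] = (W_new, b_new)

    def train_epoch(self, x, target, batch_size, lr, rng) -> float:
        """One pass of mini-batch Adam; returns mean per-batch loss."""
        n = x.shape[0]
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = self._loss_and_grads(x[idx], target[idx], rng)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            self._adam_step(grads, lr)
            losses.append(loss)
        return float(np.mean(losses))

    def evaluate(self, x, target) -> float:
        """Loss without dropout or penalties (pure data term)."""
        out, _ = self.forward(x)
        if self.output == "softmax":
            return float(-np.mean(np.sum(target * np.log(out + 1e-12), axis=1)))
        return float(np.mean((out - target) ** 2))

    def get_weights(self):
        return [(W.copy(), b.copy()) for W, b in self.params]

    def set_weights(self, weights):
        self.params = [(W.copy(), b.copy()) for W, b in weights]


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out
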
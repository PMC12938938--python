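"""SGD with classical momentum, softmax, and the cross-entropy training loss."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.

    ``labels`` are integer class indices of shape (N,).
    """
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = np.finfo(np.float32).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class SGDMomentum:
    """v <- mu * v - lr * g;  p <- p + v  (classical momentum, no weight decay)."""

    def __init__(self, parameters: list[Parameter], learning_rate: float = 0.01,
                 momentum: float = 0.9):
        self.parameters = parameters
        self.lr = learning_rate
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in parameters]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.parameters, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
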
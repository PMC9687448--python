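"""Adam optimizer, stepped learning-rate schedule, early stopping."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """First-order adaptive gradient descent (bias-corrected moments).

    ``l2`` adds the gradient of an L2 weight penalty to every parameter
    flagged ``decay`` (convolution/linear weights), matching a loss of the
    form ``CE + l2 * sum(w**2)``.
    """

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8, l2: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = l2
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.l2 and p.decay:
                g = g + 2.0 * self.l2 * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def step_lr(lr0: float, drop_factor: float, drop_period: float, epoch: float) -> float:
    """Learning rate after ``epoch`` (possibly fractional) epochs of training.

    The rate starts at ``lr0`` and is multiplied by ``drop_factor`` once per
    ``drop_period`` epochs: lr = lr0 * drop_factor ** floor(epoch / drop_period).
    """
    if lr0 <= 0 or not (0 < drop_factor < 1) or drop_period <= 0:
        raise ValueError("invalid schedule parameters")
    return lr0 * drop_factor ** int(np.floor(epoch / drop_period))


class EarlyStopper:
    """Stop when validation loss fails to improve by a relative margin.

    Improvement means the new loss beats the best seen so far by more than
    ``min_rel_improvement`` (a fraction, e.g. 1e-4 for 0.01%).  After
    ``patience`` consecutive epochs without such an improvement, ``update``
    returns True.
    """

    def __init__(self, min_rel_improvement: float = 1e-4, patience: int = 5):
        self.min_rel = min_rel_improvement
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def update(self, val_loss: float) -> bool:
        if self.best == np.inf:
            improved = True
        else:
            improved = (self.best - val_loss) > self.min_rel * abs(self.best)
        if improved:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience
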
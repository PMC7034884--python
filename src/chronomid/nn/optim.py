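"""Adam optimizer with decoupled L2 kernel penalty (added to gradients)."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam (Kingma & Ba) over a list of :class:`~chronomid.nn.layers.Param`.

    ``l2`` is the coefficient of an additive ``l2 * sum(W**2)`` penalty on
    parameters flagged ``regularized``; its gradient ``2 * l2 * W`` is folded
    in here so the loss layers stay penalty-free.
    """

    def __init__(
        self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, l2=0.0, clip_norm=5.0
    ):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.l2 = l2
        #: global gradient-norm ceiling (None disables); guards the few
        #: large-batch steps that would otherwise destabilise batch norm
        self.clip_norm = clip_norm
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def penalty(self):
        """Current L2 penalty value (for loss reporting)."""
        if self.l2 == 0.0:
            return 0.0
        return self.l2 * sum(float(np.sum(p.value**2)) for p in self.params if p.regularized)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for i, p in enumerate(self.params):
            g = p.grad * scale
            if self.l2 and p.regularized:
                g = g + 2.0 * self.l2 * p.value
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1**self.t)
            vhat = self._v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
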
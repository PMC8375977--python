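"""Nesterov-accelerated adaptive moment estimation (Nadam).

The update follows Dozat's formulation with bias-corrected first and second
moments and a Nesterov look-ahead on the first moment:

    m_t = b1 m_{t-1} + (1-b1) g_t
    v_t = b2 v_{t-1} + (1-b2) g_t^2
    m_hat = b1 m_t / (1 - b1^{t+1}) + (1-b1) g_t / (1 - b1^t)
    v_hat = v_t / (1 - b2^t)
    theta -= lr * m_hat / (sqrt(v_hat) + eps)
"""

from __future__ import annotations

import numpy as np


class Nadam:
    def __init__(self, net, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c1_next = 1.0 - b1 ** (self.t + 1)
        c2 = 1.0 - b2 ** self.t
        for name, layer, attr in self.net.named_param_layers():
            if attr not in layer.grads:
                continue
            g = layer.grads[attr]
            m = self._m.get(name)
            if m is None:
                m = np.zeros_like(g, dtype=np.float64)
                self._v[name] = np.zeros_like(g, dtype=np.float64)
            v = self._v[name]
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._m[name], self._v[name] = m, v
            m_hat = b1 * m / c1_next + (1 - b1) * g / c1
            v_hat = v / c2
            p = getattr(layer, attr)
            setattr(layer, attr,
                    (p - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))
                    .astype(p.dtype))
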
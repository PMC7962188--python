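"""Adam optimizer operating on (param, grad) array pairs in place.

The update is memory-bandwidth bound at the parameter counts the U-Net
reaches (~10^7 scalars), so the per-element loop is JIT-fused with numba
when available; the numpy path computes the same update with scratch
buffers.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_update(p, g, m, v, lr, b1, b2, eps, inv_bc1, inv_bc2):  # pragma: no cover
        # constants arrive as float32 so the loop vectorizes in single
        # precision end to end
        one = np.float32(1.0)
        for i in range(p.size):
            gi = g[i]
            mi = b1 * m[i] + (one - b1) * gi
            vi = b2 * v[i] + (one - b2) * gi * gi
            m[i] = mi
            v[i] = vi
            p[i] -= lr * (mi * inv_bc1) / (np.sqrt(vi * inv_bc2) + eps)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        # params: list of (value, grad) numpy array pairs, mutated in place
        self.params = list(params)
        self.lr = float(lr)
        self.beta1 = float(beta1)
        self.beta2 = float(beta2)
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p) for p, _ in self.params]
        self._v = [np.zeros_like(p) for p, _ in self.params]
        if not _HAVE_NUMBA:
            self._scratch = [np.empty_like(p) for p, _ in self.params]

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        if _HAVE_NUMBA:
            f32 = np.float32
            for (p, g), m, v in zip(self.params, self._m, self._v):
                _adam_update(p.reshape(-1), g.reshape(-1), m.reshape(-1),
                             v.reshape(-1), f32(self.lr), f32(b1), f32(b2),
                             f32(self.eps), f32(1.0 / bc1), f32(1.0 / bc2))
            return
        for (p, g), m, v, tmp in zip(self.params, self._m, self._v,
                                     self._scratch):
            m *= b1
            m += (1.0 - b1) * g
            np.square(g, out=tmp)
            v *= b2
            tmp *= (1.0 - b2)
            v += tmp
            np.multiply(v, 1.0 / bc2, out=tmp)
            np.sqrt(tmp, out=tmp)
            tmp += self.eps
            np.divide(m, tmp, out=tmp)
            tmp *= self.lr / bc1
            p -= tmp
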
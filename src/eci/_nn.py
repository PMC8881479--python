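"""Minimal CNN compute engine (NumPy): valid conv, overlapping max-pool,
ReLU, softmax cross-entropy, Adam, and epsilon-rule relevance backward.

Layers keep their forward intermediates, so a relevance pass can reuse them.
Array layout is channels-last: (batch, rows, cols, channels).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _windows(x: np.ndarray, kh: int, kw: int, sr: int, sc: int) -> np.ndarray:
    # (B, Ho, Wo, C, kh, kw)
    w = sliding_window_view(x, (kh, kw), axis=(1, 2))
    return w[:, ::sr, ::sc]


class Conv2D:
    def __init__(self, kh, kw, cin, cout, stride=(1, 1), rng=None, dtype=np.float32):
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        self.stride = stride
        limit = np.sqrt(6.0 / (kh * kw * cin))
        rng = rng or np.random.default_rng(0)
        self.W = rng.uniform(-limit, limit, size=(kh, kw, cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.x = None
        self.z = None

    @property
    def _Wmat(self):
        return self.W.transpose(2, 0, 1, 3).reshape(self.cin * self.kh * self.kw, self.cout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        sr, sc = self.stride
        pat = _windows(x, self.kh, self.kw, sr, sc)
        B, Ho, Wo = pat.shape[:3]
        self._pat = pat.reshape(B, Ho, Wo, -1)
        self.z = self._pat @ self._Wmat + self.b
        return self.z

    def _scatter(self, s: np.ndarray) -> np.ndarray:
        """Distribute per-patch values back onto the input grid (col2im)."""
        B, Ho, Wo, _ = s.shape
        sr, sc = self.stride
        s6 = s.reshape(B, Ho, Wo, self.cin, self.kh, self.kw)
        out = np.zeros_like(self.x)
        for i in range(self.kh):
            for j in range(self.kw):
                out[:, i:i + sr * Ho:sr, j:j + sc * Wo:sc, :] += s6[:, :, :, :, i, j]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B = dout.shape[0]
        flat_p = self._pat.reshape(-1, self._pat.shape[-1])
        flat_d = dout.reshape(-1, self.cout)
        dWmat = flat_p.T @ flat_d
        self.dW = dWmat.reshape(self.cin, self.kh, self.kw, self.cout).transpose(1, 2, 0, 3)
        self.db = flat_d.sum(axis=0)
        return self._scatter(dout @ self._Wmat.T)

    def relevance(self, R: np.ndarray, eps: float | None) -> np.ndarray:
        """Epsilon-stabilized proportional redistribution; bias relevance is
        absorbed (exact conservation only for bias-free layers).  ``eps=None``
        uses the adaptive default 1e-2 x mean |pre-activation|."""
        z = self.z
        if eps is None:
            eps = 1e-2 * float(np.abs(z).mean())
        if eps > 0:
            zs = np.where(z >= 0, z + eps, z - eps)
        else:
            zs = z
        s = np.divide(R, zs, out=np.zeros_like(R), where=zs != 0)
        c = self._scatter(s @ self._Wmat.T)
        return self.x * c

    def params(self):
        return [(self, "W"), (self, "b")]


class MaxPool2D:
    def __init__(self, ph, pw, stride):
        self.ph, self.pw = ph, pw
        self.stride = stride
        self.x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        sr, sc = self.stride
        pat = _windows(x, self.ph, self.pw, sr, sc)  # (B,Ho,Wo,C,ph,pw)
        flat = pat.reshape(pat.shape[:4] + (-1,))
        self.arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def _route(self, val: np.ndarray) -> np.ndarray:
        """Winner-take-all: send each window's value to its argmax input."""
        sr, sc = self.stride
        B, Ho, Wo, C = val.shape
        out = np.zeros_like(self.x)
        for i in range(self.ph):
            for j in range(self.pw):
                mask = self.arg == (i * self.pw + j)
                out[:, i:i + sr * Ho:sr, j:j + sc * Wo:sc, :] += val * mask
        return out

    def backward(self, dout):
        return self._route(dout)

    def relevance(self, R, eps):
        return self._route(R)

    def params(self):
        return []


class ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask

    def relevance(self, R, eps):
        return R  # identity: downstream relevance already sits on active units

    def params(self):
        return []


class Flatten:
    def forward(self, x):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.shape)

    def relevance(self, R, eps):
        return R.reshape(self.shape)

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def relevance(self, R: np.ndarray, eps: float) -> np.ndarray:
        for lay in reversed(self.layers):
            R = lay.relevance(R, eps)
        return R

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def state(self) -> list[np.ndarray]:
        return [getattr(obj, name).copy() for obj, name in self.params()]

    def load_state(self, arrays) -> None:
        for (obj, name), arr in zip(self.params(), arrays):
            setattr(obj, name, arr.copy())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    B = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(B), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(B), y] -= 1.0
    return float(loss), grad / B


class Adam:
    def __init__(self, params, lr0=0.005, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = self.lr0 = lr0
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for o, n in params]
        self.v = [np.zeros_like(getattr(o, n)) for o, n in params]

    def set_lr(self, lr: float) -> None:
        self.lr = lr

    def step(self) -> None:
        self.t += 1
        for k, (obj, name) in enumerate(self.params):
            g = getattr(obj, "d" + name)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            val = getattr(obj, name)
            setattr(obj, name, val - self.lr * mhat / (np.sqrt(vhat) + self.eps))
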
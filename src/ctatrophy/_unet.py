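"""A compact CPU U-Net: im2col convolutions, ReLU, max-pool, nearest
upsampling with skip concatenation, softmax cross-entropy, and Adam.

Tensors are ``(N, C, H, W)`` float32.  The network is the classic
encoder-decoder with skip connections: each contracting level halves the
spatial size and doubles the channels; the expanding path mirrors it and
concatenates the matching encoder feature map; a final 1x1 convolution
produces per-pixel class logits.  Everything is deterministic for a
fixed seed under single-threaded (or fixed-thread) BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * k * k
    )


def _col2im(dcols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=DTYPE)
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)  # N,C,k,k,H,W
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv:
    """k x k same-padding convolution (He-initialized)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cin * k * k, cout)) * scale).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.k, self.pad = k, k // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._x_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        self._cols, self._x_shape = cols, x.shape
        out = cols @ self.W + self.b
        return np.ascontiguousarray(out.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, cout, h, w = dy.shape
        dflat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.W.T
        return _col2im(dcols, self._x_shape, self.k, self.pad)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        blocks = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        # argmax breaks 2x2 ties deterministically (first max wins)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        mask = np.zeros(blocks.shape, dtype=bool)
        np.put_along_axis(mask, idx[..., None], True, axis=-1)
        self._mask = mask
        return np.ascontiguousarray(out)

    def backward(self, dy):
        n, c, hh, ww = dy.shape
        d = self._mask * dy[..., None]
        return np.ascontiguousarray(
            d.reshape(n, c, hh, ww, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, hh * 2, ww * 2)
        )


class Upsample2:
    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Encoder-decoder segmentation network with skip connections."""

    def __init__(self, depth: int = 3, base_channels: int = 16, in_channels: int = 1,
                 n_classes: int = 4, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth, self.n_classes = depth, n_classes
        ch = [base_channels * 2**l for l in range(depth + 1)]
        self.enc = []
        cin = in_channels
        for l in range(depth):
            self.enc.append((Conv(cin, ch[l], 3, rng), ReLU(), Conv(ch[l], ch[l], 3, rng), ReLU()))
            cin = ch[l]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bott = (Conv(ch[depth - 1], ch[depth], 3, rng), ReLU(),
                     Conv(ch[depth], ch[depth], 3, rng), ReLU())
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        for l in reversed(range(depth)):
            self.dec.append((
                Conv(ch[l + 1], ch[l], 3, rng), ReLU(),          # after upsample
                Conv(2 * ch[l], ch[l], 3, rng), ReLU(),           # after skip concat
                Conv(ch[l], ch[l], 3, rng), ReLU(),
            ))
        self.head = Conv(ch[0], n_classes, 1, rng)

    # ---- plumbing -------------------------------------------------------
    def _layers(self):
        for block in self.enc:
            yield from (block[0], block[2])
        yield from (self.bott[0], self.bott[2])
        for block in self.dec:
            yield from (block[0], block[2], block[4])
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self._layers():
            out.extend(layer.grads)
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # ---- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:
            x = x[:, None]
        if any(s % 2**self.depth for s in x.shape[2:]):
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by 2^depth={2**self.depth}"
            )
        skips = []
        for l, (c1, r1, c2, r2) in enumerate(self.enc):
            x = r2.forward(c2.forward(r1.forward(c1.forward(x))))
            skips.append(x)
            x = self.pools[l].forward(x)
        c1, r1, c2, r2 = self.bott
        x = r2.forward(c2.forward(r1.forward(c1.forward(x))))
        self._skip_channels = []
        for i, (c1, r1, c2, r2, c3, r3) in enumerate(self.dec):
            x = r1.forward(c1.forward(self.ups[i].forward(x)))
            skip = skips[self.depth - 1 - i]
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = r3.forward(c3.forward(r2.forward(c2.forward(x))))
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits.astype(DTYPE))
        dskips = [None] * self.depth
        for i in reversed(range(len(self.dec))):
            c1, r1, c2, r2, c3, r3 = self.dec[i]
            dx = c2.backward(r2.backward(c3.backward(r3.backward(dx))))
            nskip = self._skip_channels[i]
            dskips[self.depth - 1 - i] = dx[:, :nskip]
            dx = dx[:, nskip:]
            dx = self.ups[i].backward(c1.backward(r1.backward(dx)))
        c1, r1, c2, r2 = self.bott
        dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))
        for l in reversed(range(self.depth)):
            dx = self.pools[l].backward(dx)
            dx = dx + dskips[l]
            c1, r1, c2, r2 = self.enc[l]
            dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean per-pixel multiclass cross-entropy and its logit gradient.

    ``targets`` is an integer class map ``(N, H, W)``.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, k, h, w = logits.shape
    idx = np.eye(k, dtype=DTYPE)[targets].transpose(0, 3, 1, 2)
    eps = 1e-12
    loss = float(-(idx * np.log(p + eps)).sum() / (n * h * w))
    grad = (p - idx) / (n * h * w)
    return loss, grad.astype(DTYPE)


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
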
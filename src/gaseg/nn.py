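"""Minimal convolutional-network engine (numpy, manual backprop).

Implements exactly the pieces the segmentation networks need: same-padded
2-D convolutions (shifted-view GEMMs), batch normalisation, ReLU, 2x2 max
pooling, nearest-neighbour upsampling, channel softmax, and Adam /
momentum-SGD optimizers.  Tensors are ``(batch, channels, height, width)``
arrays (float32 by default, float64 for gradient checking); every layer
caches what its backward pass needs and writes parameter gradients into
``.grads``.  ``backward(..., retain=True)`` keeps the caches so a second
loss can be back-propagated through the same forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "channel_softmax",
    "channel_softmax_backward",
    "Adam",
    "SGD",
    "UNet",
]


class Conv2d:
    """Same-padded convolution (cross-correlation) with bias.

    Evaluated as k*k shifted-view GEMMs, which keeps memory traffic
    sequential and lets BLAS do the arithmetic.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32, padding: str = "zeros"):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        if padding not in ("zeros", "reflect"):
            raise ValueError("padding must be 'zeros' or 'reflect'")
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = k
        self.padding = padding
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p == 0:
            xp = x
        elif self.padding == "reflect":
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        y = np.zeros((b, self.W.shape[0], h * w), dtype=x.dtype)
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(
                    xp[:, :, di:di + h, dj:dj + w]).reshape(b, c, h * w)
                y += np.matmul(self.W[:, :, di, dj], xs)
        y += self.b[None, :, None]
        if store:
            self._xp = xp
        return y.reshape(b, -1, h, w)

    def backward(self, dy: np.ndarray, retain: bool = False) -> np.ndarray:
        b, c_out, h, w = dy.shape
        k, p = self.k, self.k // 2
        c = self.W.shape[1]
        dyf = np.ascontiguousarray(dy).reshape(b, c_out, h * w)
        xp = self._xp
        dxp = np.zeros_like(xp)
        dW = self.grads[0]
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(
                    xp[:, :, di:di + h, dj:dj + w]).reshape(b, c, h * w)
                dW[:, :, di, dj] = np.tensordot(dyf, xs, axes=([0, 2], [0, 2]))
                contrib = np.matmul(self.W[:, :, di, dj].T, dyf)
                dxp[:, :, di:di + h, dj:dj + w] += contrib.reshape(b, c, h, w)
        self.grads[1][...] = dyf.sum(axis=(0, 2))
        if not retain:
            self._xp = None
        if p == 0:
            return dxp
        if self.padding == "zeros":
            return dxp[:, :, p:p + h, p:p + w]
        # reflect padding: fold border gradients back onto their sources
        def _src(t: int, n: int) -> int:
            return -t if t < 0 else (2 * n - 2 - t if t >= n else t)
        rows = dxp[:, :, p:p + h, :].copy()
        for r in list(range(p)) + list(range(h + p, h + 2 * p)):
            rows[:, :, _src(r - p, h), :] += dxp[:, :, r, :]
        dx = rows[:, :, :, p:p + w].copy()
        for cidx in list(range(p)) + list(range(w + p, w + 2 * p)):
            dx[:, :, :, _src(cidx - p, w)] += rows[:, :, :, cidx]
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if store:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray, retain: bool = False) -> np.ndarray:
        dx = dy * self._mask
        if not retain:
            self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2; ties resolved to the first window element."""

    def __init__(self):
        self._onehot = None

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(b, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if store:
            onehot = np.zeros_like(flat)
            np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
            self._onehot = onehot
        return y

    def backward(self, dy: np.ndarray, retain: bool = False) -> np.ndarray:
        b, c, h2, w2 = dy.shape
        dflat = self._onehot * dy[..., None]
        dx = dflat.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        if not retain:
            self._onehot = None
        return dx.reshape(b, c, h2 * 2, w2 * 2)


class BatchNorm2d:
    """Per-channel normalisation over (batch, H, W) with learned scale/shift.

    Training forwards (``store=True``) use batch statistics and update
    running estimates; inference forwards use the running estimates.
    """

    def __init__(self, c: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        if store:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        xhat = xhat.astype(x.dtype)
        if store:
            self._cache = (xhat, invstd.astype(x.dtype))
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray, retain: bool = False) -> np.ndarray:
        xhat, invstd = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dbeta = dy.sum(axis=(0, 2, 3))
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads[0][...] = dgamma
        self.grads[1][...] = dbeta
        g = self.gamma[None, :, None, None] * invstd[None, :, None, None]
        dx = g * (dy - (dbeta / n)[None, :, None, None]
                  - xhat * (dgamma / n)[None, :, None, None])
        if not retain:
            self._cache = None
        return dx


class Upsample2:
    """Nearest-neighbour x2 upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray, retain: bool = False) -> np.ndarray:
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def channel_softmax(z: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of (B,C,H,W)."""
    zm = z - z.max(axis=1, keepdims=True)
    e = np.exp(zm)
    return e / e.sum(axis=1, keepdims=True)

def channel_softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Given softmax output p and dL/dp, return dL/dz."""
    dot = (dp * p).sum(axis=1, keepdims=True)
    return p * (dp - dot)


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class SGD:
    def __init__(self, params, grads, lr: float = 0.1, momentum: float = 0.9):
        self.params, self.grads = params, grads
        self.lr, self.momentum = lr, momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        for p, g, v in zip(self.params, self.grads, self.v):
            v *= self.momentum
            v -= self.lr * g
            p += v

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class _ConvBlock:
    """Two conv+BN+ReLU stages."""

    def __init__(self, c_in, c_out, k, rng, dtype=np.float32, padding="reflect"):
        self.c1 = Conv2d(c_in, c_out, k, rng, dtype, padding)
        self.b1 = BatchNorm2d(c_out, dtype)
        self.r1 = ReLU()
        self.c2 = Conv2d(c_out, c_out, k, rng, dtype, padding)
        self.b2 = BatchNorm2d(c_out, dtype)
        self.r2 = ReLU()

    def forward(self, x, store=True):
        h = self.r1.forward(self.b1.forward(self.c1.forward(x, store), store), store)
        return self.r2.forward(self.b2.forward(self.c2.forward(h, store), store), store)

    def backward(self, dy, retain: bool = False):
        dh = self.c2.backward(self.b2.backward(self.r2.backward(dy, retain), retain), retain)
        return self.c1.backward(self.b1.backward(self.r1.backward(dh, retain), retain), retain)

    @property
    def layers(self):
        return [self.c1, self.b1, self.c2, self.b2]


class UNet:
    """U-net: contracting path, expansive path with skip concatenations.

    ``depth`` down-sampling stages double the feature width each time, so the
    bottleneck carries ``base * 2**(depth-1)`` features.  ``final`` selects the
    head: ``"softmax"`` (class probabilities) or ``"linear"`` (reconstruction).
    Convolutions use reflect padding by default, keeping the network fully
    translation-equivariant (zero padding would leak absolute pixel position
    into the features, letting an unsupervised objective settle on fixed
    spatial partitions instead of content-driven ones).
    """

    def __init__(self, c_in: int, c_out: int, depth: int, base: int,
                 kernel_size: int, rng: np.random.Generator,
                 final: str = "linear", dtype=np.float32,
                 padding: str = "reflect"):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.depth = depth
        self.final = final
        self.dtype = dtype
        feats = [base * 2 ** d for d in range(depth)]
        self.enc = []
        c_prev = c_in
        for d in range(depth):
            self.enc.append(_ConvBlock(c_prev, feats[d], kernel_size, rng, dtype, padding))
            c_prev = feats[d]
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = []
        self.upconv = []
        self.dec = []
        for d in range(depth - 2, -1, -1):
            self.ups.append(Upsample2())
            self.upconv.append(Conv2d(feats[d + 1], feats[d], kernel_size, rng, dtype, padding))
            self.dec.append(_ConvBlock(2 * feats[d], feats[d], kernel_size, rng, dtype, padding))
        self.head = Conv2d(feats[0], c_out, 1, rng, dtype)

    # -- parameter plumbing ---------------------------------------------
    @property
    def _conv_layers(self) -> list[Conv2d]:
        layers: list[Conv2d] = []
        for blk in self.enc:
            layers += blk.layers
        layers += list(self.upconv)
        for blk in self.dec:
            layers += blk.layers
        layers.append(self.head)
        return layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self._conv_layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self._conv_layers for g in l.grads]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p for i, p in enumerate(self.params)}
        for j, l in enumerate(self._conv_layers):
            if isinstance(l, BatchNorm2d):
                state[f"bn{j}_mean"] = l.running_mean
                state[f"bn{j}_var"] = l.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p[...] = state[f"p{i}"]
        for j, l in enumerate(self._conv_layers):
            if isinstance(l, BatchNorm2d):
                l.running_mean[...] = state[f"bn{j}_mean"]
                l.running_var[...] = state[f"bn{j}_var"]

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, store: bool = True) -> np.ndarray:
        skips = []
        h = x
        for d in range(self.depth - 1):
            h = self.enc[d].forward(h, store)
            skips.append(h)
            h = self.pools[d].forward(h, store)
        h = self.enc[self.depth - 1].forward(h, store)
        for i, d in enumerate(range(self.depth - 2, -1, -1)):
            h = self.ups[i].forward(h, store)
            h = self.upconv[i].forward(h, store)
            h = np.concatenate([skips[d], h], axis=1)
            h = self.dec[i].forward(h, store)
        z = self.head.forward(h, store)
        if self.final == "softmax":
            p = channel_softmax(z)
            if store:
                self._soft = p
            return p
        return z

    def backward(self, dout: np.ndarray, retain: bool = False) -> np.ndarray:
        if self.final == "softmax":
            dout = channel_softmax_backward(self._soft, dout)
            if not retain:
                self._soft = None
        dh = self.head.backward(dout, retain)
        dskips = [None] * (self.depth - 1)
        for i in range(self.depth - 2, -1, -1):
            d = self.depth - 2 - i  # encoder level of dec block i
            dh = self.dec[i].backward(dh, retain)
            c_skip = dh.shape[1] // 2
            dskips[d] = dh[:, :c_skip]
            dh = self.upconv[i].backward(dh[:, c_skip:], retain)
            dh = self.ups[i].backward(dh, retain)
        dh = self.enc[self.depth - 1].backward(dh, retain)
        for d in range(self.depth - 2, -1, -1):
            dh = self.pools[d].backward(dh, retain)
            dh = dh + dskips[d]
            dh = self.enc[d].backward(dh, retain)
        return dh

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))
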
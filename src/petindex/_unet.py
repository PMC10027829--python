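"""Minimal NumPy 3D U-Net with valid convolutions and manual backprop.

The network follows the classic 3D U-Net layout — per-level blocks of 3x3x3
convolutions + ReLU, 2x max pooling on the way down, nearest-neighbour
upsampling with center-cropped skip concatenation on the way up, and a final
1x1x1 convolution to class logits. All convolutions are *valid* (no spatial
padding), so the output window is strictly smaller than the input patch:
with depth 3 and 2 convolutions per block a 100 voxel axis shrinks to 12,
realizing the 100³ -> 12³ patch contract; shallower configurations realize
desk-scale contracts such as 36³ -> 12³ (depth 1, 3 convolutions per block).

Everything is float32 and seeded; the only dependency is numpy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet3D", "Adam", "softmax", "softmax_cross_entropy", "output_size"]


def output_size(in_size: int, depth: int, convs_per_block: int) -> int:
    """Spatial output size of the valid U-Net along one axis.

    Raises ValueError if the size goes non-positive or odd before a pooling
    step, i.e. the configuration is geometrically invalid.
    """
    k = convs_per_block
    s = in_size
    for _ in range(depth):
        s -= 2 * k
        if s <= 0 or s % 2:
            raise ValueError(
                f"input size {in_size} invalid for depth={depth}, "
                f"convs_per_block={k}: reaches {s} before pooling")
        s //= 2
    s -= 2 * k  # bottom block
    for _ in range(depth):
        s = 2 * s - 2 * k
    if s <= 0:
        raise ValueError(
            f"input size {in_size} too small for depth={depth}, convs_per_block={k}")
    return s


# ---------------------------------------------------------------------------
# functional ops with explicit caches
# ---------------------------------------------------------------------------

def _conv3_forward(x, W, b):
    win = sliding_window_view(x, (3, 3, 3), axis=(2, 3, 4))
    out = np.tensordot(win, W, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    return np.ascontiguousarray(np.moveaxis(out, -1, 1)) + b[None, :, None, None, None]


def _conv3_backward(grad, x, W):
    win = sliding_window_view(x, (3, 3, 3), axis=(2, 3, 4))
    gW = np.tensordot(grad, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
    gb = grad.sum(axis=(0, 2, 3, 4))
    gp = np.pad(grad, ((0, 0), (0, 0), (2, 2), (2, 2), (2, 2)))
    win_g = sliding_window_view(gp, (3, 3, 3), axis=(2, 3, 4))
    Wf = W[:, :, ::-1, ::-1, ::-1]
    gx = np.tensordot(win_g, Wf, axes=([1, 5, 6, 7], [0, 2, 3, 4]))
    return np.ascontiguousarray(np.moveaxis(gx, -1, 1)), gW.astype(np.float32), gb.astype(np.float32)


class Conv3:
    """Valid 3x3x3 convolution (He-initialised)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 27))
        self.W = rng.normal(0.0, scale, (cout, cin, 3, 3, 3)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        return _conv3_forward(x, self.W, self.b)

    def backward(self, grad):
        gx, gW, gb = _conv3_backward(grad, self._x, self.W)
        self.gW[...] = gW  # in place: the optimiser holds references
        self.gb[...] = gb
        self._x = None
        return gx

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Conv1:
    """1x1x1 convolution (per-voxel linear map)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, scale, (cout, cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        out = np.tensordot(x, self.W, axes=([1], [1]))
        return np.ascontiguousarray(np.moveaxis(out, -1, 1)) + self.b[None, :, None, None, None]

    def backward(self, grad):
        self.gW[...] = np.tensordot(grad, self._x,
                                    axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        self.gb[...] = grad.sum(axis=(0, 2, 3, 4))
        gx = np.tensordot(grad, self.W, axes=([1], [0]))
        self._x = None
        return np.ascontiguousarray(np.moveaxis(gx, -1, 1))

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g

    def params(self):
        return []


def _pool2_forward(x):
    n, c, d, h, w = x.shape
    r = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5, 7))
    mask = r == out[:, :, :, None, :, None, :, None]
    return out, (mask, x.shape)


def _pool2_backward(grad, cache):
    mask, shape = cache
    cnt = mask.sum(axis=(3, 5, 7), keepdims=True)
    gr = mask * (grad[:, :, :, None, :, None, :, None] / cnt)
    return gr.reshape(shape).astype(np.float32)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)


def _upsample2_backward(grad):
    n, c, d, h, w = grad.shape
    r = grad.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    return r.sum(axis=(3, 5, 7))


def _center_crop(x, target_spatial):
    off = [(s - t) // 2 for s, t in zip(x.shape[2:], target_spatial)]
    sl = tuple(slice(o, o + t) for o, t in zip(off, target_spatial))
    return x[(slice(None), slice(None)) + sl], sl


def softmax(logits, axis=1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, target):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    ``target`` holds integer class indices with shape = logits without the
    channel axis.
    """
    p = softmax(logits.astype(np.float64))
    n_vox = target.size
    idx = np.indices(target.shape)
    picked = p[idx[0], target, idx[1], idx[2], idx[3]]
    loss = float(-np.mean(np.log(np.maximum(picked, 1e-12))))
    grad = p.copy()
    grad[idx[0], target, idx[1], idx[2], idx[3]] -= 1.0
    return loss, (grad / n_vox).astype(np.float32)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class _Block:
    """convs_per_block x (Conv3 -> ReLU)."""

    def __init__(self, cin, cout, k, rng):
        self.layers = []
        c = cin
        for _ in range(k):
            self.layers += [Conv3(c, cout, rng), ReLU()]
            c = cout

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class UNet3D:
    """Valid-convolution 3D U-Net mapping (N, C, D, H, W) patches to
    per-voxel class logits over the centred output window."""

    def __init__(self, in_channels: int, n_classes: int = 2, depth: int = 3,
                 convs_per_block: int = 2, base_filters: int = 16,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.depth = depth
        self.convs_per_block = convs_per_block
        self.base_filters = base_filters

        f = [base_filters * 2**l for l in range(depth + 1)]
        self.enc = []
        cin = in_channels
        for l in range(depth):
            self.enc.append(_Block(cin, f[l], convs_per_block, rng))
            cin = f[l]
        self.bottom = _Block(cin, f[depth], convs_per_block, rng)
        self.dec = []
        for l in reversed(range(depth)):
            self.dec.append(_Block(f[l + 1] + f[l], f[l], convs_per_block, rng))
        self.head = Conv1(f[0] if depth else f[depth], n_classes, rng)
        self._cache = None

    # -- graph ------------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips, pools = [], []
        for block in self.enc:
            x = block.forward(x)
            skips.append(x)
            x, cache = _pool2_forward(x)
            pools.append(cache)
        x = self.bottom.forward(x)
        crops = []
        for block, skip in zip(self.dec, reversed(skips)):
            x = _upsample2(x)
            cropped, sl = _center_crop(skip, x.shape[2:])
            crops.append((skip.shape, sl, cropped.shape[1]))
            x = np.concatenate([cropped, x], axis=1)
            x = block.forward(x)
        self._cache = (pools, crops)
        return self.head.forward(x)

    def backward(self, grad: np.ndarray) -> None:
        pools, crops = self._cache
        grad = self.head.backward(grad)
        skip_grads = []
        for block, (skip_shape, sl, c_skip) in zip(reversed(self.dec),
                                                   reversed(crops)):
            grad = block.backward(grad)
            g_skip, grad = grad[:, :c_skip], grad[:, c_skip:]
            full = np.zeros(skip_shape, dtype=np.float32)
            full[(slice(None), slice(None)) + sl] = g_skip
            skip_grads.append(full)
            grad = _upsample2_backward(grad)
        grad = self.bottom.backward(grad)
        for block, cache, g_skip in zip(reversed(self.enc), reversed(pools),
                                        skip_grads):
            grad = _pool2_backward(grad, cache)
            grad = grad + g_skip
            grad = block.backward(grad)
        self._cache = None

    def params(self):
        out = []
        for block in self.enc:
            out += block.params()
        out += self.bottom.params()
        for block in self.dec:
            out += block.params()
        out += self.head.params()
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of input patches."""
        return softmax(self.forward(x))

    # -- (de)serialisation -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": w for i, (w, _) in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (w, _) in enumerate(self.params()):
            w[...] = state[f"p{i}"]


class Adam:
    """Adam optimiser over (param, grad) pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
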
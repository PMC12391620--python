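"""A small, deterministic convolutional network implemented in NumPy.

This module provides exactly what the droplet classifiers need and nothing
more: 3×3 same-padding convolutions (im2col), ReLU, 2×2 max pooling, global
average pooling, linear classification heads with softmax cross-entropy, and
an Adam optimiser.  All randomness (initialisation, shuffling, augmentation)
flows through an explicit ``numpy.random.Generator``, so training is
bit-reproducible under a fixed seed on a given platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet", "Adam", "softmax", "cross_entropy_grad"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) → (N*H*W, C*9) patches of a 3×3 same-padding convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * 9)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        n, c, h, w = x.shape
        self.cols = _im2col(x)
        out = self.cols @ self.w.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_out, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        self.gw += g.T @ self.cols
        self.gb += g.sum(axis=0)
        # input gradient = convolution of grad with the flipped kernels
        c_in = self.x_shape[1]
        w_k = self.w.reshape(c_out, c_in, 3, 3)
        w_flip = w_k[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(c_in, c_out * 9)
        cols_g = _im2col(grad)
        dx = cols_g @ w_flip.T
        return dx.reshape(n, h, w, c_in).transpose(0, 3, 1, 2)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        self.idx = np.argmax(xr, axis=-1)
        self.in_shape = x.shape
        return np.take_along_axis(xr, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self.in_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self.idx[..., None], grad[..., None], axis=-1)
        return (
            out.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    def params(self):
        return []


class _GlobalAvgPool:
    def forward(self, x):
        self.in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self.in_shape
        return np.broadcast_to(grad[:, :, None, None], self.in_shape) / (h * w)

    def params(self):
        return []


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        self.x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.gw += grad.T @ self.x
        self.gb += grad.sum(axis=0)
        return grad @ self.w

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class ConvNet:
    """Conv-pool trunk(s) with one or more softmax classification heads.

    ``head_classes`` gives the number of classes of each head.  With
    ``shared_trunk=True`` (default) all heads read one trunk's pooled
    features; with ``False`` every head owns a full private trunk — the
    "parallel networks" configuration.
    """

    def __init__(
        self,
        in_channels: int,
        input_size: int,
        conv_channels: tuple[int, ...],
        head_classes: tuple[int, ...],
        rng: np.random.Generator,
        shared_trunk: bool = True,
    ):
        if input_size % (2 ** len(conv_channels)) != 0:
            raise ValueError("input_size must be divisible by 2^n_conv_blocks")
        self.in_channels = in_channels
        self.input_size = input_size
        self.conv_channels = tuple(conv_channels)
        self.head_classes = tuple(head_classes)
        self.shared_trunk = shared_trunk

        def make_trunk():
            layers = []
            c_prev = in_channels
            for c in conv_channels:
                layers += [_Conv3x3(c_prev, c, rng), _ReLU(), _MaxPool2()]
                c_prev = c
            layers.append(_GlobalAvgPool())
            return layers

        n_trunks = 1 if shared_trunk else len(head_classes)
        self.trunks = [make_trunk() for _ in range(n_trunks)]
        feat = conv_channels[-1]
        self.heads = [_Linear(feat, k, rng) for k in head_classes]

    # -- plumbing -----------------------------------------------------------
    def _run_trunk(self, trunk, x):
        for layer in trunk:
            x = layer.forward(x)
        return x

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Return one logits array per head for input (N,C,H,W)."""
        if x.shape[1:] != (self.in_channels, self.input_size, self.input_size):
            raise ValueError(
                f"expected input (N,{self.in_channels},{self.input_size},"
                f"{self.input_size}), got {x.shape}"
            )
        if self.shared_trunk:
            feat = self._run_trunk(self.trunks[0], x)
            return [h.forward(feat) for h in self.heads]
        return [
            h.forward(self._run_trunk(t, x)) for t, h in zip(self.trunks, self.heads)
        ]

    def backward(self, head_grads: list[np.ndarray]) -> None:
        if self.shared_trunk:
            gfeat = sum(h.backward(g) for h, g in zip(self.heads, head_grads))
            for layer in reversed(self.trunks[0]):
                gfeat = layer.backward(gfeat)
        else:
            for trunk, head, g in zip(self.trunks, self.heads, head_grads):
                gf = head.backward(g)
                for layer in reversed(trunk):
                    gf = layer.backward(gf)

    def params(self):
        out = []
        for trunk in self.trunks:
            for layer in trunk:
                out.extend(layer.params())
        for head in self.heads:
            out.extend(head.params())
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> list[np.ndarray]:
        """Per-head class probabilities, evaluated in batches."""
        chunks: list[list[np.ndarray]] = [[] for _ in self.heads]
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size])
            for k, lg in enumerate(logits):
                chunks[k].append(softmax(lg))
        return [np.concatenate(c, axis=0) for c in chunks]

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, (p, _) in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (p, _) in enumerate(self.params()):
            p[...] = arrays[f"p{i}"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
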
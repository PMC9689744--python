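"""Minimal numpy neural-network core for the 1D CNN family.

Layers operate on float32 batches.  Convolutions use stride 1 with same
padding; max pooling floors the length.  The network object owns its parameter
arrays; :class:`Adam` updates them in place.  Everything is deterministic
given the init seed and the data order, which makes seeded training runs
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Conv1D:
    """1D convolution, stride 1, same padding, weights (F, C, K)."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size < 3 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")
        fan_in = in_channels * kernel_size
        s = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-s, s, size=(filters, in_channels, kernel_size)).astype(DTYPE)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.k = kernel_size
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        win = sliding_window_view(xp, self.k, axis=2)  # (B, C, L, K)
        self._win = win if train else None
        self._in_len = x.shape[2]
        out = np.einsum("bclk,fck->bfl", win, self.W, optimize=True) + self.b[None, :, None]
        return out.astype(DTYPE, copy=False)

    def backward(self, go: np.ndarray) -> np.ndarray:
        win = self._win
        self.grads[0][...] = np.einsum("bclk,bfl->fck", win, go, optimize=True)
        self.grads[1][...] = go.sum(axis=(0, 2))
        tmp = np.einsum("bfl,fck->bclk", go, self.W, optimize=True)
        B, C, L, K = tmp.shape
        pad = self.k // 2
        dxp = np.zeros((B, C, L + 2 * pad), dtype=DTYPE)
        for k in range(K):
            dxp[:, :, k : k + L] += tmp[:, :, :, k]
        return dxp[:, :, pad : pad + self._in_len]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0)

    def backward(self, go):
        return go * self._mask


class MaxPool1D:
    """Non-overlapping max pooling; trailing remainder samples are dropped (floor)."""

    params: list = []
    grads: list = []

    def __init__(self, size: int = 2):
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size

    def forward(self, x, train=False):
        if self.size == 1:
            self._shape = None
            return x
        B, C, L = x.shape
        Lo = L // self.size
        xr = x[:, :, : Lo * self.size].reshape(B, C, Lo, self.size)
        idx = xr.argmax(axis=3)
        if train:
            self._idx, self._shape = idx, (B, C, L, Lo)
        out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        return out

    def backward(self, go):
        if self.size == 1:
            return go
        B, C, L, Lo = self._shape
        dx = np.zeros((B, C, Lo, self.size), dtype=DTYPE)
        np.put_along_axis(dx, self._idx[..., None], go[..., None], axis=3)
        dx = dx.reshape(B, C, Lo * self.size)
        if Lo * self.size < L:
            dx = np.pad(dx, ((0, 0), (0, 0), (0, L - Lo * self.size)))
        return dx


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, go):
        return go.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-s, s, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, go):
        self.grads[0][...] = self._x.T @ go
        self.grads[1][...] = go.sum(axis=0)
        return go @ self.W.T


class BatchNorm:
    """Batch normalization over the feature axis of a (B, D) activation."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim, dtype=DTYPE)
        self.beta = np.zeros(dim, dtype=DTYPE)
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
            self._xhat = (x - mu) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.running_mean) / np.sqrt(self.running_var + self.eps) + self.beta

    def backward(self, go):
        xhat, istd = self._xhat, self._istd
        B = go.shape[0]
        self.grads[0][...] = (go * xhat).sum(axis=0)
        self.grads[1][...] = go.sum(axis=0)
        dxhat = go * self.gamma
        return (istd / B) * (B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConcatNet:
    """One or two convolutional branches feeding a shared classifier head.

    Each branch: ``depth`` blocks of Conv1D -> ReLU -> MaxPool.  Branch outputs
    are flattened and concatenated along the feature axis, then batch-norm ->
    dense hidden (ReLU) -> dense logits; :meth:`predict_proba` applies softmax.
    Input batches have shape (B, n_branches, input_length).
    """

    def __init__(self, n_branches: int, depth: int, filters: tuple, kernel_size: int,
                 pool_size: int, hidden_units: int, n_classes: int, input_length: int,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_branches = n_branches
        self.input_length = input_length
        self.branches = []
        length = input_length
        for _ in range(n_branches):
            layers = []
            length = input_length
            cin = 1
            for f in filters[:depth]:
                layers.append(Conv1D(cin, f, kernel_size, rng))
                layers.append(ReLU())
                layers.append(MaxPool1D(pool_size))
                length //= pool_size
                cin = f
            layers.append(Flatten())
            self.branches.append(layers)
        branch_width = length * filters[depth - 1]
        self.fused_width = n_branches * branch_width
        self.head = [
            BatchNorm(self.fused_width),
            Dense(self.fused_width, hidden_units, rng),
            ReLU(),
            Dense(hidden_units, n_classes, rng),
        ]
        self.n_classes = n_classes

    # -- parameter access ---------------------------------------------------
    def _layers(self):
        for br in self.branches:
            yield from br
        yield from self.head

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

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state(self):
        """Copy of all weights and batch-norm running stats (for checkpointing)."""
        st = [p.copy() for p in self.parameters()]
        for layer in self._layers():
            if isinstance(layer, BatchNorm):
                st.append(layer.running_mean.copy())
                st.append(layer.running_var.copy())
        return st

    def load_state(self, st):
        params = self.parameters()
        for p, s in zip(params, st[: len(params)]):
            p[...] = s
        extra = st[len(params) :]
        i = 0
        for layer in self._layers():
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = extra[i]
                layer.running_var[...] = extra[i + 1]
                i += 2

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 3 or x.shape[1] != self.n_branches or x.shape[2] != self.input_length:
            raise ValueError(
                f"expected input of shape (B, {self.n_branches}, {self.input_length}), got {x.shape}"
            )
        feats = []
        for i, layers in enumerate(self.branches):
            h = x[:, i : i + 1, :]
            for layer in layers:
                h = layer.forward(h, train=train)
            feats.append(h)
        h = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        self._split = [f.shape[1] for f in feats]
        for layer in self.head:
            h = layer.forward(h, train=train)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def loss_and_grad(self, x: np.ndarray, y_onehot: np.ndarray, sample_weight=None):
        """Categorical cross-entropy on a batch; fills layer gradients."""
        logits = self.forward(x, train=True)
        p = softmax(logits)
        eps = 1e-12
        if sample_weight is None:
            loss = float(-(y_onehot * np.log(p + eps)).sum(axis=1).mean())
            go = ((p - y_onehot) / x.shape[0]).astype(DTYPE)
        else:
            w = sample_weight / sample_weight.sum()
            loss = float(-(w * (y_onehot * np.log(p + eps)).sum(axis=1)).sum())
            go = ((p - y_onehot) * w[:, None]).astype(DTYPE)
        h = go
        for layer in reversed(self.head):
            h = layer.backward(h)
        # split fused gradient back into branches
        offs = np.cumsum([0] + self._split)
        for i, layers in enumerate(self.branches):
            g = h[:, offs[i] : offs[i + 1]]
            for layer in reversed(layers):
                g = layer.backward(g)
        return loss


class Adam:
    """Adam optimizer updating the network's parameter arrays in place."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
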
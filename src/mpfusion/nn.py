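"""Compact seeded neural-network core (numpy).

Implements exactly the pieces the hierarchical classifier needs: 3x3
same-padding convolution (im2col), 2x2 max pooling, dense layers, ReLU,
softmax, cross-entropy, and Adam — all driven by a single
``numpy.random.Generator`` so that a fixed seed reproduces training
bit-for-bit.  Forward/backward passes are vectorised over the batch;
float32 throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPS_LOG = 1e-12


# ---------------------------------------------------------------------------
# activation / loss primitives


def relu(x):
    """Rectified linear unit, element-wise ``max(0, x)``."""
    return np.maximum(0, x)


def softmax(v, axis=-1):
    """Numerically stable softmax along ``axis``; invariant to constant shifts."""
    v = np.asarray(v, float)
    z = v - v.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(t, p):
    """Cross-entropy ``-sum_j t_j log p_j`` with probabilities clipped to
    ``[1e-12, 1]`` to guard ``log(0)``."""
    t = np.asarray(t, float)
    p = np.clip(np.asarray(p, float), EPS_LOG, 1.0)
    return float(-(t * np.log(p)).sum(axis=-1).mean())


# ---------------------------------------------------------------------------
# layers


class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, same padding, via im2col."""

    def __init__(self, in_ch, out_ch, rng, kernel=3):
        assert kernel % 2 == 1
        self.k = kernel
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = rng.normal(0.0, std, size=(fan_in, out_ch)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.in_ch, self.out_ch = in_ch, out_ch

    def _im2col(self, x):
        # (B*H*W, C*k*k) patch matrix; single contiguous copy, BLAS-friendly
        B, C, H, W = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * H * W, C * self.k * self.k)

    def forward(self, x):
        self.x_shape = x.shape
        self.col = self._im2col(x)
        B, C, H, W = x.shape
        out = self.col @ self.W + self.b
        return out.reshape(B, H, W, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout, need_dx=True):
        B, F, H, W = dout.shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(B * H * W, F)
        self.grads[0][...] = self.col.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        if not need_dx:  # first layer: input gradient is never consumed
            return None
        dcol = dflat @ self.W.T
        k, p = self.k, self.k // 2
        dcol = dcol.reshape(B, H, W, self.in_ch, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((B, self.in_ch, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcol[:, :, i, j]
        return dxp[:, :, p:p + H, p:p + W]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x):
        B, C, H, W = x.shape
        h, w = H // 2, W // 2
        self.x_shape = x.shape
        xc = x[:, :, :2 * h, :2 * w].reshape(B, C, h, 2, w, 2)
        flat = np.ascontiguousarray(xc.transpose(0, 1, 2, 4, 3, 5)).reshape(B, C, h, w, 4)
        self.arg = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self.arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        B, C, h, w = dout.shape
        dflat = np.zeros((B, C, h, w, 4), dtype=np.float32)
        np.put_along_axis(dflat, self.arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self.x_shape, dtype=np.float32)
        dxc = dflat.reshape(B, C, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx[:, :, :2 * h, :2 * w] = dxc.reshape(B, C, 2 * h, 2 * w)
        return dx


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class Flatten(Layer):
    def forward(self, x):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.x_shape)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng):
        std = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0.0, std, size=(in_dim, out_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self.x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Network:
    """A plain layer stack with a softmax cross-entropy head."""

    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def logits(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x, batch_size=256):
        x = np.asarray(x, np.float32)
        out = [softmax(self.logits(x[i:i + batch_size]))
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0) if out else np.empty((0, 2))

    def train_step(self, x, y, optimizer):
        """One minibatch of softmax cross-entropy backprop; returns the loss."""
        logits = self.logits(x)
        probs = softmax(logits)
        B = len(x)
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        loss = cross_entropy(onehot, probs)
        dout = ((probs - onehot) / B).astype(np.float32)
        first = self.layers[0]
        for layer in reversed(self.layers):
            if layer is first and isinstance(layer, Conv2D):
                layer.backward(dout, need_dx=False)
            else:
                dout = layer.backward(dout)
        optimizer.step(self.params, self.grads)
        return loss

    def params_digest(self) -> str:
        """SHA-256 over all parameter bytes — bit-level identity check."""
        h = hashlib.sha256()
        for p in self.params:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()


class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = None
        self.t = 0

    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    val_frac: float = 0.1
    patience: int = 5  # early-stopping patience on validation loss; 0 disables


def train_network(net: Network, X, y, config: TrainConfig, rng) -> pd.DataFrame:
    """Minibatch Adam training with an internal validation split and early
    stopping; returns the per-epoch log (epoch, train_loss, val_loss, val_acc)."""
    X = np.asarray(X, np.float32)
    y = np.asarray(y, np.int64)
    if len(X) == 0:
        raise ValueError("empty training set")
    n_val = int(round(config.val_frac * len(X))) if config.patience > 0 else 0
    order = rng.permutation(len(X))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]
    optimizer = Adam(lr=config.learning_rate)
    rows = []
    best_val = np.inf
    best_params = None
    stale = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(len(Xtr))
        losses = []
        for i in range(0, len(Xtr), config.batch_size):
            sel = perm[i:i + config.batch_size]
            losses.append(net.train_step(Xtr[sel], ytr[sel], optimizer))
        val_loss = val_acc = np.nan
        if n_val:
            probs = net.predict_proba(Xval)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yval)), yval] = 1.0
            val_loss = cross_entropy(onehot, probs)
            val_acc = float((probs.argmax(axis=1) == yval).mean())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "val_acc": val_acc})
        if n_val and config.patience > 0:
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = [p.copy() for p in net.params]
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_params is not None:
        for p, bp in zip(net.params, best_params):
            p[...] = bp
    return pd.DataFrame(rows)


def build_mlp(in_dim: int, hidden: int, n_classes: int, seed) -> Network:
    """One-hidden-layer feedforward classifier (ReLU hidden, softmax head)."""
    rng = np.random.default_rng(seed)
    return Network([Dense(in_dim, hidden, rng), ReLU(),
                    Dense(hidden, n_classes, rng)])
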
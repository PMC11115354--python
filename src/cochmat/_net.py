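"""Minimal convolutional network framework (numpy, explicit backprop).

Implements exactly what the training module needs: 2-D convolutions (im2col),
ReLU, 2x2 max pooling, global average pooling, fully connected layers,
residual blocks, softmax cross-entropy and plain SGD.  Everything is float32
and seeded, so training runs are bit-reproducible on one thread.

Two architectures are provided: a small 4-conv network trainable at desk
scale with batch size 1, and an 18-layer residual network whose 20
convolutional layers (initial 7x7, sixteen 3x3 block convolutions, three 1x1
projection shortcuts) are exposed for layerwise probing.  The residual
variant omits batch normalization: training here uses batch size 1, where
batch statistics are degenerate, and the probing analyses need deterministic
post-activation responses.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seeds import substream

DTYPE = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv2d:
    """k x k convolution with symmetric zero padding and stride."""

    def __init__(self, cin, cout, k, stride=1, pad=None, rng=None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.W = (rng.standard_normal((cout, cin, k, k)) * std).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x):
        B, C, H, Wd = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        B, C, Ho, Wo, _, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k)
        self._cols, self._xshape, self._out_hw = cols, x.shape, (Ho, Wo)
        out = cols @ self.W.reshape(self.cout, -1).T + self.b
        return out.transpose(0, 2, 1).reshape(B, self.cout, Ho, Wo).astype(DTYPE, copy=False)

    def backward(self, dout):
        B, _, Ho, Wo = dout.shape
        k, s, p = self.k, self.stride, self.pad
        dmat = dout.reshape(B, self.cout, Ho * Wo).transpose(0, 2, 1)  # (B, HW, cout)
        self.gW += np.einsum("bno,bni->oi", dmat, self._cols).reshape(self.W.shape)
        self.gb += dmat.sum(axis=(0, 1))
        dcols = dmat @ self.W.reshape(self.cout, -1)  # (B, HW, C*k*k)
        _, C, H, Wd = self._xshape
        dcols = dcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((B, C, H + 2 * p, Wd + 2 * p), dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + s * Ho : s, dj : dj + s * Wo : s] += dcols[:, :, di, dj]
        return dxp[:, :, p : p + H, p : p + Wd] if p else dxp


class ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2x2, stride-2 max pooling; trailing odd row/column dropped."""

    def params(self):
        return []

    def forward(self, x):
        B, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xt = x[:, :, : 2 * Ho, : 2 * Wo].reshape(B, C, Ho, 2, Wo, 2)
        win = xt.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, 4)
        idx = win.argmax(axis=-1)
        self._idx, self._xshape = idx, x.shape
        return np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        B, C, H, W = self._xshape
        Ho, Wo = H // 2, W // 2
        dwin = np.zeros((B, C, Ho, Wo, 4), dtype=DTYPE)
        np.put_along_axis(dwin, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._xshape, dtype=DTYPE)
        dx[:, :, : 2 * Ho, : 2 * Wo] = (
            dwin.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, 2 * Ho, 2 * Wo)
        )
        return dx


class GlobalAvgPool:
    def params(self):
        return []

    def forward(self, x):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        B, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / self._hw


class Flatten:
    def params(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear:
    def __init__(self, nin, nout, rng):
        std = np.sqrt(1.0 / nin)
        self.W = (rng.standard_normal((nout, nin)) * std).astype(DTYPE)
        self.b = np.zeros(nout, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.gW += dout.T @ self._x
        self.gb += dout.sum(axis=0)
        return dout @ self.W


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy loss over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    B = logits.shape[0]
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(B), targets] + eps)))
    g = p.copy()
    g[np.arange(B), targets] -= 1.0
    return loss, (g / B).astype(DTYPE)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class _BaseNet:
    conv_layer_ids: list[str]

    def parameters(self):
        out = []
        for layer in self._param_layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0

    def sgd_step(self, lr: float):
        for p, g in self.parameters():
            p -= lr * g

    def clone(self):
        import copy

        return copy.deepcopy(self)

    def forward(self, x):
        return self.forward_probes(x, probes=False)[0]


class ReducedNet(_BaseNet):
    """Four 3x3 conv blocks (conv-ReLU-maxpool) and a linear classifier.

    Probe ids ``conv1..conv4`` expose the flattened post-ReLU response of
    each convolution.
    """

    architecture = "reduced"

    def __init__(self, n_classes: int, init_seed: int = 0, widths=(8, 16, 32, 32), input_hw=(100, 100)):
        rng = substream(init_seed, "net-init")
        self.n_classes = n_classes
        self.convs, self.relus, self.pools = [], [], []
        cin = 1
        h, w = input_hw
        for cout in widths:
            self.convs.append(Conv2d(cin, cout, 3, rng=rng))
            self.relus.append(ReLU())
            self.pools.append(MaxPool2())
            cin = cout
            h, w = h // 2, w // 2
        self.flatten = Flatten()
        self.fc = Linear(widths[-1] * h * w, n_classes, rng)
        self.conv_layer_ids = [f"conv{i + 1}" for i in range(len(widths))]

    def _param_layers(self):
        return [*self.convs, self.fc]

    def forward_probes(self, x, probes=True):
        acts = {}
        h = x.astype(DTYPE, copy=False)
        for i, (conv, relu, pool) in enumerate(zip(self.convs, self.relus, self.pools)):
            h = relu.forward(conv.forward(h))
            if probes:
                acts[f"conv{i + 1}"] = h.reshape(h.shape[0], -1).copy()
            h = pool.forward(h)
        logits = self.fc.forward(self.flatten.forward(h))
        return logits, acts

    def backward(self, dlogits):
        d = self.flatten.backward(self.fc.backward(dlogits))
        for conv, relu, pool in zip(reversed(self.convs), reversed(self.relus), reversed(self.pools)):
            d = conv.backward(relu.backward(pool.backward(d)))
        return d


class _BasicBlock:
    """Two 3x3 convolutions with an identity or 1x1-projection shortcut."""

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.relu2 = ReLU()
        self.down = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng) if (stride != 1 or cin != cout) else None

    def layers(self):
        out = [self.conv1, self.conv2]
        if self.down is not None:
            out.append(self.down)
        return out

    def forward(self, x, acts, ids, probes):
        h = self.relu1.forward(self.conv1.forward(x))
        if probes:
            acts[ids[0]] = h.reshape(h.shape[0], -1).copy()
        h2 = self.conv2.forward(h)
        idn = self.down.forward(x) if self.down is not None else x
        if probes and self.down is not None:
            acts[ids[2]] = idn.reshape(idn.shape[0], -1).copy()
        out = self.relu2.forward(h2 + idn)
        if probes:
            acts[ids[1]] = out.reshape(out.shape[0], -1).copy()
        return out

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dx = self.down.backward(d) if self.down is not None else d
        d1 = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return dx + d1


class ResNet18(_BaseNet):
    """18-layer residual network exposing 20 convolutional probe layers.

    conv1 (7x7, stride 2) + 16 block convolutions + 3 projection shortcuts.
    Kept for structural fidelity with full-scale replication runs; desk-scale
    training uses :class:`ReducedNet`.
    """

    architecture = "resnet18"

    def __init__(self, n_classes: int, init_seed: int = 0):
        rng = substream(init_seed, "net-init")
        self.n_classes = n_classes
        self.conv1 = Conv2d(1, 64, 7, stride=2, pad=3, rng=rng)
        self.relu1 = ReLU()
        self.pool1 = MaxPool2()
        plan = [(64, 64, 1), (64, 64, 1), (64, 128, 2), (128, 128, 1),
                (128, 256, 2), (256, 256, 1), (256, 512, 2), (512, 512, 1)]
        self.blocks = [_BasicBlock(ci, co, s, rng) for ci, co, s in plan]
        self.gap = GlobalAvgPool()
        self.fc = Linear(512, n_classes, rng)
        # probe ids in forward order
        self.conv_layer_ids = ["conv1"]
        self._block_ids = []
        n = 1
        for blk in self.blocks:
            ids = [f"conv{n + 1}", f"conv{n + 2}"]
            n += 2
            if blk.down is not None:
                ids.append(f"conv{n + 1}")
                n += 1
            self._block_ids.append(ids)
            self.conv_layer_ids.extend(ids)

    def _param_layers(self):
        out = [self.conv1]
        for blk in self.blocks:
            out.extend(blk.layers())
        out.append(self.fc)
        return out

    def forward_probes(self, x, probes=True):
        acts = {}
        h = self.relu1.forward(self.conv1.forward(x.astype(DTYPE, copy=False)))
        if probes:
            acts["conv1"] = h.reshape(h.shape[0], -1).copy()
        h = self.pool1.forward(h)
        for blk, ids in zip(self.blocks, self._block_ids):
            h = blk.forward(h, acts, ids, probes)
        logits = self.fc.forward(self.gap.forward(h))
        return logits, acts

    def backward(self, dlogits):
        d = self.gap.backward(self.fc.backward(dlogits))
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        return self.conv1.backward(self.relu1.backward(self.pool1.backward(d)))
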
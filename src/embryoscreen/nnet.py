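"""A compact CPU neural-network engine for the time-conditioned classifier.

Implements exactly the pieces the classifier needs: 2-D convolutions
(im2col + BLAS matmul), ReLU, max pooling, residual blocks, global pooling,
a dense head, softmax cross-entropy and Adam — all in numpy with explicit
forward/backward passes and a single seeded initializer.

Two backbone presets share the same contract: a 4-channel input whose 4th
plane is the constant timestamp tau, a final convolutional feature stack
exposed for class-activation mapping, global pooling (max by default), and
a fully connected classification layer that receives tau concatenated to
the pooled features.

* ``tinycnn_timed`` - three conv/pool stages (8/16/32 planes); the desk-scale
  backbone used in tests.
* ``resnet18_timed`` - a ResNet18-style residual network (four stages of two
  basic blocks, 64..512 planes, no batch normalization) for larger runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TimedCNN", "build_backbone", "softmax", "Adam"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# layers


class _Layer:
    def params(self):  # list of [weight, grad] pairs
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(_Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, OH, OW, k, k) -> (N*OH*OW, C*k*k)
        self._oh, self._ow = sw.shape[2], sw.shape[3]
        cols = sw.transpose(0, 2, 3, 1, 4, 5).reshape(-1, C * k * k)
        self._cols = cols
        self._xshape = x.shape
        y = cols @ self.W.T + self.b
        return y.reshape(N, self._oh, self._ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._xshape
        k, s, p = self.k, self.stride, self.pad
        oh, ow = self._oh, self._ow
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.dW += dyf.T @ self._cols
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.W).reshape(N, oh, ow, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki: ki + s * oh: s, kj: kj + s * ow: s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p: p + H, p: p + W] if p else dxp


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(_Layer):
    """2x2 max pooling, stride 2 (trailing odd row/col dropped)."""

    def forward(self, x):
        N, C, H, W = x.shape
        h2, w2 = H // 2, W // 2
        xr = x[:, :, : h2 * 2, : w2 * 2].reshape(N, C, h2, 2, w2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, h2, w2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        N, C, H, W = self._shape
        h2, w2 = H // 2, W // 2
        dxr = np.zeros((N, C, h2, w2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(N, C, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((N, C, H, W))
        dx[:, :, : h2 * 2, : w2 * 2] = dxr.reshape(N, C, h2 * 2, w2 * 2)
        return dx


class BasicBlock(_Layer):
    """Two 3x3 convs with identity (or 1x1-projected) skip connection."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.proj = (Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
                     if (stride != 1 or cin != cout) else None)
        self.relu2 = ReLU()

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(y + skip)

    def backward(self, dy):
        dy = self.relu2.backward(dy)
        dskip = self.proj.backward(dy) if self.proj is not None else dy
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(dy)))
        return dx + dskip


class Dense(_Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), (cout, cin))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W


# ---------------------------------------------------------------------------
# the time-conditioned model


class TimedCNN:
    """Conv feature stack + global pooling + tau-concatenated dense head.

    Input images are (N, 4, H, W) with the 4th plane constant per example
    (the timestamp tau); the same tau is concatenated to the pooled feature
    vector before the final dense layer.
    """

    def __init__(self, preset: str, feature_layers: list[_Layer],
                 n_features: int, n_classes: int, input_size: int,
                 head_pool: str = "max",
                 rng: np.random.Generator | None = None):
        if head_pool not in ("max", "avg"):
            raise ValueError("head_pool must be 'max' or 'avg'")
        self.preset = preset
        self.feature_layers = feature_layers
        self.n_features = n_features
        self.n_classes = n_classes
        self.input_size = input_size
        self.head_pool = head_pool
        self.fc = Dense(n_features + 1, n_classes, rng=rng)

    # -- plumbing -------------------------------------------------------
    def params(self):
        out = []
        for layer in self.feature_layers:
            out += layer.params()
        return out + self.fc.params()

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    @property
    def class_weights(self) -> np.ndarray:
        """Final-layer weights over feature planes (tau weight excluded)."""
        return self.fc.W[:, : self.n_features]

    # -- forward / backward --------------------------------------------
    @staticmethod
    def make_input(images: np.ndarray, taus: np.ndarray) -> np.ndarray:
        """Stack grayscale or RGB images and a constant tau plane to 4 channels."""
        images = np.asarray(images, dtype=float)
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        if images.ndim == 2:
            images = images[None]
        if images.ndim == 3:  # grayscale replicated to 3 planes
            images = np.repeat(images[:, None], 3, axis=1)
        elif images.ndim == 4 and images.shape[-1] == 3:  # HWC -> CHW
            images = images.transpose(0, 3, 1, 2)
        n, _, h, w = images.shape
        tplane = np.broadcast_to(taus[:, None, None, None], (n, 1, h, w))
        return np.concatenate([images, tplane], axis=1)

    def features(self, x4: np.ndarray) -> np.ndarray:
        """Final conv feature maps (N, n_features, h, w)."""
        y = x4
        for layer in self.feature_layers:
            y = layer.forward(y)
        return y

    def forward(self, x4: np.ndarray) -> np.ndarray:
        """Logits (N, n_classes); caches activations for backward()."""
        feats = self.features(x4)
        N, C, h, w = feats.shape
        flat = feats.reshape(N, C, h * w)
        if self.head_pool == "max":
            self._pool_idx = flat.argmax(axis=2)
            pooled = flat.max(axis=2)
        else:
            pooled = flat.mean(axis=2)
        self._feat_shape = feats.shape
        tau = x4[:, 3, 0, 0]
        z = np.concatenate([pooled, tau[:, None]], axis=1)
        return self.fc.forward(z)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.fc.backward(dlogits)
        dpooled = dz[:, : self.n_features]  # tau is an input, not a parameter
        N, C, h, w = self._feat_shape
        if self.head_pool == "max":
            dflat = np.zeros((N, C, h * w))
            np.put_along_axis(dflat, self._pool_idx[..., None],
                              dpooled[..., None], axis=2)
        else:
            dflat = np.broadcast_to(dpooled[..., None] / (h * w),
                                    (N, C, h * w)).copy()
        dy = dflat.reshape(N, C, h, w)
        for layer in reversed(self.feature_layers):
            dy = layer.backward(dy)

    def predict_proba(self, images: np.ndarray, taus) -> np.ndarray:
        """Softmax probabilities for unit-range images and timestamps."""
        return softmax(self.forward(self.make_input(images, taus)))

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path, sidecar_extra: dict | None = None) -> None:
        """Weights (npz) plus a JSON sidecar with the architecture metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": w for i, (w, _) in enumerate(self.params())}
        np.savez(directory / "weights.npz", **arrays)
        meta = {"preset": self.preset, "n_classes": self.n_classes,
                "input_size": self.input_size, "head_pool": self.head_pool}
        meta.update(sidecar_extra or {})
        (directory / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> tuple["TimedCNN", dict]:
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = build_backbone(meta["preset"], meta["n_classes"],
                               meta["input_size"], seed=0,
                               head_pool=meta.get("head_pool", "max"))
        data = np.load(directory / "weights.npz")
        for i, (w, _) in enumerate(model.params()):
            w[...] = data[f"p{i}"]
        return model, meta


def build_backbone(preset: str, n_classes: int, input_size: int,
                   seed: int = 0, head_pool: str = "max") -> TimedCNN:
    """Construct a preset backbone with seeded initialization."""
    rng = np.random.default_rng(seed)
    if preset == "tinycnn_timed":
        # four conv/pool stages: the last two are nearly free at small
        # spatial size but extend the receptive field past the motif scale
        layers: list[_Layer] = [
            Conv2d(4, 12, rng=rng), ReLU(), MaxPool2d(),
            Conv2d(12, 24, rng=rng), ReLU(), MaxPool2d(),
            Conv2d(24, 48, rng=rng), ReLU(), MaxPool2d(),
            Conv2d(48, 64, rng=rng), ReLU(), MaxPool2d(),
        ]
        return TimedCNN(preset, layers, 64, n_classes, input_size,
                        head_pool, rng)
    if preset == "resnet18_timed":
        layers = [Conv2d(4, 64, k=7, stride=2, pad=3, rng=rng), ReLU(),
                  MaxPool2d()]
        cin = 64
        for cout, first_stride in ((64, 1), (128, 2), (256, 2), (512, 2)):
            layers.append(BasicBlock(cin, cout, first_stride, rng=rng))
            layers.append(BasicBlock(cout, cout, 1, rng=rng))
            cin = cout
        return TimedCNN(preset, layers, 512, n_classes, input_size,
                        head_pool, rng)
    raise ValueError(f"unknown backbone preset {preset!r}")


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
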
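"""Minimal 3D conv-net in NumPy (forward + backward) for patch classification.

Implements exactly the architecture used for dPVS false-positive refinement:
3x3x3 convolutions ("same" padding, so two convs + one 2x2x2 max-pool halve
the side exactly: 24 -> 12 -> 6), channels 8/16/32/32, ReLU after every conv,
one fully connected layer of 128 nodes, 3-way softmax output trained with
cross-entropy. Convolutions run as im2col matrix products in float32;
optimization is plain SGD with momentum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["NetworkSpec", "Conv3DClassifier", "softmax"]


@dataclass(frozen=True)
class NetworkSpec:
    conv_channels: tuple[int, int, int, int] = (8, 16, 32, 32)
    kernel: int = 3
    fc_nodes: int = 128
    n_classes: int = 3
    input_side: int = 24

    def __post_init__(self) -> None:
        if self.kernel != 3:
            raise ValueError("only 3x3x3 kernels are supported")
        if len(self.conv_channels) != 4:
            raise ValueError("expected four convolutional layers")
        if self.input_side % 4 != 0:
            raise ValueError("input side must be divisible by 4 (two 2x2x2 pools)")

    @property
    def flat_features(self) -> int:
        side = self.input_side // 4
        return self.conv_channels[-1] * side**3


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,D,H,W) -> (N*D*H*W, C*27) patches under same padding."""
    n, c, d, h, w = x.shape
    xp = np.zeros((n, c, d + 2, h + 2, w + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1, 1:-1] = x
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
    # (N,C,D,H,W,3,3,3) -> (N,D,H,W,C,3,3,3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    return cols.reshape(n * d * h * w, c * 27)


def _col2im(dcols: np.ndarray, shape) -> np.ndarray:
    n, c, d, h, w = shape
    dc = dcols.reshape(n, d, h, w, c, 3, 3, 3)
    dpad = np.zeros((n, c, d + 2, h + 2, w + 2), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                dpad[:, :, i : i + d, j : j + h, k : k + w] += dc[:, :, :, :, :, i, j, k].transpose(
                    0, 4, 1, 2, 3
                )
    return dpad[:, :, 1:-1, 1:-1, 1:-1]


class _Conv3D:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 27
        self.W = (rng.normal(size=(c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        n, c, d, h, w = x.shape
        out = self._cols @ self.W.T + self.b
        return out.reshape(n, d, h, w, -1).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, co, d, h, w = dout.shape
        d2 = dout.transpose(0, 2, 3, 4, 1).reshape(-1, co)
        self.dW = d2.T @ self._cols
        self.db = d2.sum(axis=0)
        dcols = d2 @ self.W
        self._cols = None
        return _col2im(dcols, self._shape)

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    def forward(self, x):
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        mask = xr == out[:, :, :, None, :, None, :, None]
        # split gradient among ties so pooled gradients are conserved
        self._mask = (mask / mask.sum(axis=(3, 5, 7), keepdims=True)).astype(x.dtype)
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, d, h, w = self._shape
        dx = self._mask * dout[:, :, :, None, :, None, :, None]
        return dx.reshape(n, c, d, h, w)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.normal(size=(n_out, n_in)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W


class Conv3DClassifier:
    """Patch classifier with the fixed conv/pool/FC layout described above."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        self.spec = spec or NetworkSpec()
        rng = np.random.default_rng(seed)
        ch = self.spec.conv_channels
        self.conv1 = _Conv3D(1, ch[0], rng)
        self.conv2 = _Conv3D(ch[0], ch[1], rng)
        self.conv3 = _Conv3D(ch[1], ch[2], rng)
        self.conv4 = _Conv3D(ch[2], ch[3], rng)
        self.pool1, self.pool2 = _MaxPool2(), _MaxPool2()
        self.r1, self.r2, self.r3, self.r4, self.r5 = (_ReLU() for _ in range(5))
        self.fc1 = _Dense(self.spec.flat_features, self.spec.fc_nodes, rng)
        self.fc2 = _Dense(self.spec.fc_nodes, self.spec.n_classes, rng)
        self._velocity = {}

    # ---- forward/backward -------------------------------------------------
    def forward(self, patches: np.ndarray) -> np.ndarray:
        """patches: (N, side, side, side) -> logits (N, n_classes)."""
        s = self.spec.input_side
        if patches.shape[1:] != (s, s, s):
            raise ValueError(f"expected {s}^3 patches, got {patches.shape[1:]}")
        x = patches[:, None].astype(np.float32)
        x = self.r1.forward(self.conv1.forward(x))
        x = self.r2.forward(self.conv2.forward(x))
        x = self.pool1.forward(x)
        x = self.r3.forward(self.conv3.forward(x))
        x = self.r4.forward(self.conv4.forward(x))
        x = self.pool2.forward(x)
        self._flat_shape = x.shape
        x = x.reshape(x.shape[0], -1)
        x = self.r5.forward(self.fc1.forward(x))
        return self.fc2.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.fc2.backward(dlogits.astype(np.float32))
        dx = self.fc1.backward(self.r5.backward(dx))
        dx = dx.reshape(self._flat_shape)
        dx = self.pool2.backward(dx)
        dx = self.conv4.backward(self.r4.backward(dx))
        dx = self.conv3.backward(self.r3.backward(dx))
        dx = self.pool1.backward(dx)
        dx = self.conv2.backward(self.r2.backward(dx))
        self.conv1.backward(self.r1.backward(dx))

    def loss_and_grad(self, patches: np.ndarray, labels: np.ndarray) -> float:
        """Mean cross-entropy; also backpropagates gradients. labels are 0-based."""
        logits = self.forward(patches)
        p = softmax(logits)
        n = len(labels)
        loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
        dlogits = p
        dlogits[np.arange(n), labels] -= 1.0
        self.backward(dlogits / n)
        return loss

    def sgd_step(self, lr: float, momentum: float = 0.9) -> None:
        for name, layer in self._layers():
            for pname in ("W", "b"):
                g = getattr(layer, "d" + pname)
                key = (name, pname)
                v = self._velocity.get(key)
                v = momentum * v - lr * g if v is not None else -lr * g
                self._velocity[key] = v
                setattr(layer, pname, getattr(layer, pname) + v)

    def _layers(self):
        return [
            ("conv1", self.conv1),
            ("conv2", self.conv2),
            ("conv3", self.conv3),
            ("conv4", self.conv4),
            ("fc1", self.fc1),
            ("fc2", self.fc2),
        ]

    # ---- inference & serialization ---------------------------------------
    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return softmax(self.forward(patches))

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Predicted class codes in {1, 2, 3}."""
        return self.predict_proba(patches).argmax(axis=1) + 1

    def save(self, path) -> None:
        arrays = {}
        for name, layer in self._layers():
            arrays[name + "_W"] = layer.W
            arrays[name + "_b"] = layer.b
        np.savez(path, spec=json.dumps(asdict(self.spec)), **arrays)

    @classmethod
    def load(cls, path) -> "Conv3DClassifier":
        data = np.load(path, allow_pickle=False)
        spec_dict = json.loads(str(data["spec"]))
        spec_dict["conv_channels"] = tuple(spec_dict["conv_channels"])
        model = cls(NetworkSpec(**spec_dict))
        for name, layer in model._layers():
            layer.W = data[name + "_W"]
            layer.b = data[name + "_b"]
        return model
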
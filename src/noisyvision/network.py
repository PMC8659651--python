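"""A small configurable convolutional network implemented in numpy.

The network follows the classic feedforward taxonomy -- convolution +
rectification blocks with interleaved max-pooling, fully connected layers,
and a softmax output -- so that the layer-specific analyses (noise
susceptibility, weight CCA, relevance propagation) can address "convolutional
layers after rectification, fully connected layers, and the softmax layer"
exactly as they would on a large vision network, while training in minutes
on a CPU.

Layers expose their linear structure (an ``(out, in)`` weight matrix acting
on im2col patches for convolutions) which the attribution module reuses to
apply z-rule relevance propagation per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Conv2D", "MaxPool2D", "Dense", "SmallCNN", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*kh*kw) patches for stride-1 'same' conv."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    return np.ascontiguousarray(win).reshape(n, h * w, c * kh * kw)


def _col2im(cols: np.ndarray, shape, kh: int, kw: int) -> np.ndarray:
    """Scatter-add patch gradients back to image positions (adjoint of _im2col)."""
    n, c, h, w = shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    cols = cols.reshape(n, h, w, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return out[:, :, ph : ph + h, pw : pw + w]


class Conv2D:
    """3x3 (or kxk) stride-1 'same' convolution followed by ReLU."""

    kind = "conv"

    def __init__(self, in_channels, out_channels, ksize=3, rng=None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ksize = ksize
        fan_in = in_channels * ksize * ksize
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.b = np.zeros(out_channels)

    @property
    def weight_matrix(self) -> np.ndarray:
        """(units, flattened incoming weights) view of the kernel bank."""
        return self.w

    def forward(self, x, cache=None):
        n, c, h, w = x.shape
        patches = _im2col(x, self.ksize, self.ksize)
        z = patches @ self.w.T + self.b
        out = np.maximum(z, 0.0).reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)
        if cache is not None:
            cache["patches"] = patches
            cache["z"] = z
            cache["x_shape"] = x.shape
        return out

    def backward(self, cache, dout):
        n, co, h, w = dout.shape
        dz = dout.transpose(0, 2, 3, 1).reshape(n, h * w, co)
        dz = dz * (cache["z"] > 0)
        self.dw = np.einsum("npo,npf->of", dz, cache["patches"]) / n
        self.db = dz.sum(axis=(0, 1)) / n
        dpatches = dz @ self.w
        return _col2im(dpatches, cache["x_shape"], self.ksize, self.ksize)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class MaxPool2D:
    """2x2 max-pooling with stride 2."""

    kind = "pool"

    def forward(self, x, cache=None):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if cache is not None:
            cache["idx"] = idx
            cache["x_shape"] = x.shape
        return out

    def unpool(self, cache, grad_out):
        """Route values back to the pooling winners (used by backprop and LRP)."""
        n, c, h, w = cache["x_shape"]
        r = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(r, cache["idx"][..., None], grad_out[..., None], axis=-1)
        r = r.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return r.reshape(n, c, h, w)

    def backward(self, cache, dout):
        return self.unpool(cache, dout)

    def params(self):
        return []


class Dense:
    """Fully connected layer, optionally followed by ReLU."""

    kind = "dense"

    def __init__(self, in_features, out_features, relu=True, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features) if relu else np.sqrt(1.0 / in_features)
        self.w = rng.normal(0.0, scale, size=(out_features, in_features))
        self.b = np.zeros(out_features)
        self.relu = relu

    @property
    def weight_matrix(self) -> np.ndarray:
        return self.w

    def forward(self, x, cache=None):
        z = x @ self.w.T + self.b
        out = np.maximum(z, 0.0) if self.relu else z
        if cache is not None:
            cache["x"] = x
            cache["z"] = z
        return out

    def backward(self, cache, dout):
        dz = dout * (cache["z"] > 0) if self.relu else dout
        n = dz.shape[0]
        self.dw = dz.T @ cache["x"] / n
        self.db = dz.sum(axis=0) / n
        return dz @ self.w

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


@dataclass
class SmallCNN:
    """B conv/ReLU blocks with max-pooling, two FC layers, softmax output.

    The default (4 blocks, canvas 64) keeps an early pooling stage -- so
    representations from block 2 onward pool over space like complex cells --
    while remaining trainable from scratch in minutes.  Input preprocessing
    (training-stream mean/SD standardisation) is frozen into the model.
    """

    canvas: int = 64
    n_classes: int = 4
    channels: tuple = (8, 16, 16, 32)
    fc_units: int = 64
    seed: int = 0
    input_mean: float = 127.5
    input_sd: float = 64.0
    layers: list = field(default_factory=list, repr=False)
    layer_names: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.layers:
            return
        rng = np.random.default_rng(self.seed)
        c_in, size = 1, self.canvas
        for i, c_out in enumerate(self.channels, start=1):
            self.layers.append((f"conv{i}", Conv2D(c_in, c_out, rng=rng)))
            self.layers.append((f"pool{i}", MaxPool2D()))
            c_in, size = c_out, size // 2
        flat = c_in * size * size
        self.layers.append((f"fc1", Dense(flat, self.fc_units, relu=True, rng=rng)))
        self.layers.append((f"fc2", Dense(self.fc_units, self.n_classes, relu=False, rng=rng)))
        self.layer_names = [name for name, _ in self.layers]

    # -- forward passes ---------------------------------------------------

    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """(N, H, W) raw-intensity images -> standardized (N, 1, H, W)."""
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[-1] != self.canvas or x.shape[-2] != self.canvas:
            raise ValueError(
                f"image shape {x.shape[-2:]} does not match canvas {self.canvas}"
            )
        return ((x - self.input_mean) / self.input_sd)[:, None, :, :]

    def forward(self, x: np.ndarray, caches=None) -> np.ndarray:
        """Standardized input -> softmax probabilities (N, K)."""
        h = x
        for name, layer in self.layers:
            cache = {} if caches is not None else None
            if layer.kind == "dense" and h.ndim == 4:
                if cache is not None:
                    cache["flattened_from"] = h.shape
                h = h.reshape(h.shape[0], -1)
            h = layer.forward(h, cache)
            if caches is not None:
                caches.append((name, layer, cache))
        return softmax(h)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.forward(self.preprocess(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    def forward_activations(self, image: np.ndarray) -> dict:
        """Per-layer flattened activation vectors for one image.

        Returns post-rectification activations for conv and FC layers plus
        the softmax output, keyed by layer name in network order.
        """
        x = self.preprocess(image)
        acts = {}
        h = x
        for name, layer in self.layers:
            if layer.kind == "dense" and h.ndim == 4:
                h = h.reshape(h.shape[0], -1)
            h = layer.forward(h)
            if layer.kind in ("conv", "dense"):
                acts[name] = h.reshape(-1).copy()
        acts["softmax"] = softmax(h).reshape(-1)
        return acts

    @property
    def analysis_layers(self) -> list:
        """Names of the layers addressed by susceptibility/RSA analyses."""
        return [f"conv{i+1}" for i in range(len(self.channels))] + ["fc1", "fc2", "softmax"]

    # -- parameterized-layer access (weight CCA, LRP schedules) -----------

    @property
    def parameterized_layers(self) -> list:
        return [(n, l) for n, l in self.layers if l.kind in ("conv", "dense")]

    def get_layer(self, name: str):
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(name)

    # -- persistence ------------------------------------------------------

    def state_dict(self) -> dict:
        state = {"__meta__": np.array([self.input_mean, self.input_sd])}
        for name, layer in self.parameterized_layers:
            state[f"{name}.w"] = layer.w
            state[f"{name}.b"] = layer.b
        return state

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load_state(self, state):
        self.input_mean, self.input_sd = (float(v) for v in state["__meta__"])
        for name, layer in self.parameterized_layers:
            layer.w = np.array(state[f"{name}.w"])
            layer.b = np.array(state[f"{name}.b"])
        return self

    @classmethod
    def from_file(cls, path, **kwargs):
        model = cls(**kwargs)
        with np.load(path) as state:
            model.load_state(state)
        return model

    def copy(self) -> "SmallCNN":
        clone = SmallCNN(
            canvas=self.canvas, n_classes=self.n_classes, channels=self.channels,
            fc_units=self.fc_units, seed=self.seed,
        )
        clone.load_state(self.state_dict())
        return clone
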
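"""Spectral-spatial CNN for per-pixel tissue classification.

The network consumes 5 x 5 x 100 hypercube sub-volumes (one input channel)
and emits two class scores.  Its layer stack interleaves 3 x 3 x 3
spectral-spatial convolutions with "pooling" layers that are themselves
trainable 1-D convolutions along the spectral axis with stride 2, so every
hidden layer is learned:

    Conv1 (3x3x3, 20) - ReLU - Pool1 (k3 s2, 20) -
    Conv2 (3x3x3, 35) - ReLU - Pool2 (k3 s2, 35) -
    Conv3 (k3 s1, 35) - ReLU - Pool3 (k2 s2, 35) - ReLU - FC (455 -> 2)

Spatial convolutions are unpadded (5 -> 3 -> 1); spectral convolutions are
same-padded and pooling strides use one-sided padding with floor division,
giving the spectral trace 100 -> 50 -> 25 -> 13 and a 35 x 13 = 455-feature
input to the fully connected head.  Total trainable parameters: 31,532.

Layers are implemented directly on NumPy with explicit forward and backward
passes.  Activations use a channels-last (n, spectral, row, col, channel)
layout and each convolution is lowered to a single large sgemm: sub-volume
slices are gathered once per spectral tap and multiplied against an
expanded weight matrix (zero-padded where a spatial shift falls outside the
kernel), which keeps the arithmetic in BLAS and the whole pipeline
dependency-free and bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationMask, Hypercube, ShapeError
from numpy.lib.stride_tricks import sliding_window_view


class ModelSpecError(ValueError):
    """The layer stack cannot produce a consistent shape chain."""


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the layer stack.

    ``layers`` is an ordered tuple of descriptors:
      ("conv3d", name, out_channels, (k_spectral, k_row, k_col))  spectral
          same-padded, spatial valid;
      ("spectral_conv", name, out_channels, kernel, stride)  1-D spectral
          convolution at every spatial position, pad 1, floor division;
      ("relu", name);
      ("fc", name, out_features)  applied after flattening (requires 1x1
          spatial extent).
    """

    input_window: int = 5
    input_bands: int = 100
    layers: tuple = field(default_factory=tuple)

    def shape_trace(self) -> dict:
        """Walk the (channels, spectral, row, col) chain through the stack.

        Returns the per-stage spectral and spatial lengths and the flattened
        feature count entering the FC head; raises :class:`ModelSpecError`,
        naming the offending layer, if the chain collapses.
        """
        c, s, h, w = 1, self.input_bands, self.input_window, self.input_window
        spectral, spatial = [s], [h]
        fc_in = None
        for layer in self.layers:
            kind, name = layer[0], layer[1]
            if kind == "conv3d":
                _, _, out_c, (ks, kh, kw) = layer
                h, w = h - kh + 1, w - kw + 1
                c = out_c
                if h < 1 or w < 1:
                    raise ModelSpecError(f"layer '{name}': spatial extent vanished")
                spectral.append(s)
                spatial.append(h)
            elif kind == "spectral_conv":
                _, _, out_c, k, stride = layer
                s = (s + 2 - k) // stride + 1
                c = out_c
                if s < 1:
                    raise ModelSpecError(f"layer '{name}': spectral extent vanished")
                spectral.append(s)
            elif kind == "fc":
                if h != 1 or w != 1:
                    raise ModelSpecError(
                        f"layer '{name}': FC requires 1x1 spatial extent, got {h}x{w}")
                fc_in = c * s
                c = layer[2]
            elif kind != "relu":
                raise ModelSpecError(f"unknown layer kind '{kind}'")
        return {"spectral": spectral, "spatial": spatial, "fc_in": fc_in,
                "n_classes": c}

    def to_json(self) -> str:
        return json.dumps({"input_window": self.input_window,
                           "input_bands": self.input_bands,
                           "layers": self.layers})

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        raw = json.loads(text)
        layers = tuple(tuple(tuple(x) if isinstance(x, list) else x for x in layer)
                       for layer in raw["layers"])
        return cls(raw["input_window"], raw["input_bands"], layers)


def default_model_spec() -> ModelSpec:
    """The published architecture: 6 convolutional layers + FC, 31,532 parameters."""
    return ModelSpec(layers=(
        ("conv3d", "Conv1", 20, (3, 3, 3)),
        ("relu", "ReLU1"),
        ("spectral_conv", "Pool1", 20, 3, 2),
        ("conv3d", "Conv2", 35, (3, 3, 3)),
        ("relu", "ReLU2"),
        ("spectral_conv", "Pool2", 35, 3, 2),
        ("spectral_conv", "Conv3", 35, 3, 1),
        ("relu", "ReLU3"),
        ("spectral_conv", "Pool3", 35, 2, 2),
        ("relu", "ReLU4"),
        ("fc", "FC", 2),
    ))


# ---------------------------------------------------------------------------
# layers (forward + explicit backward); activations are (n, S, H, W, C)


class _Layer:
    name: str
    trainable = False
    is_input_layer = False  # input-gradient computation is skipped if set

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray | None:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def n_params(self) -> int:
        return sum(p.size for p in self.params().values())


class Conv3d(_Layer):
    """Spectral-spatial convolution: spectral same-padded, spatial valid.

    Lowered to one sgemm per batch: the input is gathered into spectral-tap
    columns of shape (n*S, ks*H*W*Cin) and multiplied by an expanded weight
    matrix with one column per (out_row, out_col, out_channel); entries
    whose spatial shift falls outside the 3x3 kernel are structural zeros.
    """

    trainable = True

    def __init__(self, name: str, in_c: int, out_c: int,
                 kernel: tuple[int, int, int], rng: np.random.Generator):
        self.name = name
        self.kernel = kernel
        self.in_c, self.out_c = in_c, out_c
        ks, kh, kw = kernel
        fan_in = in_c * ks * kh * kw
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (out_c, in_c, ks, kh, kw)).astype(np.float32)
        self.b = np.zeros(out_c, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}

    def _expand_weights(self, h: int, w: int) -> np.ndarray:
        """(ks*h*w*Cin, Ho*Wo*Cout) matrix with the kernel placed per shift."""
        ks, kh, kw = self.kernel
        ho, wo = h - kh + 1, w - kw + 1
        wt = np.ascontiguousarray(self.w.transpose(2, 3, 4, 1, 0))  # ks,kh,kw,cin,oc
        big = np.zeros((ks, h, w, self.in_c, ho, wo, self.out_c), dtype=np.float32)
        for i in range(ho):
            for j in range(wo):
                big[:, i:i + kh, j:j + kw, :, i, j, :] = wt
        return big.reshape(ks * h * w * self.in_c, ho * wo * self.out_c)

    def _fold_weight_grad(self, dw2: np.ndarray, h: int, w: int) -> np.ndarray:
        ks, kh, kw = self.kernel
        ho, wo = h - kh + 1, w - kw + 1
        big = dw2.reshape(ks, h, w, self.in_c, ho, wo, self.out_c)
        acc = np.zeros((ks, kh, kw, self.in_c, self.out_c), dtype=np.float32)
        for i in range(ho):
            for j in range(wo):
                acc += big[:, i:i + kh, j:j + kw, :, i, j, :]
        return np.ascontiguousarray(acc.transpose(4, 3, 0, 1, 2))

    def forward(self, x, train):
        n, s, h, w, cin = x.shape
        ks, kh, kw = self.kernel
        ps = (ks - 1) // 2
        ho, wo = h - kh + 1, w - kw + 1
        xpad = np.pad(x, ((0, 0), (ps, ps), (0, 0), (0, 0), (0, 0)))
        cols = np.empty((n, s, ks, h, w, cin), dtype=np.float32)
        for a in range(ks):
            cols[:, :, a] = xpad[:, a:a + s]
        colmat = cols.reshape(n * s, ks * h * w * cin)
        w2 = self._expand_weights(h, w)
        y = (colmat @ w2).reshape(n, s, ho, wo, self.out_c)
        y += self.b
        if train:
            self._cache = (colmat, x.shape, w2)
        return y

    def backward(self, gy):
        colmat, xshape, w2 = self._cache
        self._cache = None
        n, s, h, w, cin = xshape
        ks, kh, kw = self.kernel
        ps = (ks - 1) // 2
        ho, wo = h - kh + 1, w - kw + 1
        gym = gy.reshape(n * s, ho * wo * self.out_c)
        self.gw[...] = self._fold_weight_grad(colmat.T @ gym, h, w)
        self.gb[...] = gym.sum(axis=0).reshape(ho * wo, self.out_c).sum(axis=0)
        if self.is_input_layer:
            return None
        dcols = (gym @ w2.T).reshape(n, s, ks, h, w, cin)
        gx_pad = np.zeros((n, s + 2 * ps, h, w, cin), dtype=np.float32)
        for a in range(ks):
            gx_pad[:, a:a + s] += dcols[:, :, a]
        return gx_pad[:, ps:ps + s] if ps else gx_pad


class SpectralConv(_Layer):
    """Trainable 1-D convolution along the spectral axis (pad 1).

    With stride 2 this is the architecture's learned "pooling": it halves
    (floor division) the spectral length while mixing channels.  Weights
    are shared across spatial positions.
    """

    trainable = True

    def __init__(self, name: str, in_c: int, out_c: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        self.name = name
        self.kernel, self.stride = kernel, stride
        self.in_c, self.out_c = in_c, out_c
        fan_in = in_c * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (out_c, in_c, kernel)).astype(np.float32)
        self.b = np.zeros(out_c, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}

    def forward(self, x, train):
        n, s, h, w, cin = x.shape
        k, stride, pad = self.kernel, self.stride, 1
        p = h * w
        so = (s + 2 * pad - k) // stride + 1
        xpad = np.pad(x.reshape(n, s, p, cin),
                      ((0, 0), (pad, pad), (0, 0), (0, 0)))
        cols = np.empty((n, so, p, k, cin), dtype=np.float32)
        last = stride * (so - 1)
        for j in range(k):
            cols[:, :, :, j, :] = xpad[:, j:j + last + 1:stride]
        colmat = cols.reshape(n * so * p, k * cin)
        w2 = np.ascontiguousarray(self.w.transpose(2, 1, 0)).reshape(k * cin,
                                                                     self.out_c)
        y = (colmat @ w2 + self.b).reshape(n, so, h, w, self.out_c)
        if train:
            self._cache = (colmat, x.shape, so, w2)
        return y

    def backward(self, gy):
        colmat, xshape, so, w2 = self._cache
        self._cache = None
        n, s, h, w, cin = xshape
        k, stride, pad = self.kernel, self.stride, 1
        p = h * w
        gym = gy.reshape(n * so * p, self.out_c)
        dw2 = colmat.T @ gym
        self.gw[...] = dw2.reshape(k, cin, self.out_c).transpose(2, 1, 0)
        self.gb[...] = gym.sum(axis=0)
        dcols = (gym @ w2.T).reshape(n, so, p, k, cin)
        gx_pad = np.zeros((n, s + 2 * pad, p, cin), dtype=np.float32)
        last = stride * (so - 1)
        for j in range(k):
            gx_pad[:, j:j + last + 1:stride] += dcols[:, :, :, j, :]
        return gx_pad[:, pad:pad + s].reshape(n, s, h, w, cin)


class ReLU(_Layer):
    def __init__(self, name: str):
        self.name = name

    def forward(self, x, train):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx


class Flatten(_Layer):
    name = "Flatten"

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Linear(_Layer):
    trainable = True

    def __init__(self, name: str, in_f: int, out_f: int, rng: np.random.Generator):
        self.name = name
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_f), (out_f, in_f)).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, gy):
        self.gw[...] = gy.T @ self._x
        self.gb[...] = gy.sum(axis=0)
        gx = gy @ self.w
        self._x = None
        return gx


# ---------------------------------------------------------------------------
# model


class Model:
    """Built network: an ordered layer list plus its spec and init seed."""

    def __init__(self, spec: ModelSpec, layers: list[_Layer], seed: int):
        self.spec = spec
        self.layers = layers
        self.seed = seed
        self._trace = spec.shape_trace()

    # -- forward/backward ---------------------------------------------------

    def _to_internal(self, patches: np.ndarray) -> np.ndarray:
        """(n, win, win, B) user layout -> (n, B, win, win, 1) channels-last."""
        patches = np.asarray(patches, dtype=np.float32)
        win, bands = self.spec.input_window, self.spec.input_bands
        if patches.ndim != 4 or patches.shape[1:] != (win, win, bands):
            raise ShapeError(
                f"expected patches of shape (n, {win}, {win}, {bands}), "
                f"got {patches.shape}")
        return np.ascontiguousarray(patches.transpose(0, 3, 1, 2))[..., None]

    def forward_logits(self, patches: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._to_internal(patches)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, glogits: np.ndarray) -> None:
        g = glogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if g is None:  # the input layer does not propagate further
                break

    def predict_scores(self, patches: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, shape (n, 2); rows sum to 1."""
        return softmax(self.forward_logits(patches, train=False))

    # -- introspection ------------------------------------------------------

    @property
    def trainable_layers(self) -> list[_Layer]:
        return [l for l in self.layers if l.trainable]

    def parameters(self):
        """Yield (array, grad) pairs over all trainable parameters, in order."""
        for layer in self.trainable_layers:
            params, grads = layer.params(), layer.grads()
            for key in params:
                yield params[key], grads[key]

    def observed_shape_trace(self, n: int = 2) -> dict:
        """Run a probe batch and record the realized spectral/spatial lengths."""
        win, bands = self.spec.input_window, self.spec.input_bands
        x = self._to_internal(np.zeros((n, win, win, bands), dtype=np.float32))
        spectral, spatial = [x.shape[1]], [x.shape[2]]
        for layer in self.layers:
            x = layer.forward(x, train=False)
            if x.ndim == 5:
                if x.shape[1] != spectral[-1]:
                    spectral.append(x.shape[1])
                if x.shape[2] != spatial[-1]:
                    spatial.append(x.shape[2])
        return {"spectral": spectral, "spatial": spatial}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> Model:
    """Construct and seed the network, asserting the published shape chain.

    Raises :class:`ModelSpecError` (naming the layer) if the stack cannot
    reach a consistent fully connected input.
    """
    spec = spec or default_model_spec()
    trace = spec.shape_trace()  # raises on inconsistent stacks
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    c, h = 1, spec.input_window
    for layer in spec.layers:
        kind, name = layer[0], layer[1]
        if kind == "conv3d":
            _, _, out_c, kernel = layer
            layers.append(Conv3d(name, c, out_c, kernel, rng))
            c, h = out_c, h - kernel[1] + 1
        elif kind == "spectral_conv":
            _, _, out_c, k, stride = layer
            layers.append(SpectralConv(name, c, out_c, k, stride, rng))
            c = out_c
        elif kind == "relu":
            layers.append(ReLU(name))
        elif kind == "fc":
            layers.append(Flatten())
            layers.append(Linear(name, trace["fc_in"], layer[2], rng))
    for lyr in layers:
        if lyr.trainable:
            lyr.is_input_layer = True
            break
    return Model(spec, layers, seed)


def count_parameters(model: Model) -> tuple[list[tuple[str, int]], int]:
    """Per-trainable-layer parameter counts (spec order) and their total."""
    per_layer = [(l.name, l.n_params()) for l in model.trainable_layers]
    return per_layer, sum(n for _, n in per_layer)


# ---------------------------------------------------------------------------
# per-pixel inference


@dataclass
class PredictionMap:
    """Per-pixel classification over the evaluated support.

    ``class_map`` holds 0 where no prediction was made and the predicted
    label (1 or 2) elsewhere; ``score_map`` the corresponding softmax
    scores.  Ties at score 0.5 resolve to class 1 (colon-mesocolon).
    """

    class_map: np.ndarray
    score_map: np.ndarray
    animal_id: str = "unknown"

    def evaluated(self) -> np.ndarray:
        return self.class_map > 0


def predict_map(model: Model, cube: Hypercube,
                support: AnnotationMask | str = "all",
                batch_size: int = 4096) -> PredictionMap:
    """Classify every supported pixel of a hypercube.

    ``support`` is an :class:`AnnotationMask` (predict on annotated pixels
    only — the default evaluation regime) or ``"all"`` (every pixel whose
    window fits).  The result is independent of ``batch_size``.
    """
    win, bands = model.spec.input_window, model.spec.input_bands
    if cube.n_bands != bands:
        raise ShapeError(f"cube has {cube.n_bands} bands, model expects {bands}")
    h, w, _ = cube.shape
    margin = (win - 1) // 2
    interior = np.zeros((h, w), dtype=bool)
    if h >= win and w >= win:
        interior[margin:h - margin, margin:w - margin] = True
    if isinstance(support, str):
        if support != "all":
            raise ValueError(f"support must be a mask or 'all', got {support!r}")
        wanted = interior
    else:
        if support.shape != (h, w):
            raise ShapeError(
                f"support mask shape {support.shape} != cube spatial shape {(h, w)}")
        wanted = (support.labels > 0) & interior

    class_map = np.zeros((h, w), dtype=np.uint8)
    score_map = np.zeros((h, w, 2), dtype=np.float32)
    coords = np.argwhere(wanted)
    if len(coords) == 0:
        return PredictionMap(class_map, score_map, cube.animal_id)

    windows = sliding_window_view(cube.data, (win, win), axis=(0, 1))
    for start in range(0, len(coords), batch_size):
        chunk = coords[start:start + batch_size]
        batch = windows[chunk[:, 0] - margin, chunk[:, 1] - margin]  # (m, B, win, win)
        batch = np.ascontiguousarray(np.moveaxis(batch, 1, -1))
        scores = model.predict_scores(batch)
        score_map[chunk[:, 0], chunk[:, 1]] = scores
        class_map[chunk[:, 0], chunk[:, 1]] = np.where(
            scores[:, 0] >= scores[:, 1], 1, 2)
    return PredictionMap(class_map, score_map, cube.animal_id)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: Model, path) -> None:
    """Single-file checkpoint: weights + spec + init seed."""
    arrays = {}
    for i, layer in enumerate(model.trainable_layers):
        for key, value in layer.params().items():
            arrays[f"{i}_{layer.name}_{key}"] = value
    np.savez(path, _spec=np.frombuffer(model.spec.to_json().encode(), dtype=np.uint8),
             _seed=np.array(model.seed), **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path) as data:
        spec = ModelSpec.from_json(bytes(data["_spec"]).decode())
        model = build_model(spec, seed=int(data["_seed"]))
        for i, layer in enumerate(model.trainable_layers):
            for key in layer.params():
                layer.params()[key][...] = data[f"{i}_{layer.name}_{key}"]
    return model
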
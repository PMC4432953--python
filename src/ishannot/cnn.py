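"""Forward-only convolutional feature extraction from ISH sections.

Sections are resized to the network's 231x231x3 input, forwarded through a
fixed reference topology (the 18 feature-extraction layers of the classic
"fast" ImageNet architecture: 6 stages of convolution / rectification /
optional 2x2 max-pooling followed by one fully connected stage; the
classifier head is omitted), and activations are tapped at the last layer
of each stage — layers 6, 9, 12, 16 and 18.  Layer indexing counts the
zero-padding modules of stages 3-5 as layers, which is the indexing under
which those taps land on stage outputs.

Tap shapes (maps, height, width) are a hard contract, enforced by symbolic
shape propagation before any forward pass:

====  ==================  =============
tap   feature maps        vector length
====  ==================  =============
6     256 @ 12x12         36864
9     512 @ 12x12         73728
12    1024 @ 12x12        147456
16    1024 @ 6x6          36864
18    3072 @ 1x1          3072
====  ==================  =============

Feature maps are flattened map-major (map, then row, then column) and, per
gene, combined across sections by element-wise maximum (default) or
average.  Weights are pluggable: seeded He-style random initialisation by
default (sufficient for every structural contract and for random-projection
feature extraction), or a flat binary weight file for users who have
converted pretrained weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .features import FeatureMatrix
from .stack import SectionStack

INPUT_SIZE = 231
TAP_LAYERS = (6, 9, 12, 16, 18)
TAP_SHAPES = {
    6: (256, 12, 12),
    9: (512, 12, 12),
    12: (1024, 12, 12),
    16: (1024, 6, 6),
    18: (3072, 1, 1),
}
TAP_LENGTHS = {t: int(np.prod(s)) for t, s in TAP_SHAPES.items()}


class ArchitectureError(ValueError):
    """Topology whose propagated shapes violate the tap contract."""


# ---------------------------------------------------------------------------
# layer and architecture description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Conv:
    out_maps: int
    kernel: int
    stride: int = 1


@dataclass(frozen=True)
class ReLU:
    pass


@dataclass(frozen=True)
class MaxPool:
    size: int
    stride: int


@dataclass(frozen=True)
class ZeroPad:
    pad: int


@dataclass(frozen=True)
class Linear:
    out_features: int


@dataclass
class CnnArchitecture:
    """Ordered layers (1-indexed) with tap points and expected tap shapes."""

    layers: list
    input_shape: tuple = (3, INPUT_SIZE, INPUT_SIZE)
    taps: tuple = TAP_LAYERS
    expected_tap_shapes: dict = field(default_factory=lambda: dict(TAP_SHAPES))

    def propagate_shapes(self) -> dict[int, tuple]:
        """Symbolic (maps, height, width) after every layer."""
        c, h, w = self.input_shape
        shapes = {}
        for idx, layer in enumerate(self.layers, start=1):
            if isinstance(layer, Conv):
                h = (h - layer.kernel) // layer.stride + 1
                w = (w - layer.kernel) // layer.stride + 1
                c = layer.out_maps
            elif isinstance(layer, MaxPool):
                h = (h - layer.size) // layer.stride + 1
                w = (w - layer.size) // layer.stride + 1
            elif isinstance(layer, ZeroPad):
                h, w = h + 2 * layer.pad, w + 2 * layer.pad
            elif isinstance(layer, Linear):
                c, h, w = layer.out_features, 1, 1
            elif isinstance(layer, ReLU):
                pass
            else:
                raise ArchitectureError(f"unknown layer type at index {idx}: {layer!r}")
            if h < 1 or w < 1:
                raise ArchitectureError(
                    f"layer {idx} ({type(layer).__name__}) collapses the spatial "
                    f"extent to {h}x{w}"
                )
            shapes[idx] = (c, h, w)
        return shapes

    def validate(self) -> dict[int, tuple]:
        shapes = self.propagate_shapes()
        for tap in self.taps:
            if tap not in shapes:
                raise ArchitectureError(f"tap layer {tap} beyond network depth")
            expected = self.expected_tap_shapes.get(tap)
            if expected is not None and shapes[tap] != tuple(expected):
                raise ArchitectureError(
                    f"layer {tap} produces shape {shapes[tap]}, expected "
                    f"{tuple(expected)}; first offending layer: {tap}"
                )
        return shapes


def default_architecture() -> CnnArchitecture:
    """The fast reference topology satisfying the published tap shapes."""
    layers = [
        Conv(96, 11, stride=4),   # 1
        ReLU(),                   # 2
        MaxPool(2, 2),            # 3
        Conv(256, 5),             # 4
        ReLU(),                   # 5
        MaxPool(2, 2),            # 6  tap: 256 @ 12x12
        ZeroPad(1),               # 7
        Conv(512, 3),             # 8
        ReLU(),                   # 9  tap: 512 @ 12x12
        ZeroPad(1),               # 10
        Conv(1024, 3),            # 11
        ReLU(),                   # 12 tap: 1024 @ 12x12
        ZeroPad(1),               # 13
        Conv(1024, 3),            # 14
        ReLU(),                   # 15
        MaxPool(2, 2),            # 16 tap: 1024 @ 6x6
        Linear(3072),             # 17
        ReLU(),                   # 18 tap: 3072
    ]
    return CnnArchitecture(layers)


# ---------------------------------------------------------------------------
# extractor
# ---------------------------------------------------------------------------

@dataclass
class LayerFeatureVector:
    """Flattened activations of one tap layer for a section or a gene."""

    source_id: str
    tap: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).ravel()


class CnnExtractor:
    """Deterministic forward-pass feature extractor.

    ``weights_source`` is either an integer seed (He-style random
    initialisation, zero biases) or a path to a weight file written by
    :func:`save_weights`.
    """

    def __init__(self, arch: CnnArchitecture | None = None,
                 weights_source: int | str = 0):
        self.arch = arch or default_architecture()
        self.shapes = self.arch.validate()
        if isinstance(weights_source, (int, np.integer)):
            self.weights = _init_weights(self.arch, int(weights_source))
            self.weights_source = f"seed:{int(weights_source)}"
        else:
            self.weights = load_weights(weights_source, self.arch)
            self.weights_source = str(weights_source)

    # -- forward ---------------------------------------------------------
    def forward_batch(self, x: np.ndarray, taps=TAP_LAYERS) -> dict[int, np.ndarray]:
        """Forward a batch (n, 3, H, W) and return flattened activations at
        each requested tap, stopping at the deepest one."""
        taps = tuple(taps)
        for t in taps:
            if t not in self.arch.taps:
                raise ValueError(f"unsupported tap {t}; valid taps: {self.arch.taps}")
        deepest = max(taps)
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != self.arch.input_shape:
            raise ValueError(
                f"expected batch of shape (n, {self.arch.input_shape}), got {x.shape}"
            )
        out = {}
        for idx, layer in enumerate(self.arch.layers, start=1):
            if isinstance(layer, Conv):
                W, b = self.weights[idx]
                x = _conv2d(x, W, b, layer.stride)
            elif isinstance(layer, ReLU):
                x = np.maximum(x, 0.0)
            elif isinstance(layer, MaxPool):
                win = sliding_window_view(x, (layer.size, layer.size), axis=(2, 3))
                x = win[:, :, ::layer.stride, ::layer.stride].max(axis=(-1, -2))
            elif isinstance(layer, ZeroPad):
                p = layer.pad
                x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            elif isinstance(layer, Linear):
                W, b = self.weights[idx]
                x = (x.reshape(x.shape[0], -1) @ W.T + b)[:, :, None, None]
            if idx in taps:
                out[idx] = x.reshape(x.shape[0], -1).copy()
            if idx >= deepest:
                break
        return out


def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Valid cross-correlation via im2col + one BLAS matmul per batch."""
    n, c, h, w = x.shape
    c_out, c_in, k, _ = W.shape
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c_in * k * k)
    out = cols @ W.reshape(c_out, -1).T.astype(np.float32, copy=False)
    out += b
    return out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)


def _init_weights(arch: CnnArchitecture, seed: int) -> dict[int, tuple]:
    """He-style N(0, sqrt(2/fan_in)) weights, zero biases, reproducible."""
    rng = np.random.default_rng(seed)
    shapes = arch.propagate_shapes()
    weights = {}
    c, h, w = arch.input_shape
    for idx, layer in enumerate(arch.layers, start=1):
        if isinstance(layer, Conv):
            fan_in = c * layer.kernel ** 2
            Wk = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(layer.out_maps, c, layer.kernel, layer.kernel))
            weights[idx] = (Wk.astype(np.float32), np.zeros(layer.out_maps, np.float32))
        elif isinstance(layer, Linear):
            fan_in = c * h * w
            Wk = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(layer.out_features, fan_in))
            weights[idx] = (Wk.astype(np.float32),
                            np.zeros(layer.out_features, np.float32))
        c, h, w = shapes[idx]
    return weights


def build_extractor(arch: CnnArchitecture | None = None,
                    weights_source: int | str = 0) -> CnnExtractor:
    """Validate the architecture and construct a deterministic extractor."""
    return CnnExtractor(arch, weights_source)


# ---------------------------------------------------------------------------
# weight file format: one JSON header line, then raw little-endian float32
# ---------------------------------------------------------------------------

def save_weights(extractor: CnnExtractor, path) -> None:
    header = {
        "layers": {
            str(idx): {"W": list(W.shape), "b": list(b.shape)}
            for idx, (W, b) in sorted(extractor.weights.items())
        }
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode())
        for idx in sorted(extractor.weights):
            W, b = extractor.weights[idx]
            fh.write(W.astype("<f4").tobytes())
            fh.write(b.astype("<f4").tobytes())


def load_weights(path, arch: CnnArchitecture) -> dict[int, tuple]:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        weights = {}
        for idx_str, shapes in sorted(header["layers"].items(), key=lambda kv: int(kv[0])):
            w_shape, b_shape = tuple(shapes["W"]), tuple(shapes["b"])
            n_w, n_b = int(np.prod(w_shape)), int(np.prod(b_shape))
            W = np.frombuffer(fh.read(4 * n_w), dtype="<f4").reshape(w_shape)
            b = np.frombuffer(fh.read(4 * n_b), dtype="<f4").reshape(b_shape)
            weights[int(idx_str)] = (W.copy(), b.copy())
    return weights


# ---------------------------------------------------------------------------
# preprocessing, extraction, pooling
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, size: int = INPUT_SIZE,
               center: float = 0.5) -> np.ndarray:
    """Resize to ``size x size``, replicate grayscale to 3 channels, scale
    intensities to [0, 1] and centre at ``center``.  Returns (3, size, size)
    float32, channels-first."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    img = img.astype(np.float64)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        img = img / np.iinfo(np.asarray(image).dtype).max
    if img.ndim == 2:
        img = img[:, :, None].repeat(3, axis=2)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected 2-D or 3-channel image, got shape {image.shape}")
    if img.shape[:2] != (size, size):
        img = resize(img, (size, size), order=1, preserve_range=True,
                     anti_aliasing=False)
    return (img - center).transpose(2, 0, 1).astype(np.float32)


def extract(extractor: CnnExtractor, image: np.ndarray, tap: int,
            source_id: str = "section") -> LayerFeatureVector:
    """Preprocess one section and read the flattened tap activations."""
    batch = preprocess(image)[None]
    values = extractor.forward_batch(batch, taps=(tap,))[tap][0]
    return LayerFeatureVector(source_id, tap, values)


def pool_sections(vectors: list[LayerFeatureVector], mode: str = "max",
                  gene_id: str = "gene") -> LayerFeatureVector:
    """Element-wise maximum (default) or average across a gene's sections."""
    if not vectors:
        raise ValueError("no section vectors to pool")
    taps = {v.tap for v in vectors}
    lengths = {v.values.shape[0] for v in vectors}
    if len(taps) > 1 or len(lengths) > 1:
        raise ValueError(f"mixed taps {taps} or lengths {lengths}")
    stackv = np.stack([v.values for v in vectors])
    if mode == "max":
        pooled = stackv.max(axis=0)
    elif mode in ("average", "mean", "ave"):
        pooled = stackv.mean(axis=0)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}; use 'max' or 'average'")
    return LayerFeatureVector(gene_id, vectors[0].tap, pooled)


def cnn_feature_matrix(
    stacks: list[SectionStack],
    tap: int = 12,
    mode: str = "max",
    seed: int = 0,
    weights_source: int | str | None = None,
    arch: CnnArchitecture | None = None,
) -> FeatureMatrix:
    """Per-gene global CNN features: forward every section, flatten the tap
    activations, pool element-wise across sections."""
    extractor = build_extractor(arch, seed if weights_source is None else weights_source)
    if tap not in extractor.arch.taps:
        raise ValueError(f"unsupported tap {tap}; valid taps: {extractor.arch.taps}")
    rows = []
    for stack in stacks:
        batch = np.stack([preprocess(im) for im in stack.images])
        acts = extractor.forward_batch(batch, taps=(tap,))[tap]
        vectors = [LayerFeatureVector(f"{stack.gene_id}#{i}", tap, a)
                   for i, a in enumerate(acts)]
        rows.append(pool_sections(vectors, mode, stack.gene_id).values)
    values = np.asarray(rows, dtype=np.float64)
    meta = {"tap": tap, "mode": mode, "weights": extractor.weights_source}
    return FeatureMatrix(values, [s.gene_id for s in stacks], f"cnn:L{tap}", meta)
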
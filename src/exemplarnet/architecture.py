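"""LiteNeXt: a lightweight ConvNeXt-style convolutional classifier.

The network is built from four components:

* **stem** — a patchify 4x4/stride-4 convolution to ``filters[0]`` channels,
  followed by batch norm and GELU; a 224x224 input becomes 56x56x96.
* **stages** — four stages of dual-shortcut blocks. Each block contains two
  residual sub-units; a sub-unit is pre-LN -> 3x3 depth-wise convolution with a
  4x channel multiplier (inverted bottleneck) -> GELU -> 1x1 point-wise
  projection back to the stage width -> batch norm, wrapped in an additive
  shortcut. Two shortcuts per block improve gradient flow in small networks.
* **downsampling** — between stages 1-3, a grouped patchify convolution
  (2x2 kernel, stride 2, one input channel and two output filters per group,
  doubling the channel count) followed by channel layer norm and GELU.
* **output block** — a 1x1 convolution widening ``filters[3]`` to
  ``filters[4]`` (768 -> 1280 by default), layer norm, GELU, batch norm, global
  average pooling, and a fully connected softmax head.

With the default schedule ``filters = (96, 192, 384, 768, 1280)`` and a 4-class
head the network has 7,405,348 trainable parameters (~7.4 M, ~28.2 MiB at FP32).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigurationError, FormatError, InputError
from .nn import (
    BatchNorm2d,
    ChannelLayerNorm,
    Conv2d,
    GELU,
    GlobalAvgPool,
    Linear,
    Residual,
    Sequential,
)
from .nn.optim import softmax

DEFAULT_FILTERS = (96, 192, 384, 768, 1280)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters defining a LiteNeXt instance.

    ``filters`` are the five stage widths (the last is the pre-GAP width, and
    the first four must double stage to stage so the grouped downsampling can
    pair each input channel with two output filters); ``repetitions`` is the
    number of dual-shortcut blocks per stage (the fifth entry is kept for
    symmetry with the filter schedule and is not consumed by the builder);
    ``expansion_factor`` is the inverted-bottleneck channel multiplier.
    """

    filters: tuple[int, ...] = DEFAULT_FILTERS
    repetitions: tuple[int, ...] = (1, 1, 1, 1, 1)
    input_side: int = 224
    input_channels: int = 3
    num_classes: int = 2
    expansion_factor: int = 4

    def __post_init__(self):
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))
        object.__setattr__(self, "repetitions", tuple(int(r) for r in self.repetitions))

    def validate(self) -> None:
        if len(self.filters) != 5:
            raise ConfigurationError("filters must have exactly 5 entries")
        if len(self.repetitions) != 5:
            raise ConfigurationError("repetitions must have exactly 5 entries")
        if any(f <= 0 for f in self.filters):
            raise ConfigurationError("filters must be positive")
        if any(r <= 0 for r in self.repetitions):
            raise ConfigurationError("repetitions must be positive")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if self.expansion_factor < 1:
            raise ConfigurationError("expansion_factor must be a positive integer")
        if self.input_channels < 1:
            raise ConfigurationError("input_channels must be positive")
        for i in range(3):
            if self.filters[i + 1] != 2 * self.filters[i]:
                raise ConfigurationError(
                    f"filters[{i + 1}] must equal 2*filters[{i}] "
                    f"(grouped downsampling doubles channels), got {self.filters}")
        if self.input_side < 4 or self.input_side % 4:
            raise ConfigurationError(
                f"input_side must be a positive multiple of 4 (patchify stem), got "
                f"{self.input_side}; multiples of 32 give exact halving at every stage")
        stage_shapes(self)  # raises if some side collapses below the kernel

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        d["filters"] = tuple(d["filters"])
        d["repetitions"] = tuple(d["repetitions"])
        return cls(**d)


def stage_shapes(spec: ArchitectureSpec) -> list[tuple[int, int]]:
    """Analytic (side, channels) trace after the stem, each downsample, and the
    output 1x1 convolution — without building any weights.

    Sides follow convolution arithmetic: the stem divides by 4 exactly; each
    2x2/stride-2 downsample maps ``s`` to ``(s - 2) // 2 + 1`` (floor on odd
    sides). Raises :class:`ConfigurationError` if a side collapses below the
    downsampling kernel.
    """
    if spec.input_side < 4 or spec.input_side % 4:
        raise ConfigurationError(
            f"input_side must be a multiple of 4, got {spec.input_side}")
    side = spec.input_side // 4
    trace = [(side, spec.filters[0])]
    for f in spec.filters[1:4]:
        if side < 2:
            raise ConfigurationError(
                f"spatial side {side} too small for a 2x2 stride-2 downsample; "
                f"increase input_side")
        side = (side - 2) // 2 + 1
        trace.append((side, f))
    trace.append((side, spec.filters[4]))
    return trace


def _subunit(c: int, expansion: int, rng: np.random.Generator) -> Residual:
    e = c * expansion
    return Residual(Sequential(
        ChannelLayerNorm(c),
        Conv2d(c, e, kernel=3, stride=1, padding=1, groups=c, rng=rng, name="dw"),
        GELU(),
        Conv2d(e, c, kernel=1, rng=rng, name="pw"),
        BatchNorm2d(c),
    ))


class LiteNeXt:
    """The built network: weights plus topology, with forward and backward passes."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.filters
        trunk: list = [
            Conv2d(spec.input_channels, f[0], kernel=4, stride=4, rng=rng, name="stem"),
            BatchNorm2d(f[0]),
            GELU(),
        ]
        for stage in range(4):
            c = f[stage]
            for _ in range(spec.repetitions[stage]):
                trunk.append(_subunit(c, spec.expansion_factor, rng))
                trunk.append(_subunit(c, spec.expansion_factor, rng))
            if stage < 3:
                trunk += [
                    Conv2d(c, 2 * c, kernel=2, stride=2, groups=c, rng=rng, name="down"),
                    ChannelLayerNorm(2 * c),
                    GELU(),
                ]
                if 2 * c != f[stage + 1]:
                    raise ConfigurationError(
                        f"filters must double per stage for grouped downsampling: "
                        f"{c} -> {f[stage + 1]}")
        trunk += [
            Conv2d(f[3], f[4], kernel=1, rng=rng, name="out"),
            ChannelLayerNorm(f[4]),
            GELU(),
            BatchNorm2d(f[4]),
        ]
        self.trunk = Sequential(*trunk)
        self.gap = GlobalAvgPool()
        self.fc = Linear(f[4], spec.num_classes, rng=rng)

    # -- forward ----------------------------------------------------------

    def _check_batch(self, x: np.ndarray) -> np.ndarray:
        s, c = self.spec.input_side, self.spec.input_channels
        if x.ndim != 4 or x.shape[1] != c:
            raise InputError(f"expected (N, {c}, H, W) input, got {x.shape}")
        return np.ascontiguousarray(x, dtype=np.float32)

    def activation_map(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Final pre-GAP activation map, shape (N, filters[4], h, w)."""
        return self.trunk.forward(self._check_batch(x), train)

    def features_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """GAP feature vectors, shape (N, filters[4])."""
        return self.gap.forward(self.activation_map(x, train), train)

    def logits_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.fc.forward(self.features_batch(x, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        self.trunk.backward(self.gap.backward(self.fc.backward(dlogits)))

    def parameters(self):
        return self.trunk.parameters() + self.gap.parameters() + self.fc.parameters()

    # -- serialization helpers -------------------------------------------

    def _norm_layers(self) -> list[BatchNorm2d]:
        out = []

        def walk(layer):
            if isinstance(layer, Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, Residual):
                walk(layer.body)
            elif isinstance(layer, BatchNorm2d):
                out.append(layer)

        walk(self.trunk)
        return out


def build_model(spec: ArchitectureSpec, seed: int = 0) -> LiteNeXt:
    """Instantiate a seeded, randomly initialised network from a validated spec."""
    return LiteNeXt(spec, seed=seed)


def count_parameters(model: LiteNeXt) -> int:
    """Number of trainable scalars (kernels, biases, norm scales and shifts, head)."""
    return int(sum(p.size for p in model.parameters()))


def fp32_payload_bytes(model: LiteNeXt) -> int:
    """Bytes of FP32 weight payload in a serialized archive: 4 per parameter."""
    return 4 * count_parameters(model)


def _image_to_batch(model: LiteNeXt, image: np.ndarray) -> np.ndarray:
    """Validate one HWC image in [0, 1] against the spec; return a (1,C,S,S) batch."""
    s, c = model.spec.input_side, model.spec.input_channels
    img = np.asarray(image, dtype=np.float32)
    if img.shape != (s, s, c):
        raise InputError(f"expected image of shape ({s}, {s}, {c}), got {img.shape}")
    return img.transpose(2, 0, 1)[None]


def forward_logits(model: LiteNeXt, image: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for one HWC image in [0, 1]."""
    return softmax(model.logits_batch(_image_to_batch(model, image)))[0]


def gap_features(model: LiteNeXt, image: np.ndarray) -> np.ndarray:
    """The 1280-long (``filters[4]``) GAP feature vector for one HWC image."""
    return model.features_batch(_image_to_batch(model, image))[0]


def save_model(model: LiteNeXt, path) -> None:
    """Serialize spec + all weights (FP32) + batch-norm running stats to one file."""
    arrays = {f"param_{i:04d}": p.value for i, p in enumerate(model.parameters())}
    for j, bn in enumerate(model._norm_layers()):
        arrays[f"bn_{j:03d}_mean"] = bn.running_mean
        arrays[f"bn_{j:03d}_var"] = bn.running_var
    arrays["spec_json"] = np.array(model.spec.to_json())
    np.savez(path, **arrays)


def load_model(path) -> LiteNeXt:
    """Rebuild a network from an archive written by :func:`save_model`.

    Raises :class:`FormatError` with a stored-vs-expected diff on corrupt or
    structurally incompatible files.
    """
    try:
        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
    except (OSError, ValueError, KeyError, zipfile.BadZipFile, io.UnsupportedOperation) as e:
        raise FormatError(f"cannot read model archive {path}: {e}") from e
    if "spec_json" not in arrays:
        raise FormatError(f"model archive {path} lacks an embedded spec")
    try:
        spec = ArchitectureSpec.from_json(str(arrays["spec_json"]))
    except (json.JSONDecodeError, TypeError, KeyError) as e:
        raise FormatError(f"model archive {path} has an unreadable spec: {e}") from e
    model = LiteNeXt(spec, seed=0)
    params = model.parameters()
    stored = sorted(k for k in arrays if k.startswith("param_"))
    if len(stored) != len(params):
        raise FormatError(
            f"archive stores {len(stored)} parameter arrays, spec requires {len(params)}")
    for key, p in zip(stored, params):
        a = arrays[key]
        if a.shape != p.value.shape:
            raise FormatError(
                f"{key}: stored shape {a.shape} vs expected {p.value.shape}")
        p.value[...] = a
    for j, bn in enumerate(model._norm_layers()):
        try:
            bn.running_mean = arrays[f"bn_{j:03d}_mean"].astype(np.float32)
            bn.running_var = arrays[f"bn_{j:03d}_var"].astype(np.float32)
        except KeyError as e:
            raise FormatError(f"archive lacks batch-norm state {e}") from e
    return model
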
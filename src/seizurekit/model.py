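"""Declarative 1D CNN-LSTM architecture with analytic shape/parameter oracles.

The default network is a six-convolution, four-pool stack feeding a single
200-unit LSTM whose final hidden state passes through a 64-unit regularized
dense layer, dropout, and a classification head (one sigmoid unit for binary
problems, a softmax of ``n_classes`` units otherwise).  All convolutions and
pools use valid padding, so every length follows
``out = floor((in - kernel) / stride) + 1``.

Parameter accounting convention: conv ``filters·(kernel·in_channels) +
filters``; batch norm ``4·channels`` (scale, offset and the two moving
statistics); LSTM ``4·((features + units)·units + units)``; dense
``in·units + units``; everything else zero.  For an input length of 4100
the default binary spec totals 765,553 parameters.

``infer_shapes`` and ``count_parameters`` are closed-form and independent of
the network engine; ``build`` materializes the same spec as a trainable
:class:`~seizurekit.nn.Sequential` whose realized shapes and parameter
count must agree with them exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "default_spec",
    "infer_shapes",
    "count_parameters",
    "build",
    "describe",
    "spec_to_json",
    "spec_from_json",
]

_KINDS = (
    "conv1d",
    "batchnorm",
    "relu",
    "maxpool1d",
    "lstm",
    "flatten",
    "dense",
    "dropout",
    "activation",
)


@dataclass(frozen=True)
class LayerSpec:
    """One layer row: kind plus the fields that kind uses.

    ``kernel``/``stride`` apply to conv1d, ``pool``/``stride`` to maxpool1d,
    ``units`` to lstm/dense, ``l2`` to dense, ``rate`` to dropout and
    ``activation`` to activation layers.  Padding is always valid.
    """

    kind: str
    filters: int | None = None
    units: int | None = None
    kernel: int | None = None
    stride: int | None = None
    pool: int | None = None
    l2: float = 0.0
    rate: float = 0.0
    activation: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        for name in ("filters", "units", "kernel", "stride", "pool"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{self.kind}: {name} must be positive, got {v}")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer list over a 1D single-feature input sequence."""

    input_length: int
    layers: tuple[LayerSpec, ...]
    n_classes: int = 2
    input_channels: int = 1

    def __post_init__(self) -> None:
        if self.input_length < 1:
            raise ValueError("input_length must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def head(self) -> str:
        return "sigmoid" if self.n_classes == 2 else "softmax"


def default_spec(input_length: int, n_classes: int = 2) -> ModelSpec:
    """The reference 28-layer architecture for a given input length.

    Binary problems get a single sigmoid output unit; multi-class problems
    an ``n_classes``-unit softmax.  Raises a shape error (naming the failing
    layer) if the input is too short to survive the conv/pool stack.
    """
    if input_length < 64:
        raise ValueError(f"input_length must be >= 64, got {input_length}")
    L = LayerSpec
    head_units = 1 if n_classes == 2 else n_classes
    head_act = "sigmoid" if n_classes == 2 else "softmax"
    layers = (
        L("conv1d", filters=16, kernel=2, stride=2),
        L("batchnorm"),
        L("relu"),
        L("conv1d", filters=32, kernel=2, stride=2),
        L("batchnorm"),
        L("relu"),
        L("conv1d", filters=64, kernel=2, stride=2),
        L("batchnorm"),
        L("relu"),
        L("maxpool1d", pool=3, stride=2),
        L("conv1d", filters=128, kernel=1, stride=1),
        L("batchnorm"),
        L("relu"),
        L("maxpool1d", pool=3, stride=2),
        L("conv1d", filters=256, kernel=1, stride=1),
        L("batchnorm"),
        L("relu"),
        L("maxpool1d", pool=3, stride=2),
        L("conv1d", filters=512, kernel=1, stride=1),
        L("batchnorm"),
        L("relu"),
        L("maxpool1d", pool=3, stride=2),
        L("lstm", units=200),
        L("flatten"),
        L("dense", units=64, l2=0.03, activation="relu"),
        L("dropout", rate=0.4),
        L("dense", units=head_units),
        L("activation", activation=head_act),
    )
    spec = ModelSpec(input_length=input_length, layers=layers, n_classes=n_classes)
    infer_shapes(spec)  # fail fast with the offending layer named
    return spec


def infer_shapes(spec: ModelSpec) -> list[tuple[int, ...]]:
    """Output shape of every layer, batch axis excluded.

    Sequence stages report ``(length, channels)``; the LSTM and everything
    after it report ``(features,)``.  Raises ``ValueError`` naming the layer
    whose output would be empty.
    """
    shape: tuple[int, ...] = (spec.input_length, spec.input_channels)
    out: list[tuple[int, ...]] = []
    for idx, layer in enumerate(spec.layers):
        k = layer.kind
        if k == "conv1d":
            if len(shape) != 2:
                raise ValueError(f"layer {idx}: conv1d needs a sequence input")
            n = (shape[0] - layer.kernel) // layer.stride + 1
            if n < 1:
                raise ValueError(
                    f"layer {idx}: conv1d(k={layer.kernel}, s={layer.stride}) "
                    f"empties length {shape[0]}"
                )
            shape = (n, layer.filters)
        elif k == "maxpool1d":
            if len(shape) != 2:
                raise ValueError(f"layer {idx}: maxpool1d needs a sequence input")
            n = (shape[0] - layer.pool) // layer.stride + 1
            if n < 1:
                raise ValueError(
                    f"layer {idx}: maxpool1d(p={layer.pool}, s={layer.stride}) "
                    f"empties length {shape[0]}"
                )
            shape = (n, shape[1])
        elif k == "lstm":
            if len(shape) != 2:
                raise ValueError(f"layer {idx}: lstm needs a sequence input")
            shape = (layer.units,)
        elif k == "flatten":
            shape = (int(np.prod(shape)),)
        elif k == "dense":
            if len(shape) != 1:
                raise ValueError(f"layer {idx}: dense needs a flat input")
            shape = (layer.units,)
        # batchnorm / relu / dropout / activation preserve shape
        out.append(shape)
    return out


def count_parameters(spec: ModelSpec) -> tuple[list[int], int]:
    """Analytic per-layer parameter counts and their total."""
    shapes = infer_shapes(spec)
    counts: list[int] = []
    in_shape: tuple[int, ...] = (spec.input_length, spec.input_channels)
    for layer, out_shape in zip(spec.layers, shapes):
        k = layer.kind
        if k == "conv1d":
            cin = in_shape[1]
            counts.append(layer.filters * (layer.kernel * cin) + layer.filters)
        elif k == "batchnorm":
            counts.append(4 * in_shape[-1])
        elif k == "lstm":
            f = in_shape[1]
            u = layer.units
            counts.append(4 * ((f + u) * u + u))
        elif k == "dense":
            counts.append(in_shape[0] * layer.units + layer.units)
        else:
            counts.append(0)
        in_shape = out_shape
    return counts, int(sum(counts))


def build(spec: ModelSpec, seed: int = 0) -> nn.Sequential:
    """Materialize the spec on the network engine.

    The returned model's realized parameter count equals
    ``count_parameters(spec)`` exactly; construction errors name the layer
    index they arose at.
    """
    layers: list[nn.Layer] = []
    for idx, ls in enumerate(spec.layers):
        k = ls.kind
        try:
            if k == "conv1d":
                layers.append(nn.Conv1D(ls.filters, ls.kernel, ls.stride))
            elif k == "batchnorm":
                layers.append(nn.BatchNorm())
            elif k == "relu":
                layers.append(nn.Activation("relu"))
            elif k == "maxpool1d":
                layers.append(nn.MaxPool1D(ls.pool, ls.stride))
            elif k == "lstm":
                layers.append(nn.LSTM(ls.units))
            elif k == "flatten":
                layers.append(nn.Flatten())
            elif k == "dense":
                layers.append(nn.Dense(ls.units, l2=ls.l2))
                if ls.activation and ls.activation != "linear":
                    layers.append(nn.Activation(ls.activation))
            elif k == "dropout":
                layers.append(nn.Dropout(ls.rate))
            elif k == "activation":
                layers.append(nn.Activation(ls.activation))
        except ValueError as exc:
            raise ValueError(f"layer {idx} ({k}): {exc}") from exc
    return nn.Sequential(
        layers, input_shape=(spec.input_length, spec.input_channels), seed=seed
    )


def describe(spec: ModelSpec) -> str:
    """Human-readable summary table: layer, output shape, parameter count."""
    shapes = infer_shapes(spec)
    counts, total = count_parameters(spec)
    lines = [f"{'No.':>3}  {'Layer':<12} {'Output shape':<14} {'Params':>10}"]
    for i, (ls, sh, c) in enumerate(zip(spec.layers, shapes, counts), start=1):
        shape_txt = str(sh if len(sh) > 1 else sh[0])
        lines.append(f"{i:>3}  {ls.kind:<12} {shape_txt:<14} {c:>10,}")
    lines.append(f"{'':>3}  {'Total':<12} {'':<14} {total:>10,}")
    return "\n".join(lines)


def spec_to_json(spec: ModelSpec, path: str | Path | None = None) -> str:
    doc = json.dumps(asdict(spec), indent=2)
    if path is not None:
        Path(path).write_text(doc)
    return doc


def spec_from_json(source: str | Path) -> ModelSpec:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    raw = json.loads(text)
    layers = tuple(LayerSpec(**d) for d in raw.pop("layers"))
    return ModelSpec(layers=layers, **raw)
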
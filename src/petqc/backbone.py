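"""VGG-style 5-block convolutional backbone with replaceable head and
block-wise freezing.

The feature extractor mirrors the VGG16 layout — five blocks of
(2, 2, 3, 3, 3) 3x3 convolutions, each block closed by a 2x2 max-pool —
but with a configurable channel width so it trains on a CPU.  The
classification head is replaced by a single fully connected layer: three
rectified outputs for the clinical metrics (GQR, PR, DC), or one linear
output for the dose-inference pretext task.  Features are globally
average-pooled before the head, so the head size is independent of the
input patch size.

Transfer learning freezes the first ``5 - k`` blocks and trains the last
``k`` blocks plus the head; frozen parameters carry a strict no-update
contract enforced by the optimiser operating only on trainable layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Conv3x3, Dense, GlobalAvgPool, Layer, MaxPool2, ReLU, Sequential

__all__ = [
    "BackboneSpec",
    "HeadSpec",
    "FreezePolicy",
    "QualityNet",
    "UnavailableResourceError",
    "build_backbone",
    "apply_freeze",
    "replace_head",
    "save_checkpoint",
    "load_checkpoint",
]

#: VGG16 width multipliers per block (64, 128, 256, 512, 512 at base 64).
WIDTH_MULTIPLIERS = (1, 2, 4, 8, 8)


class UnavailableResourceError(RuntimeError):
    """A requested external resource (e.g. ImageNet weights) is not available."""


@dataclass(frozen=True)
class BackboneSpec:
    n_blocks: int = 5
    convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)
    base_width: int = 8
    input_size: int = 80
    input_channels: int = 3

    def __post_init__(self):
        if self.n_blocks != len(self.convs_per_block):
            raise ValueError("convs_per_block must have n_blocks entries")
        if self.input_size < 2**self.n_blocks:
            raise ValueError(
                f"input_size {self.input_size} too small for {self.n_blocks} pooling stages"
            )

    @property
    def block_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * m for m in WIDTH_MULTIPLIERS[: self.n_blocks])


@dataclass(frozen=True)
class HeadSpec:
    """Fully connected output head: 'clinical' (3 rectified) or 'dose' (1 linear)."""

    kind: str = "clinical"
    activation: str | None = None  # default chosen by kind

    def __post_init__(self):
        if self.kind not in ("clinical", "dose"):
            raise ValueError(f"unknown head kind {self.kind!r}")

    @property
    def outputs(self) -> int:
        return 3 if self.kind == "clinical" else 1

    @property
    def resolved_activation(self) -> str:
        if self.activation is not None:
            return self.activation
        return "relu" if self.kind == "clinical" else "linear"


@dataclass(frozen=True)
class FreezePolicy:
    """Train the last ``trainable_last_k_blocks`` blocks plus the head."""

    trainable_last_k_blocks: int = 0
    head_trainable: bool = True

    def __post_init__(self):
        if not (0 <= self.trainable_last_k_blocks <= 5):
            raise ValueError("trainable_last_k_blocks must be in [0, 5]")


@dataclass
class QualityNet:
    """A Sequential stack with named block and head layer ranges."""

    spec: BackboneSpec
    head_spec: HeadSpec
    net: Sequential
    block_slices: list[slice]
    head_slice: slice
    freeze: FreezePolicy = field(default_factory=lambda: FreezePolicy(5))

    # -- structure ---------------------------------------------------------
    def block_layers(self, block: int) -> list[Layer]:
        return self.net.layers[self.block_slices[block]]

    @property
    def head_layers(self) -> list[Layer]:
        return self.net.layers[self.head_slice]

    def conv_params(self) -> dict[str, np.ndarray]:
        stop = self.head_slice.start
        return {
            k: v for k, v in self.net.params().items() if int(k.split(".")[0]) < stop
        }

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.net.params().values())

    @property
    def n_trainable_params(self) -> int:
        return sum(p.size for p in self.net.trainable_params().values())

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, start: int = 0) -> np.ndarray:
        return self.net.forward(x.astype(np.float32, copy=False), train=train, start=start)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def first_trainable_layer(self) -> int:
        """Index of the shallowest layer with trainable parameters (len if none)."""
        for i, layer in enumerate(self.net.layers):
            if layer.trainable and layer.params():
                return i
        return len(self.net.layers)


def _make_head(spec: BackboneSpec, head: HeadSpec, rng: np.random.Generator) -> list[Layer]:
    width = spec.block_widths[-1]
    # rectified heads start with a positive bias so no output unit is born dead
    bias = 1.0 if head.resolved_activation == "relu" else 0.0
    layers: list[Layer] = [GlobalAvgPool(), Dense(width, head.outputs, rng, bias_init=bias)]
    if head.resolved_activation == "relu":
        layers.append(ReLU())
    elif head.resolved_activation != "linear":
        raise ValueError(f"unknown head activation {head.resolved_activation!r}")
    return layers


def build_backbone(
    spec: BackboneSpec | None = None,
    head: HeadSpec | None = None,
    init: str = "random",
    seed: int = 0,
    checkpoint: "str | Path | None" = None,
    imagenet_weights: "str | Path | None" = None,
) -> QualityNet:
    """Construct the 5-block backbone with the requested head.

    ``init`` is one of ``random`` (seeded He/Glorot), ``checkpoint`` (load
    parameters from :func:`save_checkpoint` output) or ``imagenet``
    (requires a locally converted weight file at ``imagenet_weights`` and
    ``base_width=64``; absent weights raise
    :class:`UnavailableResourceError`, never a silent fallback).
    """
    spec = spec or BackboneSpec()
    head = head or HeadSpec()
    rng = np.random.default_rng(seed)

    layers: list[Layer] = []
    block_slices: list[slice] = []
    c_in = spec.input_channels
    for width, n_convs in zip(spec.block_widths, spec.convs_per_block):
        start = len(layers)
        for _ in range(n_convs):
            layers.append(Conv3x3(c_in, width, rng))
            layers.append(ReLU())
            c_in = width
        layers.append(MaxPool2())
        block_slices.append(slice(start, len(layers)))
    head_start = len(layers)
    layers.extend(_make_head(spec, head, rng))
    model = QualityNet(
        spec=spec,
        head_spec=head,
        net=Sequential(layers),
        block_slices=block_slices,
        head_slice=slice(head_start, len(layers)),
    )

    if init == "random":
        pass
    elif init == "checkpoint":
        if checkpoint is None:
            raise ValueError("init='checkpoint' requires a checkpoint path")
        _load_params_into(model, checkpoint)
    elif init == "imagenet":
        if imagenet_weights is None or not Path(imagenet_weights).exists():
            raise UnavailableResourceError(
                "ImageNet weights are not available locally; download and convert "
                "them first, or use the pretext-pretraining path"
            )
        if spec.base_width != 64:
            raise ValueError("ImageNet initialisation requires base_width=64")
        _load_params_into(model, imagenet_weights, conv_only=True)
    else:
        raise ValueError(f"unknown init {init!r}")
    return model


def apply_freeze(model: QualityNet, policy: FreezePolicy) -> QualityNet:
    """Mark the first ``5 - k`` blocks non-trainable (in place)."""
    k = policy.trainable_last_k_blocks
    n_blocks = len(model.block_slices)
    if k > n_blocks:
        raise ValueError(f"policy trains last {k} blocks but model has {n_blocks}")
    for b in range(n_blocks):
        trainable = b >= n_blocks - k
        for layer in model.block_layers(b):
            if layer.params():
                layer.trainable = trainable
    for layer in model.head_layers:
        if layer.params():
            layer.trainable = policy.head_trainable
    model.freeze = policy
    return model


def replace_head(model: QualityNet, new_head: HeadSpec, seed: int = 0) -> QualityNet:
    """Swap in a freshly initialised head; convolutional parameters are untouched."""
    rng = np.random.default_rng(seed)
    layers = model.net.layers[: model.head_slice.start] + _make_head(model.spec, new_head, rng)
    out = QualityNet(
        spec=model.spec,
        head_spec=new_head,
        net=Sequential(layers),
        block_slices=model.block_slices,
        head_slice=slice(model.head_slice.start, len(layers)),
        freeze=model.freeze,
    )
    return out


# ---------------------------------------------------------------------------
# Checkpoints: .npz parameters + JSON sidecar describing the architecture
# ---------------------------------------------------------------------------


def save_checkpoint(model: QualityNet, path: str | Path, seed: int | None = None) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **model.net.params())
    sidecar = {
        "backbone": {
            "n_blocks": model.spec.n_blocks,
            "convs_per_block": list(model.spec.convs_per_block),
            "base_width": model.spec.base_width,
            "input_size": model.spec.input_size,
            "input_channels": model.spec.input_channels,
        },
        "head": {"kind": model.head_spec.kind, "activation": model.head_spec.activation},
        "freeze": {
            "trainable_last_k_blocks": model.freeze.trainable_last_k_blocks,
            "head_trainable": model.freeze.head_trainable,
        },
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _load_params_into(model: QualityNet, path: str | Path, conv_only: bool = False) -> None:
    with np.load(Path(path).with_suffix(".npz")) as data:
        stored = {k: data[k] for k in data.files}
    wanted = model.conv_params() if conv_only else model.net.params()
    for key, current in wanted.items():
        if key not in stored:
            raise ValueError(f"checkpoint incompatible: missing parameter {key!r}")
        if stored[key].shape != current.shape:
            raise ValueError(
                f"checkpoint incompatible: {key!r} has shape {stored[key].shape}, "
                f"model expects {current.shape}"
            )
        current[...] = stored[key]


def load_checkpoint(path: str | Path) -> QualityNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = BackboneSpec(
        n_blocks=meta["backbone"]["n_blocks"],
        convs_per_block=tuple(meta["backbone"]["convs_per_block"]),
        base_width=meta["backbone"]["base_width"],
        input_size=meta["backbone"]["input_size"],
        input_channels=meta["backbone"]["input_channels"],
    )
    head = HeadSpec(kind=meta["head"]["kind"], activation=meta["head"]["activation"])
    model = build_backbone(spec, head, init="checkpoint", checkpoint=path)
    policy = FreezePolicy(
        trainable_last_k_blocks=meta["freeze"]["trainable_last_k_blocks"],
        head_trainable=meta["freeze"]["head_trainable"],
    )
    return apply_freeze(model, policy)
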
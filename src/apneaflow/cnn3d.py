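"""Spatiotemporal CNNs for obstructive- vs central-apnea classification.

Two architectures are provided:

* a whole-body network that consumes the dense-optical-flow volume of an
  entire 10-s window, input ``(H, W, T, C) = (480, 640, 20, 2)`` at the
  nominal camera resolution — its layer stack is declared as a
  :class:`NetworkSpec` from which output shapes and exact parameter counts
  (95,649 total / 95,393 trainable / 256 non-trainable at nominal size) are
  computable without instantiating any weights;
* a two-branch late-fusion network whose branches process 100×100 crops
  around the chest and abdomen centers through the same stack, differing
  only in the first average-pooling layer (size 10×10, stride 5×5).

Label encoding is CA = 1 (positive class), OA = 0 throughout.

Convolutions are unpadded ("valid"); where a printed kernel omits the
temporal extent it is 1.  When a layer's kernel exceeds the available
extent of a small input (which happens in the fusion branches), the kernel
is clamped to that extent — a 2×2 kernel on a 1-pixel-wide map degrades to
1 in that dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import windowing
from .nn import (
    AvgPool3D,
    BatchNorm,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    MaxPool3D,
    ReLU,
    Sequential,
    Sigmoid,
    TrainConfig,
    TrainedModel,
    TwoBranchModel,
    train_model,
)

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ArchitectureError",
    "build_whole_body_net",
    "build_two_branch_net",
    "count_parameters",
    "train",
    "predict_event",
    "PAPER_INPUT_SHAPE",
    "DESK_INPUT_HW",
]

PAPER_INPUT_SHAPE = (480, 640, 20, 2)  # (H, W, T, C)
#: Reduced frame size whose 3×3/2×2 first pool lands on the same 23×31 grid
#: as the nominal 480×640 input, so all later shapes and parameter counts
#: are unchanged.
DESK_INPUT_HW = (48, 64)

LEAKY_SLOPE = 0.01
DROPOUT_RATE = 0.3


class ArchitectureError(ValueError):
    """A layer cannot be applied to its input shape."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a declarative network description.

    ``kernel``/``stride`` are (kh, kw, kt); ``activation`` is applied after
    the layer (batch-norm rows carry their activation as printed).
    """

    kind: str  # avgpool | conv | maxpool | batchnorm | dropout | flatten | dense
    filters: int | None = None
    kernel: tuple[int, int, int] | None = None
    stride: tuple[int, int, int] | None = None
    activation: str | None = None
    name: str = ""


def _pool_out(n: int, k: int, s: int) -> int:
    return (n - k) // s + 1


@dataclass
class NetworkSpec:
    """Declarative network: input shape plus an ordered layer list.

    Output shapes, the flatten width, and exact per-layer parameter counts
    are derived by propagation; :meth:`build` instantiates the matching
    :class:`~apneaflow.nn.Sequential`.
    """

    input_shape: tuple[int, int, int, int]
    layers: list[LayerSpec] = field(default_factory=list)

    def propagate(self) -> list[tuple]:
        """Per-layer output shapes ((H, W, T, C) tuples; flatten/dense give ints).

        Returns one entry per layer.  Kernels are clamped to the available
        extent; a non-positive dimension raises :class:`ArchitectureError`
        naming the layer.
        """
        shapes: list[tuple] = []
        shape = tuple(self.input_shape)
        for i, spec in enumerate(self.layers):
            label = spec.name or f"layer {i} ({spec.kind})"
            if spec.kind in ("avgpool", "maxpool", "conv"):
                if not isinstance(shape, tuple):
                    raise ArchitectureError(f"{label}: expected a volume input")
                h, w, t, c = shape
                kh, kw, kt = (min(k, n) for k, n in zip(spec.kernel, (h, w, t)))
                sh, sw, st = spec.stride if spec.stride else (1, 1, 1)
                out = (_pool_out(h, kh, sh), _pool_out(w, kw, sw), _pool_out(t, kt, st))
                if min(out) < 1:
                    raise ArchitectureError(
                        f"{label}: kernel {spec.kernel} does not fit input {shape}"
                    )
                shape = (*out, spec.filters if spec.kind == "conv" else c)
            elif spec.kind in ("batchnorm", "dropout"):
                pass
            elif spec.kind == "flatten":
                shape = int(np.prod(shape))
            elif spec.kind == "dense":
                if isinstance(shape, tuple):
                    raise ArchitectureError(f"{label}: dense layer needs a flat input")
                shape = int(spec.filters)
            else:
                raise ArchitectureError(f"{label}: unknown layer kind {spec.kind!r}")
            shapes.append(shape)
        return shapes

    def effective_kernels(self) -> list[tuple[int, int, int] | None]:
        """Kernels after clamping to the actual input extents."""
        kernels: list[tuple[int, int, int] | None] = []
        shape = tuple(self.input_shape)
        shapes = self.propagate()
        for spec, out in zip(self.layers, shapes):
            if spec.kind in ("avgpool", "maxpool", "conv"):
                h, w, t = shape[:3]
                kernels.append(tuple(min(k, n) for k, n in zip(spec.kernel, (h, w, t))))
            else:
                kernels.append(None)
            shape = out
        return kernels

    @property
    def flatten_width(self) -> int:
        for spec, shape in zip(self.layers, self.propagate()):
            if spec.kind == "flatten":
                return int(shape)
        raise ArchitectureError("network has no flatten layer")

    def parameter_counts(self) -> tuple[int, int, int]:
        """(total, trainable, non-trainable) parameter counts.

        Convolutions contribute ``kh·kw·kt·C_in·C_out + C_out``; dense layers
        ``n_in·n_out + n_out``; batch-norm 2 trainable (scale, shift) plus 2
        non-trainable (running mean, variance) per channel.  Pooling, dropout
        and flatten are parameter-free.
        """
        trainable = nontrainable = 0
        shape = tuple(self.input_shape)
        shapes = self.propagate()
        kernels = self.effective_kernels()
        for spec, out, keff in zip(self.layers, shapes, kernels):
            if spec.kind == "conv":
                c_in = shape[3]
                trainable += int(np.prod(keff)) * c_in * spec.filters + spec.filters
            elif spec.kind == "batchnorm":
                c = shape[3] if isinstance(shape, tuple) else shape
                trainable += 2 * c
                nontrainable += 2 * c
            elif spec.kind == "dense":
                trainable += int(shape) * spec.filters + spec.filters
            shape = out
        return trainable + nontrainable, trainable, nontrainable

    def build(self) -> Sequential:
        """Instantiate the spec as a trainable NumPy network."""
        layers = []
        shape = tuple(self.input_shape)
        shapes = self.propagate()
        kernels = self.effective_kernels()

        def activation(name):
            if name in (None, "linear"):
                return None
            return {
                "relu": ReLU,
                "leaky_relu": lambda: LeakyReLU(LEAKY_SLOPE),
                "sigmoid": Sigmoid,
            }[name]()

        for spec, out, keff in zip(self.layers, shapes, kernels):
            if spec.kind == "avgpool":
                layers.append(AvgPool3D(keff, spec.stride))
            elif spec.kind == "maxpool":
                layers.append(MaxPool3D(keff, spec.stride))
            elif spec.kind == "conv":
                layers.append(Conv3D(shape[3], spec.filters, keff))
            elif spec.kind == "batchnorm":
                layers.append(BatchNorm(shape[3] if isinstance(shape, tuple) else shape))
            elif spec.kind == "dropout":
                layers.append(Dropout(DROPOUT_RATE))
            elif spec.kind == "flatten":
                layers.append(Flatten())
            elif spec.kind == "dense":
                layers.append(Dense(int(shape), spec.filters))
            act = activation(spec.activation)
            if act is not None:
                layers.append(act)
            shape = out
        return Sequential(layers)


def _core_stack(first_pool_kernel, first_pool_stride, head: bool = True) -> list[LayerSpec]:
    stack = [
        LayerSpec("avgpool", kernel=first_pool_kernel, stride=first_pool_stride, name="avgpool1"),
        LayerSpec("conv", filters=8, kernel=(2, 2, 1), activation="linear", name="conv1"),
        LayerSpec("dropout", name="dropout1"),
        LayerSpec("conv", filters=16, kernel=(3, 3, 5), name="conv2"),
        LayerSpec("maxpool", kernel=(8, 8, 1), stride=(2, 2, 1), name="maxpool1"),
        LayerSpec("batchnorm", activation="leaky_relu", name="bn1"),
        LayerSpec("conv", filters=64, kernel=(2, 2, 2), name="conv3"),
        LayerSpec("batchnorm", activation="leaky_relu", name="bn2"),
        LayerSpec("conv", filters=32, kernel=(4, 4, 1), name="conv4"),
        LayerSpec("batchnorm", activation="relu", name="bn3"),
        LayerSpec("dropout", name="dropout2"),
        LayerSpec("conv", filters=16, kernel=(2, 2, 1), name="conv5"),
        LayerSpec("batchnorm", activation="relu", name="bn4"),
        LayerSpec("flatten", name="flatten"),
        LayerSpec("dense", filters=16, name="fc1"),
    ]
    if head:
        stack += [
            LayerSpec("dense", filters=4, name="fc2"),
            LayerSpec("dense", filters=1, activation="sigmoid", name="output"),
        ]
    return stack


_FIRST_POOL_PRESETS = {
    (480, 640): ((25, 25, 1), (20, 20, 1)),
    DESK_INPUT_HW: ((3, 3, 1), (2, 2, 1)),
}


def build_whole_body_net(
    input_shape: tuple[int, int, int, int] = PAPER_INPUT_SHAPE,
    first_pool: tuple[tuple, tuple] | None = None,
    instantiate: bool = True,
) -> tuple[NetworkSpec, Sequential | None]:
    """Build the whole-body 3D-CNN.

    At the nominal (480, 640) frame size the first average pool is
    25×25×1 / 20×20×1, landing on a 23×31 grid.  The (48, 64) desk preset
    uses a 3×3/2×2 pool that lands on the identical grid, so every later
    shape and all parameter counts match the nominal network.  Other frame
    sizes require an explicit ``first_pool``.
    """
    h, w, t, c = input_shape
    if first_pool is None:
        try:
            first_pool = _FIRST_POOL_PRESETS[(h, w)]
        except KeyError:
            raise ArchitectureError(
                f"no first-pool preset for frame size {(h, w)}; pass first_pool explicitly"
            ) from None
    spec = NetworkSpec(input_shape=tuple(input_shape), layers=_core_stack(*first_pool))
    return spec, (spec.build() if instantiate else None)


def build_two_branch_net(
    crop_size: int = 100,
    n_frames: int = 20,
    first_pool: tuple[tuple, tuple] = ((10, 10, 1), (5, 5, 1)),
    instantiate: bool = True,
) -> tuple[NetworkSpec, TwoBranchModel | None]:
    """Build the chest/abdomen two-branch fusion network.

    Each branch is the whole-body stack with the first average pool
    replaced by 10×10 / 5×5 (crop inputs are ``crop × crop × T × 2``),
    embedded to 16 features; the embeddings are concatenated into a fully
    connected head emitting one probability.  Returns the branch spec and
    the instantiated model.
    """
    if crop_size < first_pool[0][0]:
        raise ArchitectureError(
            f"crop size {crop_size} is smaller than the first pool {first_pool[0]}"
        )
    branch_spec = NetworkSpec(
        input_shape=(crop_size, crop_size, n_frames, 2),
        layers=_core_stack(*first_pool, head=False),
    )
    branch_spec.propagate()  # validate
    model = None
    if instantiate:
        head = Sequential([Dense(32, 4), ReLU(), Dense(4, 1), Sigmoid()])
        model = TwoBranchModel(branch_spec.build(), branch_spec.build(), head)
    return branch_spec, model


def count_parameters(network: Sequential | TwoBranchModel | NetworkSpec) -> tuple[int, int, int]:
    """(total, trainable, non-trainable) of a spec or instantiated network.

    Non-trainable parameters are exactly the batch-norm running statistics.
    """
    if isinstance(network, NetworkSpec):
        return network.parameter_counts()
    trainable = sum(int(p.size) for p in network.params())
    total = sum(int(s.size) for s in network.state())
    return total, trainable, total - trainable


def train(
    network,
    train_windows,
    train_labels,
    val_windows,
    val_labels,
    config: TrainConfig,
) -> TrainedModel:
    """Train a network on labeled windows with the shared protocol.

    Thin wrapper over :func:`apneaflow.nn.train_model`: RMSProp on
    class-weighted BCE, window-level validation MCC for early stopping,
    best-weights restoration.  CA = 1.
    """
    return train_model(network, train_windows, train_labels, val_windows, val_labels, config)


def predict_event(
    model,
    event,
    flow,
    crop_centers: tuple | None = None,
    crop_size: int = 100,
    batch_size: int = 32,
):
    """Score one annotated event: stride-1 test windows, then majority vote.

    ``model`` is anything with ``predict_proba`` (a trained network or a
    :class:`~apneaflow.nn.TrainedModel`'s ``.model``).  For two-branch
    models pass ``crop_centers = (chest_center, abdomen_center)`` in
    (x, y) pixels; windows are then cropped per branch.
    """
    from . import flowproc

    if isinstance(model, TrainedModel):
        model = model.model
    ws = windowing.make_windows(event, flow, stride=1.0, mode="test")
    tensors = np.stack([w.tensor for w in ws.windows]).astype(np.float32)
    if crop_centers is not None:
        crops = []
        for center in crop_centers:
            cropped = np.stack(
                [
                    flowproc.crop_region_flow_array(win, center, crop_size)
                    for win in tensors
                ]
            )
            crops.append(cropped.astype(np.float32))
        probs = model.predict_proba((crops[0], crops[1]), batch_size=batch_size)
    else:
        probs = model.predict_proba(tensors, batch_size=batch_size)
    return windowing.vote(list(map(float, probs)), event=event)
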
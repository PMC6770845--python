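"""The four counting architectures, assembled from three reusable parts.

* a U-Net **density branch** that regresses an image to its dot density
  map (encoder-decoder with skip connections, non-negative output),
* a convolutional **mask branch** autoencoder (3 conv+pool encoder
  stages, 3 conv+upsample decoder stages, sigmoid output in [0, 1]),
* a VGG-style **regression tail** (four blocks of batch-norm -> 3x3
  conv + leaky ReLU -> dropout 0.6 -> 2x2 max-pool, then two dense
  layers ending in one linear unit) that collapses decoded feature maps
  to a scalar count.

Model kinds:

``DRDCNN``  density branch -> tail (1 input channel)
``FRDCNN``  mask branch -> tail (1 input channel)
``ERDCNN``  channel-wise concatenation of both branches' decoded
            outputs -> tail (2 input channels)
``DDCNN``   density branch alone; the count is the summed density mass
            divided by the per-cell kernel mass (no regression tail)
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _nn
from ._nn import (Adam, BatchNorm2D, Conv2D, Dense, Dropout, Flatten,
                  LeakyReLU, MaxPool2D, ReLU, Sequential, Sigmoid, UNet,
                  Upsample2D)

__all__ = ["ArchitectureConfig", "NetworkHandle", "build_density_branch",
           "build_mask_branch", "build_regression_tail", "build_model",
           "predict_counts", "count_from_density", "audit_architecture",
           "MODEL_KINDS", "BRANCH_KINDS"]

MODEL_KINDS = ("DRDCNN", "FRDCNN", "ERDCNN", "DDCNN")
BRANCH_KINDS = ("density_branch", "mask_branch", "tail")


@dataclasses.dataclass(frozen=True)
class ArchitectureConfig:
    input_height: int = 256
    input_width: int = 256
    unet_depth: int = 4
    unet_base_filters: int = 32
    ae_filters: tuple[int, int, int] = (32, 16, 8)
    tail_blocks: int = 4          # fixed by the architecture definition
    tail_filters: tuple[int, int, int, int] = (32, 64, 128, 128)
    tail_dense_units: int = 128
    dropout_rate: float = 0.6
    leaky_slope: float = 0.3
    density_scale: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.tail_blocks != 4:
            raise ValueError("the regression tail has exactly 4 blocks")
        div = 2 ** max(self.unet_depth, 3, self.tail_blocks)
        if self.input_height % div or self.input_width % div:
            raise ValueError(
                f"input dims {self.input_height}x{self.input_width} must be "
                f"divisible by {div}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if self.density_scale <= 0:
            raise ValueError("density_scale must be positive")


@dataclasses.dataclass
class NetworkHandle:
    """An assembled architecture plus its weights and trainability flags.

    ``components`` maps component names (density_branch / mask_branch /
    tail) to network modules; ``trainable`` flags whether a component's
    weights may change during a training stage.
    """

    kind: str
    config: ArchitectureConfig
    components: dict
    trainable: dict
    stage_results: list = dataclasses.field(default_factory=list)

    def get_weights(self):
        state = {}
        for name, module in self.components.items():
            state.update(_nn.get_weights(module, prefix=name + "/"))
        return state

    def set_weights(self, state):
        for name, module in self.components.items():
            sub = {k: v for k, v in state.items() if k.startswith(name + "/")}
            _nn.set_weights(module, sub, prefix=name + "/")

    def branch_names(self):
        return [n for n in self.components if n != "tail"]


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_density_branch(config: ArchitectureConfig, seed=None) -> NetworkHandle:
    """U-Net image -> dot-density-map regressor (ReLU output, so the
    predicted map is non-negative everywhere)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    net = UNet(in_ch=1, depth=config.unet_depth,
               base_filters=config.unet_base_filters, rng=rng)
    return NetworkHandle("density_branch", config, {"density_branch": net},
                         {"density_branch": True})


def build_mask_branch(config: ArchitectureConfig, seed=None) -> NetworkHandle:
    """Plain convolutional autoencoder image -> foreground mask.

    Three conv(3x3)+ReLU+max-pool encoder stages and three
    conv(3x3)+upsample decoder stages — six convolutional layers in
    total, no skip connections — ending in a sigmoid so the predicted
    mask lives in [0, 1]. Weights are initialized orthogonally.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    f1, f2, f3 = config.ae_filters
    mk = lambda ci, co: Conv2D(ci, co, 3, init="orthogonal", rng=rng)
    net = Sequential([
        mk(1, f1), ReLU(), MaxPool2D(),
        mk(f1, f2), ReLU(), MaxPool2D(),
        mk(f2, f3), ReLU(), MaxPool2D(),
        mk(f3, f2), ReLU(), Upsample2D(),
        mk(f2, f1), ReLU(), Upsample2D(),
        mk(f1, 1), Upsample2D(),
        Sigmoid(),
    ])
    # prior-probability init: start the sigmoid output near the typical
    # foreground fraction, so MSE against sparse masks does not have to
    # wash the decoder weights out to reach the base rate (after which
    # gradients are too small to recover any structure)
    out_conv = [l for l in net.layers if isinstance(l, Conv2D)][-1]
    out_conv.params["b"][:] = -2.0
    return NetworkHandle("mask_branch", config, {"mask_branch": net},
                         {"mask_branch": True})


def build_regression_tail(config: ArchitectureConfig, in_channels: int = 1,
                          seed=None) -> NetworkHandle:
    """VGG-style tail: 4 x [BN -> 3x3 conv + leaky ReLU -> dropout ->
    2x2 max-pool], flatten, dense(hidden) + leaky ReLU, dense(1)."""
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    layers = []
    ci = in_channels
    for f in config.tail_filters:
        layers += [BatchNorm2D(ci), Conv2D(ci, f, 3, rng=rng),
                   LeakyReLU(config.leaky_slope), Dropout(config.dropout_rate),
                   MaxPool2D()]
        ci = f
    fh = config.input_height // 2 ** config.tail_blocks
    fw = config.input_width // 2 ** config.tail_blocks
    layers += [Flatten(),
               Dense(fh * fw * ci, config.tail_dense_units, rng=rng),
               LeakyReLU(config.leaky_slope),
               Dense(config.tail_dense_units, 1, rng=rng)]
    net = Sequential(layers)
    net.in_channels = in_channels
    return NetworkHandle("tail", config, {"tail": net}, {"tail": True})


def build_model(kind: str, config: ArchitectureConfig, seed=None) -> NetworkHandle:
    """Assemble a full model of the given kind from fresh parts."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    seed = config.seed if seed is None else seed
    components, trainable = {}, {}
    if kind in ("DRDCNN", "ERDCNN", "DDCNN"):
        h = build_density_branch(config, seed=seed)
        components["density_branch"] = h.components["density_branch"]
        trainable["density_branch"] = True
    if kind in ("FRDCNN", "ERDCNN"):
        h = build_mask_branch(config, seed=seed)
        components["mask_branch"] = h.components["mask_branch"]
        trainable["mask_branch"] = True
    if kind != "DDCNN":
        in_ch = 2 if kind == "ERDCNN" else 1
        h = build_regression_tail(config, in_channels=in_ch, seed=seed)
        components["tail"] = h.components["tail"]
        trainable["tail"] = True
    return NetworkHandle(kind, config, components, trainable)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _as_batch(images, config):
    x = np.asarray(images, dtype=_nn.DTYPE)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[1] != config.input_height or x.shape[2] != config.input_width:
        raise ValueError(
            f"image shape {x.shape[1:3]} does not match configured input "
            f"{config.input_height}x{config.input_width}")
    return x


def forward_features(handle: NetworkHandle, x4, training=False):
    """Decoded branch output(s) for a prepared NHWC batch; multiple
    branches are concatenated along the channel axis."""
    maps = []
    for name in ("density_branch", "mask_branch"):
        if name in handle.components:
            train_branch = training and handle.trainable.get(name, False)
            maps.append(handle.components[name].forward(x4, training=train_branch))
    return maps[0] if len(maps) == 1 else np.concatenate(maps, axis=-1)


def predict_counts(handle: NetworkHandle, images, batch_size: int = 16) -> np.ndarray:
    """One finite scalar count estimate per image (eval mode).

    For DDCNN the estimate is the summed predicted density mass divided
    by the per-cell kernel mass; regression kinds apply the tail.
    """
    x = np.asarray(images, dtype=_nn.DTYPE)
    if x.ndim == 3 and x.shape[0] == 0:
        return np.zeros(0)
    x4 = _as_batch(images, handle.config)
    out = []
    for i in range(0, len(x4), batch_size):
        xb = x4[i:i + batch_size]
        feats = forward_features(handle, xb, training=False)
        if handle.kind == "DDCNN":
            out.append(count_from_density(feats[..., 0],
                                          handle.config.density_scale))
        else:
            pred = handle.components["tail"].forward(feats, training=False)
            out.append(pred[:, 0])
    pred = np.concatenate([np.atleast_1d(o) for o in out]).astype(float)
    if not np.isfinite(pred).all():
        raise FloatingPointError("non-finite count prediction")
    return pred


def count_from_density(density_map, scale: float):
    """Count estimate = total density mass / per-cell kernel mass
    (continuous, not rounded). Accepts one map or a batch."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    d = np.asarray(density_map, dtype=float)
    if d.ndim == 2:
        return float(d.sum() / scale)
    return d.sum(axis=(1, 2)) / scale


# ---------------------------------------------------------------------------
# introspection
# ---------------------------------------------------------------------------

def audit_architecture(handle: NetworkHandle) -> dict:
    """Structural facts about an assembled model, for verification:
    tail block count and layout, dense-layer count, dropout rates,
    kernel sizes, mask-branch stage counts, tail input channels."""
    info: dict = {"kind": handle.kind,
                  "has_tail": "tail" in handle.components,
                  "dense_layers": 0}
    if "tail" in handle.components:
        layers = handle.components["tail"].layers
        blocks = 0
        i = 0
        while i + 4 < len(layers):
            group = layers[i:i + 5]
            if (isinstance(group[0], BatchNorm2D) and isinstance(group[1], Conv2D)
                    and isinstance(group[2], LeakyReLU)
                    and isinstance(group[3], Dropout)
                    and isinstance(group[4], MaxPool2D)):
                blocks += 1
                i += 5
            else:
                break
        info["tail_conv_blocks"] = blocks
        info["dense_layers"] = sum(isinstance(l, Dense) for l in layers)
        info["tail_in_channels"] = handle.components["tail"].in_channels
        info["tail_kernel_sizes"] = sorted({l.ksize for l in layers
                                            if isinstance(l, Conv2D)})
        info["tail_dropout_rates"] = sorted({l.rate for l in layers
                                             if isinstance(l, Dropout)})
    if "mask_branch" in handle.components:
        layers = handle.components["mask_branch"].layers
        # the encoder ends at the last max-pool; decoder stages follow
        last_pool = max(i for i, l in enumerate(layers)
                        if isinstance(l, MaxPool2D))
        n_enc = sum(isinstance(l, Conv2D) for l in layers[:last_pool + 1])
        info["mask_encoder_convs"] = n_enc
        info["mask_decoder_convs"] = (sum(isinstance(l, Conv2D) for l in layers)
                                      - n_enc)
        info["mask_pools"] = sum(isinstance(l, MaxPool2D) for l in layers)
        info["mask_upsamples"] = sum(isinstance(l, Upsample2D) for l in layers)
    if "density_branch" in handle.components:
        net = handle.components["density_branch"]
        info["unet_depth"] = net.depth
        info["unet_has_skips"] = True
    return info
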
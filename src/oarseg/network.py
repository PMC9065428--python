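"""3D residual U-Net with deep supervision and switchable decoder up-sampling.

The architecture follows the classic encoder/decoder layout: residual
blocks of zero-padded 3x3x3 convolutions with 2x2x2 max-pooling between
encoder levels, and either stride-2 2x2x2 transpose convolutions
(``decoder_mode="transpose"``) or trilinear up-sampling followed by a
zero-padded 3x3x3 convolution (``decoder_mode="resize"``) between decoder
levels.  Residual shortcuts use 1x1x1 projection convolutions wherever the
block changes its channel count.  Deep supervision attaches bottleneck
1x1x1 classification heads to the coarser decoder features; the auxiliary
class maps are resampled trilinearly to full resolution and only emitted in
training mode.

The reference configuration (:func:`reference_network_config`) uses four
resolution levels with feature widths (32, 64, 128, 256).  Encoder blocks
run ``conv(c_in -> c_out/2) -> conv(c_out/2 -> c_out)`` — the stem is
``in -> 16 -> 32`` — and decoder blocks ``conv(concat -> mid) ->
conv(mid -> c_out)`` with mid widths (128, 72, 21).  The interior widths are
a reconstruction: the four reference trainable-parameter totals pin the
stem, the level widths, the channel-preserving up-sampling stages and the
input/decoder deltas, and the remaining two mid widths are solved so that
all four totals are reproduced exactly (see docs/methods.md).  The
reference configuration uses plain biased convolutions with no
normalisation layers; affine instance normalisation is available via
``norm_kind="instance"`` for small-scale training runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import functional as F
from .volume import LabelMap


class ConfigurationError(ValueError):
    """Inconsistent network configuration."""


@dataclass(frozen=True)
class NetworkConfig:
    """Complete architecture description; the parameter count follows from it."""

    in_channels: int = 1
    num_classes: int = 6
    channel_scheme: tuple[int, ...] = (32, 64, 128, 256)
    decoder_mode: str = "transpose"  # "transpose" | "resize"
    deep_supervision: bool = True
    norm_kind: str = "none"  # "none" | "instance"
    #: First-conv width of each encoder block; None means half the block output.
    encoder_mid_channels: tuple[int, ...] | None = None
    #: First-conv width of each decoder block; None means the block output.
    decoder_mid_channels: tuple[int, ...] | None = None
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be >= 1")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        if len(self.channel_scheme) < 2:
            raise ConfigurationError("need at least two resolution levels")
        if self.decoder_mode not in ("transpose", "resize"):
            raise ConfigurationError(f"unknown decoder_mode {self.decoder_mode!r}")
        if self.norm_kind not in ("none", "instance"):
            raise ConfigurationError(f"unknown norm_kind {self.norm_kind!r}")
        for name, mids, expect in (
            ("encoder_mid_channels", self.encoder_mid_channels, self.levels),
            ("decoder_mid_channels", self.decoder_mid_channels, self.levels - 1),
        ):
            if mids is not None and len(mids) != expect:
                raise ConfigurationError(f"{name} must have length {expect}")

    @property
    def levels(self) -> int:
        return len(self.channel_scheme)

    @property
    def stem_channels(self) -> int:
        mids = self.resolved_encoder_mids()
        return mids[0]

    def resolved_encoder_mids(self) -> tuple[int, ...]:
        if self.encoder_mid_channels is not None:
            return tuple(self.encoder_mid_channels)
        return tuple(max(c // 2, 1) for c in self.channel_scheme)

    def resolved_decoder_mids(self) -> tuple[int, ...]:
        if self.decoder_mid_channels is not None:
            return tuple(self.decoder_mid_channels)
        return tuple(reversed(self.channel_scheme[:-1]))


def reference_network_config(in_channels: int = 3, decoder_mode: str = "transpose") -> NetworkConfig:
    """The reference architecture (see module docstring for provenance)."""
    if in_channels not in (1, 3):
        raise ConfigurationError("the reference model uses 1 or 3 input channels")
    return NetworkConfig(
        in_channels=in_channels,
        num_classes=6,
        channel_scheme=(32, 64, 128, 256),
        decoder_mode=decoder_mode,
        deep_supervision=True,
        norm_kind="none",
        encoder_mid_channels=(16, 32, 64, 128),
        decoder_mid_channels=(128, 72, 21),
    )


class _ResidualBlock(nn.Module):
    def __init__(self, c_in, c_mid, c_out, norm_kind, *, rng, dtype):
        self.conv1 = nn.Conv3d(c_in, c_mid, 3, rng=rng, dtype=dtype)
        self.conv2 = nn.Conv3d(c_mid, c_out, 3, rng=rng, dtype=dtype)
        self.norm1 = nn.InstanceNorm3d(c_mid, dtype=dtype) if norm_kind == "instance" else None
        self.norm2 = nn.InstanceNorm3d(c_out, dtype=dtype) if norm_kind == "instance" else None
        self.proj = (
            nn.Conv3d(c_in, c_out, 1, rng=rng, dtype=dtype) if c_in != c_out else None
        )

    def __call__(self, x):
        h = self.conv1(x)
        if self.norm1 is not None:
            h = self.norm1(h)
        h = h.relu()
        h = self.conv2(h)
        if self.norm2 is not None:
            h = self.norm2(h)
        shortcut = self.proj(x) if self.proj is not None else x
        return (h + shortcut).relu()


class _UpStage(nn.Module):
    """Channel-preserving 2x up-sampling: transpose conv or resize conv."""

    def __init__(self, channels, mode, *, rng, dtype):
        self.mode = mode
        if mode == "transpose":
            self.up = nn.ConvTranspose3d(channels, channels, rng=rng, dtype=dtype)
        else:
            self.up = nn.Conv3d(channels, channels, 3, rng=rng, dtype=dtype)

    def __call__(self, x):
        if self.mode == "transpose":
            return self.up(x)
        return self.up(F.upsample_trilinear2x(x))


class SegmentationNetwork(nn.Module):
    """Res-UNet3D; callable on a ``(C, X, Y, Z)`` array or Tensor."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.training = False
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype).type
        ch = config.channel_scheme
        enc_mids = config.resolved_encoder_mids()
        dec_mids = config.resolved_decoder_mids()

        self.encoder = []
        c_in = config.in_channels
        for c_out, c_mid in zip(ch, enc_mids):
            self.encoder.append(
                _ResidualBlock(c_in, c_mid, c_out, config.norm_kind, rng=rng, dtype=dtype)
            )
            c_in = c_out

        self.ups = []
        self.decoder = []
        skips = list(reversed(ch[:-1]))  # e.g. (128, 64, 32)
        c = ch[-1]
        for skip, c_mid in zip(skips, dec_mids):
            self.ups.append(_UpStage(c, config.decoder_mode, rng=rng, dtype=dtype))
            self.decoder.append(
                _ResidualBlock(c + skip, c_mid, skip, config.norm_kind, rng=rng, dtype=dtype)
            )
            c = skip

        self.head = nn.Conv3d(c, config.num_classes, 1, rng=rng, dtype=dtype)
        self.aux_heads = []
        if config.deep_supervision:
            # heads on the bottleneck and every decoder feature above full res
            for feat in [ch[-1]] + skips[:-1]:
                self.aux_heads.append(
                    nn.Conv3d(feat, config.num_classes, 1, rng=rng, dtype=dtype)
                )

    # -- mode switches ---------------------------------------------------------
    def train_mode(self) -> "SegmentationNetwork":
        self.training = True
        return self

    def eval_mode(self) -> "SegmentationNetwork":
        self.training = False
        return self

    # -- forward ---------------------------------------------------------------
    def _pad_to_divisible(self, x: nn.Tensor):
        div = 2 ** (self.config.levels - 1)
        pads = [(0, 0)]
        slices = [slice(None)]
        for n in x.shape[1:]:
            target = int(np.ceil(n / div)) * div
            lo = (target - n) // 2
            hi = target - n - lo
            pads.append((lo, hi))
            slices.append(slice(lo, lo + n))
        if any(p != (0, 0) for p in pads):
            x = x.pad(pads)
        return x, tuple(slices)

    def __call__(self, x):
        """Return the full-resolution class-probability map.

        In training mode with deep supervision the return value is
        ``(main, [aux...])`` where every auxiliary map is already resampled
        to full resolution and softmax-normalised.
        """
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=self.config.dtype))
        if x.data.ndim != 4:
            raise ValueError(f"expected a (C, X, Y, Z) input, got shape {x.shape}")
        if x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"input has {x.shape[0]} channels but the network expects "
                f"{self.config.in_channels}"
            )
        x, out_slices = self._pad_to_divisible(x)

        skips = []
        h = x
        for i, block in enumerate(self.encoder):
            h = block(h)
            if i < len(self.encoder) - 1:
                skips.append(h)
                h = F.max_pool3d(h)

        aux_feats = [h]  # bottleneck
        for up, block, skip in zip(self.ups, self.decoder, reversed(skips)):
            h = block(nn.concat([up(h), skip], axis=0))
            aux_feats.append(h)

        logits = self.head(h)
        main = F.softmax_channels(logits)[out_slices]

        if self.training and self.config.deep_supervision:
            aux_out = []
            for head, feat, level in zip(
                self.aux_heads, aux_feats, range(len(self.aux_heads), 0, -1)
            ):
                a = head(feat)
                for _ in range(level):
                    a = F.upsample_trilinear2x(a)
                aux_out.append(F.softmax_channels(a)[out_slices])
            return main, aux_out
        return main


def build_network(config: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    return SegmentationNetwork(config, seed=seed)


def count_trainable_parameters(network: SegmentationNetwork) -> int:
    """Exact number of trainable scalars (kernels, biases, norm affines)."""
    return network.n_parameters()


def predict_labels(probs, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
    """Voxel-wise argmax; ties break toward the lowest class index."""
    p = probs.data if isinstance(probs, nn.Tensor) else np.asarray(probs)
    return LabelMap(labels=p.argmax(axis=0).astype(np.int16), spacing=spacing)


# -- checkpointing --------------------------------------------------------------

def save_checkpoint(network: SegmentationNetwork, path) -> None:
    """Single-file checkpoint with the config embedded for reload."""
    cfg = asdict(network.config)
    arrays = {f"p{i}": a for i, a in enumerate(network.state_arrays())}
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> SegmentationNetwork:
    with np.load(path, allow_pickle=False) as data:
        cfg_raw = json.loads(str(data["__config__"]))
        for key in ("channel_scheme", "encoder_mid_channels", "decoder_mid_channels"):
            if cfg_raw.get(key) is not None:
                cfg_raw[key] = tuple(cfg_raw[key])
        config = NetworkConfig(**cfg_raw)
        net = SegmentationNetwork(config)
        arrays = [data[f"p{i}"] for i in range(len(net.parameters()))]
        net.load_state_arrays(arrays)
    return net
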
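"""Structured run configuration (YAML) with strict schema validation.

A config file has nested sections mirroring the library objects::

    seed: 0
    input_mode: multi          # "baseline" (1 channel) or "multi" (3 channels)
    windows:                   # optional per-channel overrides
      - {name: soft-tissue, level: 40, width: 400}
    network: {decoder_mode: transpose, deep_supervision: true, ...}
    loss: {kind: explog, xe_coefficient: 1.0}
    augmentation: {mirror_prob: 0.5, ...}
    train: {initial_lr: 0.01, ...}
    crop: {target_shape: [200, 200, 56]}

Unknown keys anywhere are rejected before any computation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .augmentation import AugmentationPolicy
from .io import CropSpec
from .losses import LOSS_KINDS
from .network import NetworkConfig, reference_network_config
from .training import TrainConfig
from .windowing import MULTI_WINDOW_NAMES, WindowSpec, get_preset


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


@dataclass(frozen=True)
class LossSettings:
    kind: str = "explog"
    xe_coefficient: float = 1.0
    ds_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ConfigError(f"loss kind must be one of {LOSS_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    input_mode: str = "multi"  # "baseline" | "multi"
    windows: tuple[WindowSpec, ...] | None = None
    network: NetworkConfig = field(default_factory=lambda: reference_network_config(3))
    loss: LossSettings = field(default_factory=LossSettings)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    train: TrainConfig = field(default_factory=TrainConfig)
    crop: CropSpec = field(default_factory=CropSpec)

    def __post_init__(self) -> None:
        if self.input_mode not in ("baseline", "multi"):
            raise ConfigError(f"input_mode must be 'baseline' or 'multi', got {self.input_mode!r}")
        expected = 1 if self.input_mode == "baseline" else 3
        if self.network.in_channels != expected:
            raise ConfigError(
                f"input_mode {self.input_mode!r} implies {expected} network input "
                f"channel(s), config says {self.network.in_channels}"
            )

    def window_specs(self) -> tuple[WindowSpec, ...]:
        if self.windows is not None:
            return self.windows
        if self.input_mode == "baseline":
            return (get_preset("baseline"),)
        return tuple(get_preset(n) for n in MULTI_WINDOW_NAMES)


def _build(cls, section: dict, name: str, tuple_keys=()):
    if section is None:
        return cls()
    if not isinstance(section, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    kwargs = dict(section)
    for key in tuple_keys:
        if kwargs.get(key) is not None:
            val = kwargs[key]
            if key == "lr_label_pairs":
                kwargs[key] = tuple(tuple(p) for p in val)
            else:
                kwargs[key] = tuple(val)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def parse_config(raw: dict | None) -> RunConfig:
    raw = dict(raw or {})
    known = {"seed", "input_mode", "windows", "network", "loss", "augmentation", "train", "crop"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    windows = None
    if raw.get("windows") is not None:
        if not isinstance(raw["windows"], list):
            raise ConfigError("'windows' must be a list of {name, level, width}")
        windows = tuple(
            _build(WindowSpec, w, f"windows[{i}]") for i, w in enumerate(raw["windows"])
        )

    input_mode = raw.get("input_mode", "multi")
    if raw.get("network") is None:
        # default to the reference architecture matching the input mode
        network = reference_network_config(1 if input_mode == "baseline" else 3)
    else:
        network = _build(
            NetworkConfig, raw.get("network"), "network",
            tuple_keys=("channel_scheme", "encoder_mid_channels", "decoder_mid_channels"),
        )
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        input_mode=input_mode,
        windows=windows,
        network=network,
        loss=_build(LossSettings, raw.get("loss"), "loss", tuple_keys=("ds_weights",)),
        augmentation=_build(
            AugmentationPolicy, raw.get("augmentation"), "augmentation",
            tuple_keys=("shift_max", "scale_range", "lr_label_pairs"),
        ),
        train=_build(TrainConfig, raw.get("train"), "train"),
        crop=_build(CropSpec, raw.get("crop"), "crop", tuple_keys=("target_shape", "centre")),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh))


def dump_config(config: RunConfig) -> dict:
    """Plain-dict form suitable for YAML serialisation (round-trips)."""
    out = {
        "seed": config.seed,
        "input_mode": config.input_mode,
        "network": asdict(config.network),
        "loss": asdict(config.loss),
        "augmentation": asdict(config.augmentation),
        "train": asdict(config.train),
        "crop": asdict(config.crop),
    }
    if config.windows is not None:
        out["windows"] = [asdict(w) for w in config.windows]
    for key in ("channel_scheme", "encoder_mid_channels", "decoder_mid_channels"):
        if out["network"].get(key) is not None:
            out["network"][key] = list(out["network"][key])
    if out["loss"].get("ds_weights") is not None:
        out["loss"]["ds_weights"] = list(out["loss"]["ds_weights"])
    aug = out["augmentation"]
    aug["shift_max"] = list(aug["shift_max"])
    aug["scale_range"] = list(aug["scale_range"])
    aug["lr_label_pairs"] = [list(p) for p in aug["lr_label_pairs"]]
    out["crop"]["target_shape"] = list(out["crop"]["target_shape"])
    if out["crop"].get("centre") is not None:
        out["crop"]["centre"] = list(out["crop"]["centre"])
    return out


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dump_config(config), fh, sort_keys=False)
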
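"""Clinician-style window/level intensity normalisation.

A CT window is a ``(level, width)`` pair.  The ramp maps HU intensity ``I``
to ``clip((I - (L - W/2)) / W, 0, 1)``: everything below the lower window
edge saturates at 0, everything above the upper edge at 1, and the window
midpoint maps to 0.5.  Stacking several windows yields a multi-channel
network input in which each channel enhances a different tissue class,
analogous to RGB channels in natural images.

The full-width baseline window ``L=488, W=3024`` spans [-1024, 2512] HU and
standardises the whole usable Hounsfield range onto [0, 1] in one channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import CTVolume


class WindowError(ValueError):
    """Invalid window specification."""


@dataclass(frozen=True)
class WindowSpec:
    """A window ``(level, width)`` in HU with a human-readable tag."""

    level: float
    width: float
    name: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.level) or not np.isfinite(self.width):
            raise WindowError("window level and width must be finite")
        if self.width <= 0:
            raise WindowError(f"window width must be positive, got {self.width}")

    @property
    def lower(self) -> float:
        return self.level - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.level + self.width / 2.0


@dataclass(frozen=True)
class WindowedInput:
    """Channel-major stack of windowed volumes, each channel in [0, 1]."""

    channels: np.ndarray  # (n_channels, nx, ny, nz)
    specs: tuple[WindowSpec, ...]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


#: Default presets.  The baseline covers the full HU range; the three
#: contrast channels are standard radiological viewing windows for soft
#: tissue, bony anatomy and brain tissue.  All are overridable via config.
_DEFAULT_PRESETS = {
    "baseline": WindowSpec(level=488.0, width=3024.0, name="baseline"),
    "soft-tissue": WindowSpec(level=40.0, width=400.0, name="soft-tissue"),
    "bone": WindowSpec(level=400.0, width=1800.0, name="bone"),
    "brain": WindowSpec(level=40.0, width=80.0, name="brain"),
}

#: Channel order of the three-window input.
MULTI_WINDOW_NAMES = ("soft-tissue", "bone", "brain")


def window_presets() -> dict[str, WindowSpec]:
    """Return a fresh copy of the named preset registry."""
    return dict(_DEFAULT_PRESETS)


def get_preset(name: str) -> WindowSpec:
    try:
        return _DEFAULT_PRESETS[name]
    except KeyError:
        raise WindowError(
            f"unknown window preset {name!r}; known: {sorted(_DEFAULT_PRESETS)}"
        ) from None


def apply_window(volume: CTVolume | np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Map intensities through the window ramp onto [0, 1].

    Shape is preserved; the output dtype is float32.
    """
    data = volume.intensities if isinstance(volume, CTVolume) else np.asarray(volume)
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot window non-finite intensities")
    out = (data.astype(np.float32) - np.float32(spec.lower)) / np.float32(spec.width)
    np.clip(out, 0.0, 1.0, out=out)
    return out


def stack_windows(
    volume: CTVolume, specs: list[WindowSpec] | tuple[WindowSpec, ...]
) -> WindowedInput:
    """Apply each window and concatenate along a leading channel axis.

    Channel ``k`` is ``apply_window(volume, specs[k])``; the channel order
    follows the given window order and is stable across calls.
    """
    specs = tuple(specs)
    if not specs:
        raise WindowError("at least one window spec is required")
    channels = np.stack([apply_window(volume, s) for s in specs], axis=0)
    return WindowedInput(channels=channels, specs=specs)


def baseline_input(volume: CTVolume) -> WindowedInput:
    """Single-channel input normalised with the full-width baseline window."""
    return stack_windows(volume, [get_preset("baseline")])


def multi_window_input(
    volume: CTVolume, names: tuple[str, ...] = MULTI_WINDOW_NAMES
) -> WindowedInput:
    """Three-channel input with the soft-tissue / bone / brain contrast windows."""
    return stack_windows(volume, [get_preset(n) for n in names])
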
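"""Core volumetric containers: calibrated CT volumes and integer label maps.

Axis convention (pinned repo-wide): arrays are indexed ``(x, y, z)`` with
``x`` = patient left-right (the mid-sagittal mirror axis), ``y`` =
antero-posterior and ``z`` = cranio-caudal.  Voxel spacing is in mm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Air on the Hounsfield scale; also the fill value for out-of-field voxels.
AIR_HU = -1024.0

#: Fixed label coding: background first, then the five organs-at-risk.
ORGAN_LABELS = {
    "background": 0,
    "brainstem": 1,
    "mandible": 2,
    "parotid_left": 3,
    "parotid_right": 4,
    "spinal_cord": 5,
}
ORGAN_NAMES = {v: k for k, v in ORGAN_LABELS.items()}
#: Label-code pairs swapped under lateral mirroring.
LR_LABEL_PAIRS = ((ORGAN_LABELS["parotid_left"], ORGAN_LABELS["parotid_right"]),)


class GeometryError(ValueError):
    """Raised when paired volumes disagree in shape or spacing."""


@dataclass
class CTVolume:
    """A 3D scalar field in Hounsfield units with anisotropic voxel spacing.

    Parameters
    ----------
    intensities
        3D float array of HU values, indexed (x, y, z).
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm, all strictly positive.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.intensities.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("CT intensities must be finite")
        if np.any(self.intensities < AIR_HU):
            # scanner padding conventions vary; values below air are legal but suspect
            warnings.warn(
                "volume contains intensities below -1024 HU (scanner padding?); "
                "they will clamp to the window floor",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class LabelMap:
    """Integer-coded segmentation, geometry-locked to its :class:`CTVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label maps must be integer-valued")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def organ_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def check_same_geometry(a, b) -> None:
    """Raise :class:`GeometryError` unless ``a`` and ``b`` share shape and spacing."""
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa = getattr(a, "spacing", None)
    sb = getattr(b, "spacing", None)
    if sa is not None and sb is not None and not np.allclose(sa, sb):
        raise GeometryError(f"spacing mismatch: {sa} vs {sb}")
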
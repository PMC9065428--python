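"""NIfTI I/O and the fixed-size sub-volume crop.

Volumes are stored and read as ``.nii`` / ``.nii.gz``; on read the image is
reoriented to the closest canonical (RAS) axes so the in-memory arrays
always follow the repo-wide (x = left-right, y = antero-posterior,
z = cranio-caudal) convention, and the voxel spacing is taken from the
header.  The crop produces an exactly target-shaped sub-volume centred on a
requested voxel (default: the volume centre), padding with air / background
where it reaches outside, and records the offset so predictions can be
mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .volume import AIR_HU, CTVolume, LabelMap, check_same_geometry


class IOError_(RuntimeError):
    """File-level failure with an explicit message."""


def _load_canonical(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - reported with context
        raise IOError_(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise IOError_(f"{path}: missing or invalid voxel spacing {zooms}")
    return img, tuple(float(z) for z in zooms)


def read_volume(path) -> CTVolume:
    img, spacing = _load_canonical(path)
    return CTVolume(np.asarray(img.dataobj, dtype=np.float32), spacing)


def write_volume(volume: CTVolume, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine), str(path))


def read_labels(path) -> LabelMap:
    img, spacing = _load_canonical(path)
    data = np.asarray(img.dataobj)
    rounded = np.rint(data).astype(np.int16)
    if not np.allclose(data, rounded, atol=1e-3):
        raise IOError_(f"{path}: label map contains non-integer values")
    return LabelMap(rounded, spacing)


def write_labels(labels: LabelMap, path) -> None:
    affine = np.diag(list(labels.spacing) + [1.0])
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine), str(path))


def read_pair(ct_path, label_path) -> tuple[CTVolume, LabelMap]:
    """Load a CT and its label map, enforcing identical geometry."""
    ct = read_volume(ct_path)
    lab = read_labels(label_path)
    check_same_geometry(ct, lab)
    return ct, lab


# -- fixed-size crop ------------------------------------------------------------

@dataclass(frozen=True)
class CropSpec:
    target_shape: tuple[int, int, int] = (200, 200, 56)
    centre: tuple[int, int, int] | None = None  # None => volume centre

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.target_shape):
            raise ValueError(f"target shape must be positive, got {self.target_shape}")


@dataclass(frozen=True)
class CropOffset:
    """Start index of the crop in the original volume (may be negative)."""

    start: tuple[int, int, int]
    original_shape: tuple[int, int, int]


def _crop_array(data: np.ndarray, start, target, fill):
    out = np.full(target, fill, dtype=data.dtype)
    src = []
    dst = []
    for ax in range(3):
        s0 = max(start[ax], 0)
        s1 = min(start[ax] + target[ax], data.shape[ax])
        if s1 <= s0:
            return out  # crop entirely outside
        src.append(slice(s0, s1))
        dst.append(slice(s0 - start[ax], s1 - start[ax]))
    out[tuple(dst)] = data[tuple(src)]
    return out


def crop_subvolume(
    volume: CTVolume, labels: LabelMap | None, spec: CropSpec
) -> tuple[CTVolume, LabelMap | None, CropOffset]:
    """Crop (and pad) to exactly ``spec.target_shape`` about a centre voxel."""
    if labels is not None:
        check_same_geometry(volume, labels)
    shape = volume.shape
    centre = spec.centre or tuple(n // 2 for n in shape)
    start = tuple(int(c) - t // 2 for c, t in zip(centre, spec.target_shape))
    ct = CTVolume(
        _crop_array(volume.intensities, start, spec.target_shape, np.float32(AIR_HU)),
        volume.spacing,
    )
    lab = None
    if labels is not None:
        lab = LabelMap(
            _crop_array(labels.labels, start, spec.target_shape, labels.labels.dtype.type(0)),
            labels.spacing,
        )
    return ct, lab, CropOffset(start=start, original_shape=shape)


def uncrop_labels(labels: LabelMap, offset: CropOffset) -> LabelMap:
    """Place a cropped prediction back into the original geometry."""
    out = np.zeros(offset.original_shape, dtype=labels.labels.dtype)
    src = []
    dst = []
    for ax in range(3):
        s0 = max(offset.start[ax], 0)
        s1 = min(offset.start[ax] + labels.shape[ax], offset.original_shape[ax])
        if s1 <= s0:
            break
        dst.append(slice(s0, s1))
        src.append(slice(s0 - offset.start[ax], s1 - offset.start[ax]))
    else:
        out[tuple(dst)] = labels.labels[tuple(src)]
    return LabelMap(out, labels.spacing)
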
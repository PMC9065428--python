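"""Random 3D spatial augmentation of CT / label-map pairs.

Each training draw independently includes: lateral mirroring (p=0.5),
integer voxel shifts of up to ±4 voxels per axis (p=1; at 1x1x2.5 mm this
is ±4 mm in-plane and ±10 mm axially), rotations of up to ±10° about the
left-right and cranio-caudal axes — imitating cervical flexion/extension
and axial rotation — (p=0.75), and volumetric scaling between 90 % and
110 % (p=0.5).

The sampled elementary transforms are composed (mirror -> scale -> rotate ->
shift, in physical mm coordinates about the volume centre) into a single
affine resampling so the data is interpolated only once: tri-linear for
intensities, nearest-neighbour for labels.  Out-of-field voxels are filled
with air (-1024 HU) / background.  Lateral mirroring additionally swaps the
left/right label codes so organ laterality stays anatomically correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import AIR_HU, LR_LABEL_PAIRS, CTVolume, LabelMap, check_same_geometry


@dataclass(frozen=True)
class AugmentationPolicy:
    mirror_prob: float = 0.5
    shift_prob: float = 1.0
    shift_max: tuple[int, int, int] = (4, 4, 4)  # voxels per axis
    rotate_prob: float = 0.75
    rotate_max_deg: float = 10.0
    scale_prob: float = 0.5
    scale_range: tuple[float, float] = (0.90, 1.10)
    lr_label_pairs: tuple[tuple[int, int], ...] = LR_LABEL_PAIRS

    def __post_init__(self) -> None:
        for name in ("mirror_prob", "shift_prob", "rotate_prob", "scale_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi < 2.0):
            raise ValueError(f"scale_range must lie within (0, 2), got {self.scale_range}")
        if self.rotate_max_deg < 0:
            raise ValueError("rotate_max_deg must be >= 0")

    @staticmethod
    def identity() -> "AugmentationPolicy":
        """A policy that never augments (deterministic runs)."""
        return AugmentationPolicy(mirror_prob=0.0, shift_prob=0.0, rotate_prob=0.0, scale_prob=0.0)


@dataclass(frozen=True)
class TransformRecord:
    """The drawn elementary transforms; fully determines the resampling."""

    seed: int | None = None
    mirror: bool = False
    shift_voxels: tuple[int, int, int] | None = None
    rotate_deg: tuple[float, float] | None = None  # about (x = L-R, z = cranio-caudal)
    scale: float | None = None

    @property
    def is_identity(self) -> bool:
        return (
            not self.mirror
            and self.shift_voxels is None
            and self.rotate_deg is None
            and self.scale is None
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mirror": self.mirror,
            "shift_voxels": list(self.shift_voxels) if self.shift_voxels else None,
            "rotate_deg": list(self.rotate_deg) if self.rotate_deg else None,
            "scale": self.scale,
        }

    @staticmethod
    def from_dict(d: dict) -> "TransformRecord":
        return TransformRecord(
            seed=d.get("seed"),
            mirror=bool(d.get("mirror", False)),
            shift_voxels=tuple(d["shift_voxels"]) if d.get("shift_voxels") else None,
            rotate_deg=tuple(d["rotate_deg"]) if d.get("rotate_deg") else None,
            scale=d.get("scale"),
        )


def sample_transform(policy: AugmentationPolicy, rng_seed: int) -> TransformRecord:
    """Draw one random transform; the same seed yields the same record."""
    rng = np.random.default_rng(rng_seed)
    mirror = bool(rng.random() < policy.mirror_prob)
    shift = None
    if rng.random() < policy.shift_prob:
        shift = tuple(int(rng.integers(-m, m + 1)) for m in policy.shift_max)
    rotate = None
    if rng.random() < policy.rotate_prob:
        m = policy.rotate_max_deg
        rotate = (float(rng.uniform(-m, m)), float(rng.uniform(-m, m)))
    scale = None
    if rng.random() < policy.scale_prob:
        scale = float(rng.uniform(*policy.scale_range))
    return TransformRecord(
        seed=int(rng_seed), mirror=mirror, shift_voxels=shift, rotate_deg=rotate, scale=scale
    )


def _rotation_matrix(record: TransformRecord) -> np.ndarray:
    """Linear part of mirror -> scale -> rotate in physical coordinates."""
    m = np.eye(3)
    if record.mirror:
        m = np.diag([-1.0, 1.0, 1.0]) @ m
    if record.scale is not None:
        m = record.scale * m
    if record.rotate_deg is not None:
        ax, az = np.deg2rad(record.rotate_deg)
        ca, sa = np.cos(ax), np.sin(ax)
        rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        cz, sz = np.cos(az), np.sin(az)
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        m = rz @ rx @ m
    return m


def _swap_labels(labels: np.ndarray, pairs) -> np.ndarray:
    out = labels.copy()
    for a, b in pairs:
        ma = labels == a
        mb = labels == b
        out[ma] = b
        out[mb] = a
    return out


def apply_transform(
    volume: CTVolume,
    labels: LabelMap,
    record: TransformRecord,
    lr_label_pairs=LR_LABEL_PAIRS,
) -> tuple[CTVolume, LabelMap]:
    """Resample the pair through the recorded transform.

    The identity record returns bit-identical copies.  Intensities use
    tri-linear interpolation, labels nearest-neighbour; mirroring swaps the
    codes in ``lr_label_pairs``.
    """
    check_same_geometry(volume, labels)
    if record.is_identity:
        return (
            CTVolume(volume.intensities.copy(), volume.spacing),
            LabelMap(labels.labels.copy(), labels.spacing),
        )

    spacing = np.asarray(volume.spacing)
    shape = np.asarray(volume.shape)
    centre = (shape - 1) / 2.0

    rot = _rotation_matrix(record)
    shift_mm = np.zeros(3)
    if record.shift_voxels is not None:
        shift_mm = np.asarray(record.shift_voxels, dtype=float) * spacing

    # forward: q = rot @ p + shift (physical mm, about the centre)
    # resampling needs output-voxel -> input-voxel: v_in = A @ v_out + offset
    rot_inv = np.linalg.inv(rot)
    s = np.diag(spacing)
    s_inv = np.diag(1.0 / spacing)
    a = s_inv @ rot_inv @ s
    offset = centre - a @ centre - s_inv @ rot_inv @ shift_mm

    ct_out = ndimage.affine_transform(
        volume.intensities.astype(np.float32), a, offset=offset, order=1,
        mode="constant", cval=AIR_HU,
    )
    lab_out = ndimage.affine_transform(
        labels.labels, a, offset=offset, order=0, mode="constant", cval=0,
    )
    if record.mirror:
        lab_out = _swap_labels(lab_out, lr_label_pairs)
    return CTVolume(ct_out, volume.spacing), LabelMap(lab_out, labels.spacing)


def augment_pair(
    volume: CTVolume, labels: LabelMap, policy: AugmentationPolicy, rng_seed: int
) -> tuple[CTVolume, LabelMap, TransformRecord]:
    """Sample and apply one random augmentation; returns the record too."""
    record = sample_transform(policy, rng_seed)
    ct, lab = apply_transform(volume, labels, record, policy.lr_label_pairs)
    return ct, lab, record
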
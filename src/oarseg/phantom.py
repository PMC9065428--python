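"""Synthetic HU-calibrated head-and-neck CT phantoms.

Each phantom is an air background containing a soft-tissue head/neck
ellipsoid with five organ-at-risk solids painted into it: an axial
brainstem tube and a thinner, more caudal spinal-cord tube on the
mid-sagittal plane, a bone-density mandibular arch (anterior half of a
torus) and a mirror-symmetric pair of lateral parotid ellipsoids.  The CT
is the per-tissue HU mean plus Gaussian noise and mild smoothing; the gold
label map uses the fixed repo-wide coding (0 background, 1 brainstem,
2 mandible, 3/4 left/right parotid, 5 spinal cord).

A simulated second observer is derived from the gold standard by warping
each organ with an independent smooth random displacement field whose
maximum magnitude is bounded in mm — emulating bounded inter-observer
delineation deviation.

Organ geometry is expressed in fractions of the volume shape so the same
spec scales from small test grids (default 64x64x16 at 1x1x2.5 mm) up to
full 200x200x56 crops.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import AIR_HU, ORGAN_LABELS, CTVolume, LabelMap


class PhantomSpecError(ValueError):
    """Phantom geometry inconsistent with the requested volume."""


#: Per-organ geometry in shape fractions and HU.  Ellipsoids are
#: (centre_frac, semi_axis_frac); the mandible is a torus arch.
_DEFAULT_ORGANS = {
    "brainstem": {
        "centre": (0.5, 0.57, 0.70),
        "semi": (0.065, 0.065, 0.22),
        "hu": 35.0,
    },
    "spinal_cord": {
        "centre": (0.5, 0.57, 0.24),
        "semi": (0.042, 0.042, 0.185),
        "hu": 45.0,
    },
    "parotid_left": {
        "centre": (0.72, 0.41, 0.50),
        "semi": (0.075, 0.095, 0.20),
        "hu": 25.0,
    },
    "parotid_right": {
        "centre": (0.28, 0.41, 0.50),
        "semi": (0.075, 0.095, 0.20),
        "hu": 25.0,
    },
    "mandible": {  # anterior half-torus
        "centre": (0.5, 0.30, 0.20),
        "ring_radius": 0.19,
        "tube_radius": 0.042,
        "hu": 700.0,
    },
}


#: Vertebral canal surrounding the spinal cord: a CSF-density interior inside
#: a bone-density tube, concentric with the cord.  Radii are fractions of the
#: in-plane extent; the z half-extent is a fraction of the axial extent.
_DEFAULT_CANAL = {
    "csf_radius": 0.068,
    "bone_radius": 0.10,
    "z_semi": 0.28,
    "csf_hu": 12.0,
    "bone_hu": 500.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    tissue_hu: float = 40.0
    noise_sd_hu: float = 12.0
    smoothing_voxels: float = 0.6
    #: background anatomy around the cord (None disables it)
    vertebral_canal: dict | None = field(default_factory=lambda: dict(_DEFAULT_CANAL))
    #: max random centre jitter per axis, voxels (0 => exactly symmetric)
    jitter_voxels: tuple[float, float, float] = (2.0, 2.0, 0.5)
    observer_magnitude_mm: float = 2.0
    seed: int = 0
    organs: dict = field(default_factory=lambda: _DEFAULT_ORGANS)

    def symmetric(self) -> "PhantomSpec":
        """The same spec with jitter disabled (exact lateral symmetry)."""
        return replace(self, jitter_voxels=(0.0, 0.0, 0.0))


@dataclass
class PhantomCase:
    ct: CTVolume
    gold: LabelMap
    observer2: LabelMap
    spec: PhantomSpec


def _grids(shape):
    return np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")


def _ellipsoid(grids, centre, semi):
    x, y, z = grids
    cx, cy, cz = centre
    rx, ry, rz = semi
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _mandible_arch(grids, shape, spacing, centre, ring_frac, tube_frac):
    x, y, z = grids
    cx, cy, cz = centre
    in_plane = min(shape[0], shape[1])
    ring = ring_frac * in_plane
    tube = tube_frac * in_plane
    radial = np.sqrt((x - cx) ** 2 + (y - cy) ** 2) - ring
    dz = (z - cz) * (spacing[2] / spacing[0])  # physical-round tube
    mask = radial**2 + dz**2 <= tube**2
    return mask & (y <= cy)  # anterior half only


def _organ_masks(spec: PhantomSpec, rng: np.random.Generator):
    shape = np.asarray(spec.shape, dtype=float)
    grids = _grids(spec.shape)
    jitter = np.asarray(spec.jitter_voxels, dtype=float)
    # parotids share one lateral jitter so the pair stays mirror-symmetric
    pair_jitter = rng.uniform(-1, 1, size=3) * jitter
    masks: dict[str, np.ndarray] = {}
    centres: dict[str, np.ndarray] = {}
    for name, geo in spec.organs.items():
        centre = np.asarray(geo["centre"]) * (shape - 1)
        if name == "parotid_left":
            centre = centre + pair_jitter
        elif name == "parotid_right":
            centre = centre + pair_jitter * np.array([-1.0, 1.0, 1.0])
        else:
            centre = centre + rng.uniform(-1, 1, size=3) * jitter
        if "ring_radius" in geo:
            mask = _mandible_arch(
                grids, spec.shape, spec.spacing, centre,
                geo["ring_radius"], geo["tube_radius"],
            )
        else:
            semi = np.asarray(geo["semi"]) * shape
            mask = _ellipsoid(grids, centre, semi)
        if not mask.any():
            raise PhantomSpecError(f"organ {name!r} is empty at shape {spec.shape}")
        border = np.zeros(spec.shape, dtype=bool)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        if (mask & border).any():
            raise PhantomSpecError(f"organ {name!r} touches the volume border")
        masks[name] = mask
        centres[name] = centre
    return masks, centres


def analytic_organ_volumes(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form ellipsoid volumes (voxel units) for the ellipsoidal organs."""
    shape = np.asarray(spec.shape, dtype=float)
    out = {}
    for name, geo in spec.organs.items():
        if "semi" in geo:
            semi = np.asarray(geo["semi"]) * shape
            out[name] = 4.0 / 3.0 * np.pi * float(np.prod(semi))
    return out


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomCase:
    """Deterministically generate one phantom case from a spec."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)

    masks, centres = _organ_masks(spec, rng)
    labels = np.zeros(spec.shape, dtype=np.int16)
    ct = np.full(spec.shape, AIR_HU, dtype=np.float64)

    # head/neck soft-tissue ellipsoid filling most of the volume
    shape = np.asarray(spec.shape, dtype=float)
    grids = _grids(spec.shape)
    body = _ellipsoid(
        grids,
        (shape - 1) / 2.0,
        shape * np.array([0.46, 0.46, 0.60]),
    )
    ct[body] = spec.tissue_hu

    if spec.vertebral_canal is not None and "spinal_cord" in centres:
        canal = spec.vertebral_canal
        cx, cy, _ = centres["spinal_cord"]
        cz = spec.organs["spinal_cord"]["centre"][2] * (shape[2] - 1)
        in_plane = min(spec.shape[0], spec.shape[1])
        x, y, z = grids
        radial = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        in_z = np.abs(z - cz) <= canal["z_semi"] * shape[2]
        ct[(radial <= canal["bone_radius"] * in_plane) & in_z] = canal["bone_hu"]
        ct[(radial <= canal["csf_radius"] * in_plane) & in_z] = canal["csf_hu"]

    for name, mask in masks.items():
        labels[mask] = ORGAN_LABELS[name]
        ct[mask] = spec.organs[name]["hu"]

    ct += rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)
    if spec.smoothing_voxels > 0:
        ct = ndimage.gaussian_filter(ct, spec.smoothing_voxels)
    ct = np.maximum(ct, AIR_HU)

    gold = LabelMap(labels, spec.spacing)
    observer2 = perturb_observer(
        gold, spec.observer_magnitude_mm, spec.spacing,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return PhantomCase(
        ct=CTVolume(ct.astype(np.float32), spec.spacing),
        gold=gold,
        observer2=observer2,
        spec=spec,
    )


def perturb_observer(gold: LabelMap, magnitude_mm: float, spacing=None, seed: int = 0) -> LabelMap:
    """Simulate a second observer by smoothly displacing each organ boundary.

    Every organ is warped with its own smooth random displacement field
    whose maximum magnitude equals ``magnitude_mm``; organ label codes in
    the output are a subset of the input's.  ``magnitude_mm = 0`` returns an
    identical map.
    """
    if magnitude_mm < 0:
        raise ValueError("perturbation magnitude must be >= 0")
    spacing = np.asarray(spacing if spacing is not None else gold.spacing, dtype=float)
    if magnitude_mm == 0:
        return LabelMap(gold.labels.copy(), gold.spacing)

    rng = np.random.default_rng(seed)
    shape = gold.shape
    coords = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    out = np.zeros(shape, dtype=gold.labels.dtype)

    for label in np.unique(gold.labels):
        if label == 0:
            continue
        organ = gold.labels == label
        region = ndimage.binary_dilation(organ, iterations=3)
        field_mm = rng.normal(0.0, 1.0, size=(3,) + shape)
        for ax in range(3):
            field_mm[ax] = ndimage.gaussian_filter(field_mm[ax], sigma=4.0)
        # bound the displacement by its maximum over the organ neighbourhood
        mag = np.sqrt((field_mm**2).sum(axis=0))[region].max()
        if mag > 0:
            field_mm *= magnitude_mm / mag
        # pull-back sampling: source voxel = target - displacement(voxels)
        sample = [c - field_mm[ax] / spacing[ax] for ax, c in enumerate(coords)]
        warped = ndimage.map_coordinates(
            (gold.labels == label).astype(np.uint8), sample, order=0, mode="constant", cval=0
        )
        out[warped > 0] = label
    return LabelMap(out, gold.spacing)


def phantom_dataset(n: int, base_seed: int = 0, spec: PhantomSpec | None = None) -> list[PhantomCase]:
    """Generate ``n`` independent phantoms with seeds derived from a base seed."""
    spec = spec or PhantomSpec()
    seeds = np.random.SeedSequence(base_seed).generate_state(n) % (2**31 - 1)
    return [generate_phantom(replace(spec, seed=int(s))) for s in seeds]
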
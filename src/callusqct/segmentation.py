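"""Density-threshold segmentation of calibrated micro-CT volumes.

The workflow mirrors the standard clinical micro-CT evaluation of a
healing osteotomy: Gaussian denoising, dual density thresholding — bone
above 1000 mgHA/ccm, callus in the 250–1000 mgHA/ccm band — followed by
morphological refinement of the masks (opening, closing, small-component
removal) and an optional slice-by-slice reassignment of highly
mineralized ("mature") callus that plain thresholding cannot distinguish
from native cortex.

Ties at the 1000 mgHA/ccm boundary go to callus; bone is the open
interval above it.  Density statistics downstream are computed on the
raw (unfiltered) volume within the masks; filtering only stabilizes the
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, convex_hull_image, remove_small_objects

from .volume import AXIAL_AXIS, CalibratedVolume

DEFAULT_CALLUS_LOW = 250.0  # mgHA/ccm
DEFAULT_BONE_HIGH = 1000.0  # mgHA/ccm
DEFAULT_METAL_THRESHOLD = 2000.0  # mgHA/ccm


@dataclass
class SegmentationMasks:
    """Mutually exclusive voxel label sets for one volume."""

    bone: np.ndarray
    callus: np.ndarray
    background: np.ndarray
    metal: np.ndarray | None = None
    thresholds: tuple[float, float] = (DEFAULT_CALLUS_LOW, DEFAULT_BONE_HIGH)
    voxel_pitch: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {self.bone.shape, self.callus.shape, self.background.shape}
        if self.metal is not None:
            shapes.add(self.metal.shape)
        if len(shapes) != 1:
            raise ValueError("mask shapes differ")
        self.validate_partition()

    def validate_partition(self) -> None:
        """Raise if the labels are not pairwise disjoint and exhaustive."""
        total = (
            self.bone.astype(np.uint8)
            + self.callus.astype(np.uint8)
            + self.background.astype(np.uint8)
        )
        if self.metal is not None:
            total += self.metal.astype(np.uint8)
        if not np.all(total == 1):
            raise ValueError("masks are not a partition of the volume")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.bone.shape


def denoise(volume: CalibratedVolume, sigma: float = 0.5, support: float = 2.0) -> CalibratedVolume:
    """Gaussian filter in voxel units; ``sigma=0`` returns the input unchanged.

    ``support`` is the truncation radius of the kernel in voxels.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume
    smoothed = ndimage.gaussian_filter(volume.values, sigma=sigma, truncate=support / sigma)
    return CalibratedVolume(smoothed, volume.voxel_pitch, volume.axis_convention)


def segment(
    volume: CalibratedVolume,
    callus_low: float = DEFAULT_CALLUS_LOW,
    bone_high: float = DEFAULT_BONE_HIGH,
    metal_threshold: float | None = None,
) -> SegmentationMasks:
    """Dual density thresholding into bone, callus and background.

    Bone is strictly above ``bone_high``; callus is the closed band
    ``[callus_low, bone_high]``; everything below is background.  With
    ``metal_threshold`` set, voxels at or above it are split off into a
    metal mask (screws), excluded from bone.
    """
    if not callus_low < bone_high:
        raise ValueError(f"callus_low ({callus_low}) must be < bone_high ({bone_high})")
    v = volume.values
    bone = v > bone_high
    callus = (v >= callus_low) & (v <= bone_high)
    metal = None
    if metal_threshold is not None:
        if metal_threshold <= bone_high:
            raise ValueError("metal_threshold must exceed bone_high")
        metal = v >= metal_threshold
        bone = bone & ~metal
    background = ~(bone | callus)
    if metal is not None:
        background &= ~metal
    return SegmentationMasks(
        bone=bone,
        callus=callus,
        background=background,
        metal=metal,
        thresholds=(callus_low, bone_high),
        voxel_pitch=volume.voxel_pitch,
    )


def refine_masks(
    masks: SegmentationMasks,
    opening_radius: int = 1,
    closing_radius: int = 1,
    min_component: int = 27,
) -> SegmentationMasks:
    """Morphological refinement: per-label opening then closing with ball
    structuring elements, then removal of connected components smaller
    than ``min_component`` voxels.  Radii 0 and ``min_component`` 1 leave
    the masks unchanged.  Disjointness is restored by precedence
    bone > callus; background absorbs whatever neither claims.
    """
    if opening_radius < 0 or closing_radius < 0:
        raise ValueError("radii must be >= 0")

    def _refine(mask: np.ndarray) -> np.ndarray:
        out = mask
        if opening_radius > 0:
            se = ball(opening_radius)
            out = ndimage.binary_opening(out, structure=se)
        if closing_radius > 0:
            se = ball(closing_radius)
            out = ndimage.binary_closing(out, structure=se)
        if min_component > 1:
            # keep components of >= min_component voxels
            out = remove_small_objects(out, max_size=min_component - 1)
        return out

    bone = _refine(masks.bone)
    callus = _refine(masks.callus)
    callus &= ~bone  # precedence bone > callus
    metal = masks.metal
    if metal is not None:
        bone &= ~metal
        callus &= ~metal
    background = ~(bone | callus)
    if metal is not None:
        background &= ~metal
    return SegmentationMasks(
        bone=bone,
        callus=callus,
        background=background,
        metal=metal,
        thresholds=masks.thresholds,
        voxel_pitch=masks.voxel_pitch,
    )


# ---------------------------------------------------------------------------
# mature-callus reassignment
# ---------------------------------------------------------------------------


@dataclass
class NativeEnvelope:
    """Per-slice model of the expected native (periosteal) cortical boundary.

    ``masks_by_slice[k]`` is the 2-D boolean region a native cortex is
    expected to occupy in slice ``k``; bone found outside it is callus
    that has mineralized past the bone threshold.
    """

    masks_by_slice: dict[int, np.ndarray]

    def covers(self, slices: np.ndarray) -> bool:
        return all(int(k) in self.masks_by_slice for k in slices)


def build_native_envelope(
    masks: SegmentationMasks,
    gap_bounds: tuple[float, float],
    exclusion_margin: float = 5.0,
) -> NativeEnvelope:
    """Construct the native cortical envelope slice by slice.

    In slices at least ``exclusion_margin`` mm away from the gap the
    envelope is the convex periosteal contour (convex hull) of the bone
    label.  Across the excluded region around the gap, the envelope is
    interpolated linearly between the two nearest reliable slices using
    signed Euclidean distance fields, so the periosteal boundary morphs
    smoothly across the osteotomy.
    """
    pitch_ax = masks.voxel_pitch[AXIAL_AXIS]
    n_slices = masks.shape[AXIAL_AXIS]
    z = (np.arange(n_slices) + 0.5) * pitch_ax
    far = (z <= gap_bounds[0] - exclusion_margin) | (z >= gap_bounds[1] + exclusion_margin)

    hulls: dict[int, np.ndarray] = {}
    for k in range(n_slices):
        if not far[k]:
            continue
        sl = masks.bone[:, :, k]
        if sl.any():
            hulls[k] = convex_hull_image(sl)

    if not hulls:
        raise ValueError("no reliable bone-bearing slice outside the gap region")

    def _sdf(mask: np.ndarray) -> np.ndarray:
        inside = ndimage.distance_transform_edt(mask)
        outside = ndimage.distance_transform_edt(~mask)
        return inside - outside

    keys = sorted(hulls)
    env: dict[int, np.ndarray] = dict(hulls)
    sdf_cache: dict[int, np.ndarray] = {}
    for k in range(n_slices):
        if k in env:
            continue
        lower = [j for j in keys if j < k]
        upper = [j for j in keys if j > k]
        if lower and upper:
            a, b = lower[-1], upper[0]
            for j in (a, b):
                if j not in sdf_cache:
                    sdf_cache[j] = _sdf(hulls[j])
            t = (k - a) / (b - a)
            env[k] = ((1.0 - t) * sdf_cache[a] + t * sdf_cache[b]) >= 0
        elif lower:
            env[k] = hulls[lower[-1]]
        else:
            env[k] = hulls[upper[0]]
    return NativeEnvelope(env)


def reassign_mature_callus(
    masks: SegmentationMasks, native_envelope: NativeEnvelope
) -> tuple[SegmentationMasks, np.ndarray]:
    """Relabel bone found outside the native cortical envelope as callus.

    Plain density thresholding classifies highly mineralized (mature)
    callus as bone; slice by slice, bone-labelled voxels lying outside
    the expected periosteal boundary are reassigned to the callus label.
    Returns the updated masks and the per-slice counts of relabelled
    voxels.  Total bone + callus volume is conserved exactly.
    """
    n_slices = masks.shape[AXIAL_AXIS]
    bone_bearing = np.flatnonzero(masks.bone.any(axis=(0, 1)))
    if not native_envelope.covers(bone_bearing):
        missing = [int(k) for k in bone_bearing if int(k) not in native_envelope.masks_by_slice]
        raise ValueError(f"native envelope missing for bone-bearing slices {missing[:5]}...")

    bone = masks.bone.copy()
    callus = masks.callus.copy()
    counts = np.zeros(n_slices, dtype=np.int64)
    for k in bone_bearing:
        k = int(k)
        outside = bone[:, :, k] & ~native_envelope.masks_by_slice[k]
        n = int(outside.sum())
        if n:
            bone[:, :, k] &= ~outside
            callus[:, :, k] |= outside
            counts[k] = n
    out = SegmentationMasks(
        bone=bone,
        callus=callus,
        background=masks.background.copy(),
        metal=masks.metal,
        thresholds=masks.thresholds,
        voxel_pitch=masks.voxel_pitch,
    )
    return out, counts
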
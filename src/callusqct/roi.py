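"""Analysis regions and the cis/trans partition.

Two regions of interest are used when quantifying a plated osteotomy:
the *whole bone* (the sample volume under the plate, i.e. the plate's
axial span) and the *gap* (the volume between the proximal and distal
screws adjacent to the osteotomy gap).  Within either region, callus is
split into a *cis* (plate-side) and a *trans* (far-side) compartment by
a half-space through the per-slice bone centroid.

Axial intervals are half-open ``[start, end)`` in mm along the bone
axis; a slice belongs to an interval if its centre does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import SegmentationMasks
from .volume import AXIAL_AXIS, CalibratedVolume


@dataclass
class ROISpec:
    """An axial analysis region.

    ``kind`` is ``"whole_bone"`` or ``"gap"``; ``axial_bounds`` is the
    half-open interval in mm along the bone axis; ``cis_halfspace`` is
    the in-plane unit normal of the cis (plate-side) half-space.
    """

    kind: str
    axial_bounds: tuple[float, float]
    cis_halfspace: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("whole_bone", "gap"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        lo, hi = self.axial_bounds
        if not lo < hi:
            raise ValueError(f"empty axial_bounds {self.axial_bounds}")
        if self.cis_halfspace is not None:
            n = np.asarray(self.cis_halfspace, dtype=np.float64)
            norm = np.linalg.norm(n)
            if norm == 0:
                raise ValueError("degenerate cis normal")
            self.cis_halfspace = n / norm

    def slice_selector(self, pitch_axial: float, n_slices: int) -> np.ndarray:
        """Boolean per-slice mask: slice centre in [start, end)."""
        z = (np.arange(n_slices) + 0.5) * pitch_axial
        return (z >= self.axial_bounds[0]) & (z < self.axial_bounds[1])


@dataclass
class BoneAxis:
    """Principal direction of the bone and its per-slice centroid track."""

    point: np.ndarray  # mm, a point on the axis (bone centroid)
    direction: np.ndarray  # unit vector, oriented proximal->distal (+axial)
    centroid_track: list[tuple[int, np.ndarray]]  # (slice index, in-plane centroid mm)

    def centroids_interpolated(self, n_slices: int) -> np.ndarray:
        """(n_slices, 2) in-plane centroids, linearly interpolated (and
        edge-extended) over slices without bone."""
        idx = np.array([k for k, _ in self.centroid_track])
        cts = np.array([c for _, c in self.centroid_track])
        allk = np.arange(n_slices)
        out = np.empty((n_slices, 2))
        for d in range(2):
            out[:, d] = np.interp(allk, idx, cts[:, d])
        return out


def estimate_bone_axis(masks: SegmentationMasks) -> BoneAxis:
    """Principal direction of the bone voxel cloud plus per-slice centroids.

    The direction is the leading principal component of the bone voxel
    coordinates (mm), oriented so its axial component is positive
    (proximal at low axial coordinate by convention).
    """
    if not masks.bone.any():
        raise ValueError("bone mask is empty")
    pitch = np.asarray(masks.voxel_pitch)
    coords = np.argwhere(masks.bone) * pitch  # (N, 3) mm
    centre = coords.mean(axis=0)
    centred = coords - centre
    # principal direction via SVD of the (3, 3) scatter matrix
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    direction = v[:, np.argmax(w)]
    if direction[AXIAL_AXIS] < 0:
        direction = -direction

    track = []
    bone_slices = np.flatnonzero(masks.bone.any(axis=(0, 1)))
    for k in bone_slices:
        ij = np.argwhere(masks.bone[:, :, k]) * pitch[:2]
        track.append((int(k), ij.mean(axis=0)))
    return BoneAxis(point=centre, direction=direction, centroid_track=track)


def define_gap_roi(
    screw_axial_positions: list[float],
    gap_bounds: tuple[float, float],
    cis_normal: np.ndarray | None = None,
) -> ROISpec:
    """Gap ROI: between the innermost proximal and distal screws.

    The two screws adjacent to the osteotomy gap bound the region; the
    resulting interval must contain the gap itself.
    """
    lo, hi = gap_bounds
    prox = [z for z in screw_axial_positions if z < lo]
    dist = [z for z in screw_axial_positions if z > hi]
    if not prox or not dist:
        raise ValueError("screw positions must straddle the gap on both sides")
    bounds = (max(prox), min(dist))
    if not (bounds[0] <= lo and bounds[1] >= hi):
        raise ValueError(f"gap ROI {bounds} does not contain the gap {gap_bounds}")
    return ROISpec(kind="gap", axial_bounds=bounds, cis_halfspace=cis_normal)


def define_whole_bone_roi(
    volume: CalibratedVolume,
    plate_extent: tuple[float, float],
    cis_normal: np.ndarray | None = None,
) -> ROISpec:
    """Whole-bone ROI: the sample volume under the plate (its axial span)."""
    lo, hi = plate_extent
    if lo < 0 or hi > volume.scan_length_mm:
        raise ValueError(
            f"plate extent {plate_extent} outside the scanned extent "
            f"[0, {volume.scan_length_mm:.2f}] mm"
        )
    return ROISpec(kind="whole_bone", axial_bounds=(lo, hi), cis_halfspace=cis_normal)


def apply_roi(mask: np.ndarray, roi: ROISpec, pitch_axial: float) -> np.ndarray:
    """Restrict a voxel mask to the ROI's axial slab."""
    sel = roi.slice_selector(pitch_axial, mask.shape[AXIAL_AXIS])
    out = np.zeros_like(mask)
    out[:, :, sel] = mask[:, :, sel]
    return out


def split_cis_trans(
    mask: np.ndarray,
    axis: BoneAxis,
    cis_normal: np.ndarray,
    voxel_pitch: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a mask into cis and trans half-spaces.

    The cut plane passes, in every slice, through that slice's bone
    centroid with in-plane normal ``cis_normal`` (pointing toward the
    plate); voxels with positive signed distance go to cis, the rest to
    trans.  The two outputs tile the input mask exactly.
    """
    n = np.asarray(cis_normal, dtype=np.float64)
    if np.linalg.norm(n) == 0:
        raise ValueError("degenerate cis normal")
    n = n / np.linalg.norm(n)
    if len(n) == 3:
        cosang = abs(float(np.dot(n, axis.direction)))
        if cosang > np.sin(np.deg2rad(5.0)):
            # normal must be in-plane: perpendicular to the bone axis within 5 deg
            raise ValueError("cis normal not perpendicular to the bone axis (within 5 deg)")
        n2 = n[:2]
    else:
        n2 = n
    if np.linalg.norm(n2) == 0:
        raise ValueError("cis normal has no in-plane component")
    n2 = n2 / np.linalg.norm(n2)

    n_slices = mask.shape[AXIAL_AXIS]
    cents = axis.centroids_interpolated(n_slices)  # (n_slices, 2) mm
    pitch = np.asarray(voxel_pitch)
    # same voxel-index frame as the centroid track (index * pitch)
    i = np.arange(mask.shape[0]) * pitch[0]
    j = np.arange(mask.shape[1]) * pitch[1]
    # signed distance of each in-plane position to each slice's plane
    s = (
        (i[:, None, None] - cents[None, None, :, 0]) * n2[0]
        + (j[None, :, None] - cents[None, None, :, 1]) * n2[1]
    )
    cis = mask & (s > 0)
    trans = mask & ~(s > 0)
    return cis, trans
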
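"""Morphometric outcome variables of a segmented micro-CT sample.

Per region of interest: bone and callus volume (ccm), mean mineral
density (mgHA/ccm, measured on the raw volume within the mask),
plate-side (cis) versus far-side (trans) callus volume, and the profile
of the cross-sectional polar moment of inertia (pMOI, mm^4) along the
bone axis.  Internally all lengths are mm (areas mm^2, pMOI mm^4);
volumes are reported in ccm (cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import BoneAxis, ROISpec, apply_roi, split_cis_trans
from .segmentation import SegmentationMasks
from .volume import AXIAL_AXIS, CalibratedVolume

MM3_PER_CCM = 1000.0


@dataclass
class MorphometryResult:
    """Outcome variables for one sample in one ROI.

    Densities are ``None`` when the corresponding mask is empty inside
    the ROI (an empty compartment has no density, not density zero).
    ``pmoi_profile`` rows are ``(axial position as % of scan length,
    pMOI in mm^4)``.
    """

    roi: ROISpec
    callus_volume: float  # ccm
    callus_density: float | None  # mgHA/ccm
    bone_volume: float  # ccm
    bone_density: float | None  # mgHA/ccm
    cis_callus_volume: float  # ccm
    trans_callus_volume: float  # ccm
    pmoi_profile: np.ndarray  # (n, 2): position %, pMOI mm^4

    def to_dict(self) -> dict:
        return {
            "roi": self.roi.kind,
            "callus_volume_ccm": self.callus_volume,
            "callus_density_mgHAccm": self.callus_density,
            "bone_volume_ccm": self.bone_volume,
            "bone_density_mgHAccm": self.bone_density,
            "cis_callus_volume_ccm": self.cis_callus_volume,
            "trans_callus_volume_ccm": self.trans_callus_volume,
        }


def compute_volume(mask: np.ndarray, pitch: tuple[float, float, float]) -> float:
    """Voxel count times voxel volume, in ccm."""
    pitch = tuple(float(p) for p in pitch)
    if any(p <= 0 for p in pitch):
        raise ValueError("voxel pitch must be > 0")
    return float(np.count_nonzero(mask)) * float(np.prod(pitch)) / MM3_PER_CCM


def compute_density(volume: CalibratedVolume, mask: np.ndarray) -> float:
    """Arithmetic mean of raw voxel densities over the mask, mgHA/ccm."""
    if not mask.any():
        raise ValueError("cannot compute the density of an empty mask")
    return float(volume.values[mask].mean())


def pmoi_profile(
    masks: SegmentationMasks,
    axis: BoneAxis,
    include: tuple[str, ...] = ("bone", "callus"),
) -> np.ndarray:
    """Per-slice polar moment of inertia of the included labels.

    For each cross-section k, ``J_k = sum_v ((x_v - xbar)^2 +
    (y_v - ybar)^2) * a`` over the included voxels, with ``(xbar, ybar)``
    that slice's centroid of included voxels and ``a`` the in-plane voxel
    area.  Slices with no included voxel record ``J = 0``.  Positions are
    reported as % of the scan length.

    Returns an ``(n_slices, 2)`` array of (position %, pMOI mm^4).
    """
    sel = np.zeros(masks.shape, dtype=bool)
    for name in include:
        m = getattr(masks, name)
        if m is None:
            raise ValueError(f"label {name!r} not present in masks")
        sel |= m
    pitch = masks.voxel_pitch
    area = pitch[0] * pitch[1]
    n_slices = masks.shape[AXIAL_AXIS]
    # in-plane voxel coordinates in mm (index frame, translation-invariant)
    i = np.arange(masks.shape[0], dtype=np.float64) * pitch[0]
    j = np.arange(masks.shape[1], dtype=np.float64) * pitch[1]

    counts = sel.sum(axis=(0, 1)).astype(np.float64)  # per slice
    sum_i = np.einsum("ijk,i->k", sel, i)
    sum_j = np.einsum("ijk,j->k", sel, j)
    sum_i2 = np.einsum("ijk,i->k", sel, i**2)
    sum_j2 = np.einsum("ijk,j->k", sel, j**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        # sum((x-xbar)^2) = sum(x^2) - (sum x)^2 / n, same for y
        j_poly = sum_i2 - sum_i**2 / counts + sum_j2 - sum_j**2 / counts
    j_poly = np.where(counts > 0, j_poly, 0.0) * area

    positions = (np.arange(n_slices) + 0.5) / n_slices * 100.0
    return np.column_stack([positions, j_poly])


def summarize_sample(
    volume: CalibratedVolume,
    masks: SegmentationMasks,
    axis: BoneAxis,
    rois: list[ROISpec],
    cis_normal: np.ndarray | None = None,
    pmoi_include: tuple[str, ...] = ("bone", "callus"),
) -> list[MorphometryResult]:
    """All outcome variables, one :class:`MorphometryResult` per ROI."""
    if volume.shape != masks.shape:
        raise ValueError("volume and masks are on different grids")
    pitch_ax = volume.voxel_pitch[AXIAL_AXIS]
    full_profile = pmoi_profile(masks, axis, include=pmoi_include)

    out = []
    for roi in rois:
        normal = roi.cis_halfspace if roi.cis_halfspace is not None else cis_normal
        if normal is None:
            normal = np.array([1.0, 0.0])
        bone_m = apply_roi(masks.bone, roi, pitch_ax)
        callus_m = apply_roi(masks.callus, roi, pitch_ax)
        cis_m, trans_m = split_cis_trans(callus_m, axis, normal, volume.voxel_pitch)
        sel = roi.slice_selector(pitch_ax, volume.shape[AXIAL_AXIS])
        profile = full_profile[sel]
        out.append(
            MorphometryResult(
                roi=roi,
                callus_volume=compute_volume(callus_m, volume.voxel_pitch),
                callus_density=(
                    compute_density(volume, callus_m) if callus_m.any() else None
                ),
                bone_volume=compute_volume(bone_m, volume.voxel_pitch),
                bone_density=(compute_density(volume, bone_m) if bone_m.any() else None),
                cis_callus_volume=compute_volume(cis_m, volume.voxel_pitch),
                trans_callus_volume=compute_volume(trans_m, volume.voxel_pitch),
                pmoi_profile=profile,
            )
        )
    return out


def results_to_frame(results: dict[str, list[MorphometryResult]]) -> pd.DataFrame:
    """Tidy CSV-ready table: one row per sample x ROI."""
    rows = []
    for sample, res_list in results.items():
        for r in res_list:
            row = {"sample": sample}
            row.update(r.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
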
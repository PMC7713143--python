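"""Calibrated micro-CT volume container and file I/O.

Voxel values are mineral densities in mgHA/ccm (milligrams of
hydroxyapatite per cubic centimetre), the calibrated unit of clinical
micro-CT reconstructions.  The bone long axis is, by package convention,
the *third* image axis: ``values[i, j, k]`` indexes two in-plane axes
(``i`` pointing toward the plate / cis side by default) and the axial
slice ``k``.  Cross-sections are therefore the planes ``values[:, :, k]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

AXIAL_AXIS = 2  # bone long axis = third image axis


@dataclass
class CalibratedVolume:
    """A 3-D mineral-density field with its voxel pitch.

    Parameters
    ----------
    values
        3-D array of densities, mgHA/ccm.
    voxel_pitch
        Per-axis voxel pitch in mm, ``(pitch_i, pitch_j, pitch_k)``.
    axis_convention
        Tag recording which axis is the bone long axis; only
        ``"long-axis-last"`` is produced or consumed by this package.
    """

    values: np.ndarray
    voxel_pitch: tuple[float, float, float]
    axis_convention: str = "long-axis-last"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.values.ndim}")
        self.voxel_pitch = tuple(float(p) for p in self.voxel_pitch)  # type: ignore[assignment]
        if len(self.voxel_pitch) != 3 or any(p <= 0 for p in self.voxel_pitch):
            raise ValueError(f"all three voxel pitches must be > 0, got {self.voxel_pitch}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite densities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_pitch))

    @property
    def scan_length_mm(self) -> float:
        """Axial extent of the scan in mm."""
        return self.shape[AXIAL_AXIS] * self.voxel_pitch[AXIAL_AXIS]

    def slice_positions_mm(self) -> np.ndarray:
        """Axial positions (mm) of the slice centres."""
        p = self.voxel_pitch[AXIAL_AXIS]
        return (np.arange(self.shape[AXIAL_AXIS]) + 0.5) * p


def save_nifti(volume: CalibratedVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with the voxel pitch in the affine."""
    affine = np.diag(list(volume.voxel_pitch) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(volume.voxel_pitch)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> CalibratedVolume:
    img = nib.load(str(path))
    pitch = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CalibratedVolume(np.asanyarray(img.dataobj, dtype=np.float64), pitch)


def save_tiff_stack(volume: CalibratedVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (pages = axial slices) plus a
    JSON sidecar carrying the voxel pitch."""
    path = Path(path)
    # pages along the bone axis: move axial axis first
    stack = np.moveaxis(volume.values.astype(np.float32), AXIAL_AXIS, 0)
    tifffile.imwrite(str(path), stack)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "voxel_pitch_mm": list(volume.voxel_pitch),
                "axis_convention": volume.axis_convention,
                "units": "mgHA/ccm",
            }
        )
    )


def load_tiff_stack(path: str | Path) -> CalibratedVolume:
    path = Path(path)
    stack = tifffile.imread(str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    values = np.moveaxis(np.asarray(stack, dtype=np.float64), 0, AXIAL_AXIS)
    return CalibratedVolume(values, tuple(meta["voxel_pitch_mm"]))


def save_labels(labels: np.ndarray, pitch: tuple[float, float, float], path: str | Path) -> None:
    """Write a label volume as an unsigned 8-bit NIfTI."""
    if labels.max() > 255 or labels.min() < 0:
        raise ValueError("labels do not fit in uint8")
    affine = np.diag(list(pitch) + [1.0])
    img = nib.Nifti1Image(labels.astype(np.uint8), affine)
    img.header.set_zooms(pitch)
    nib.save(img, str(path))


def load_labels(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    pitch = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj).astype(np.uint8), pitch
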
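"""Run configuration: one YAML document drives a reproducible run.

Defaults match the study conditions of the ovine plated-osteotomy model
wherever those are fixed by the protocol: callus band 250–1000 mgHA/ccm,
3 Nm failure-drop stop criterion, 3 mm osteotomy gap, six animals per
group.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # inputs / outputs
    input_paths: list[str] = field(default_factory=list)
    output_dir: str = "results"
    # ROI geometry (mm along the bone axis)
    plate_extent: tuple[float, float] | None = None
    screw_axial_positions: list[float] = field(default_factory=list)
    gap_bounds: tuple[float, float] | None = None
    cis_normal: tuple[float, float] = (1.0, 0.0)
    # segmentation thresholds (mgHA/ccm)
    callus_low: float = 250.0
    bone_high: float = 1000.0
    metal_threshold: float | None = None
    denoise_sigma: float = 0.5
    denoise_support: float = 2.0
    # refinement
    opening_radius: int = 1
    closing_radius: int = 1
    min_component: int = 27
    reassign_mature: bool = False
    envelope_margin: float = 5.0
    # torsion
    failure_drop: float = 3.0
    window_fraction: float = 0.2
    offset_angle: float = 0.5
    # phantom study
    gap_width: float = 3.0
    n_per_group: int = 6
    group_multipliers: dict[str, float] = field(
        default_factory=lambda: {"LS": 1.0, "VFLS3": 1.4, "VFLS6": 1.93}
    )
    group_cv: float = 0.25
    voxel_pitch: float = 0.2
    noise_sd: float = 0.0
    # stats
    percent_decimals: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.callus_low < self.bone_high:
            raise ValueError("callus_low must be < bone_high")
        if self.failure_drop <= 0 or self.gap_width <= 0:
            raise ValueError("failure_drop and gap_width must be > 0")
        if self.plate_extent is not None:
            self.plate_extent = tuple(float(v) for v in self.plate_extent)  # type: ignore[assignment]
        if self.gap_bounds is not None:
            self.gap_bounds = tuple(float(v) for v in self.gap_bounds)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        """Short hash of the resolved configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.content_hash(), "seed": self.seed}

    def require_roi_geometry(self) -> None:
        """Fail before any computation if the ROI geometry is incomplete."""
        if not self.screw_axial_positions:
            raise ValueError("config error: screw_axial_positions missing")
        if self.gap_bounds is None:
            raise ValueError("config error: gap_bounds missing")
        if self.plate_extent is None:
            raise ValueError("config error: plate_extent missing")
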
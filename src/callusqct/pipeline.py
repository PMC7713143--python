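"""End-to-end analysis runs tying the modules together.

These functions are the library-level bodies of the CLI subcommands:
morphometry of one calibrated volume, and a full phantom study
(generate, segment, measure, compare) producing the summary tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry, phantom, roi, segmentation, stats
from .config import RunConfig
from .volume import AXIAL_AXIS, CalibratedVolume, load_nifti, load_tiff_stack

logger = logging.getLogger("callusqct")


def load_any_volume(path: str | Path) -> CalibratedVolume:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        return load_nifti(path)
    if path.suffix in (".tif", ".tiff"):
        return load_tiff_stack(path)
    raise ValueError(f"unsupported volume format: {path}")


def analyze_volume(volume: CalibratedVolume, config: RunConfig) -> list:
    """Segment one volume and compute per-ROI morphometry."""
    config.require_roi_geometry()
    cis = np.asarray(config.cis_normal, dtype=float)
    smoothed = segmentation.denoise(volume, config.denoise_sigma, config.denoise_support)
    masks = segmentation.segment(
        smoothed, config.callus_low, config.bone_high, config.metal_threshold
    )
    if config.opening_radius or config.closing_radius or config.min_component > 1:
        masks = segmentation.refine_masks(
            masks, config.opening_radius, config.closing_radius, config.min_component
        )
    if config.reassign_mature:
        envelope = segmentation.build_native_envelope(
            masks, config.gap_bounds, config.envelope_margin
        )
        masks, n_reassigned = segmentation.reassign_mature_callus(masks, envelope)
        logger.info("reassigned %d mature-callus voxels", int(n_reassigned.sum()))
    axis = roi.estimate_bone_axis(masks)
    rois = [
        roi.define_whole_bone_roi(volume, config.plate_extent, cis),
        roi.define_gap_roi(config.screw_axial_positions, config.gap_bounds, cis),
    ]
    return morphometry.summarize_sample(volume, masks, axis, rois, cis_normal=cis)


def run_morphometry(config: RunConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """CLI body: analyze each configured input volume, write tidy results."""
    results = {}
    for path in config.input_paths:
        vol = load_any_volume(path)
        results[Path(path).stem] = analyze_volume(vol, config)
    frame = morphometry.results_to_frame(results)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(outdir / "morphometry.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(config.provenance()))
    return frame


def default_study_template(config: RunConfig) -> phantom.PhantomSpec:
    """Phantom template of the demo study: an osteotomized shaft segment
    with cis and trans periosteal callus compartments around the gap."""
    return phantom.PhantomSpec(
        shaft_outer_diameter=20.0,
        shaft_inner_diameter=12.0,
        shaft_length=50.0,
        gap_width=config.gap_width,
        voxel_pitch=config.voxel_pitch,
        callus_compartments=[
            phantom.CallusCompartmentSpec(
                side="cis", target_volume=2.3, density=720.0, axial_extent=18.0
            ),
            phantom.CallusCompartmentSpec(
                side="trans", target_volume=3.7, density=715.0, axial_extent=18.0
            ),
        ],
        noise_sd=config.noise_sd,
        seed=config.seed,
    )


def run_study(config: RunConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """CLI body: phantom study — generate groups, measure, compare.

    Generates ``n_per_group`` phantoms per configured group (effect
    multipliers scale the callus compartment volumes), runs the full
    segmentation + morphometry pipeline on each, and builds the group
    comparison table (summaries, ANOVA, Tukey, percent differences).
    """
    if len(config.group_multipliers) < 2:
        raise ValueError("need at least 2 groups configured")
    template = default_study_template(config)
    group_specs = {
        label: (template, mult) for label, mult in config.group_multipliers.items()
    }
    dataset = phantom.generate_group_dataset(
        group_specs, config.n_per_group, config.seed, cv=config.group_cv
    )

    run_cfg = RunConfig(**{**config.to_dict(), "input_paths": []})
    rows = []
    for i, (vol, truth, label) in enumerate(dataset):
        cfg_i = RunConfig(**run_cfg.to_dict())
        cfg_i.gap_bounds = truth.gap_bounds
        cfg_i.screw_axial_positions = truth.screw_axial_positions
        span = (min(truth.screw_axial_positions), max(truth.screw_axial_positions))
        cfg_i.plate_extent = (max(0.0, span[0] - 2.0), min(vol.scan_length_mm, span[1] + 2.0))
        for res in analyze_volume(vol, cfg_i):
            base = {"sample": f"s{i:02d}", "group": label, "roi": res.roi.kind}
            for var, val in (
                ("callus_volume_ccm", res.callus_volume),
                ("callus_density_mgHAccm", res.callus_density),
                ("cis_callus_volume_ccm", res.cis_callus_volume),
                ("trans_callus_volume_ccm", res.trans_callus_volume),
            ):
                rows.append({**base, "variable": f"{res.roi.kind}:{var}", "value": val})
    long = pd.DataFrame(rows)
    table = stats.build_comparison_table(
        long, percent_decimals=config.percent_decimals
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        long.to_csv(outdir / "per_sample.csv", index=False)
        table.to_csv(outdir / "comparison.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(config.provenance()))
    return table
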
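"""Morphometry: volumes, densities, pMOI against analytic and brute-force oracles."""

import numpy as np
import pytest

from callusqct import (
    CalibratedVolume,
    compute_density,
    compute_volume,
    define_gap_roi,
    define_whole_bone_roi,
    pmoi_profile,
    summarize_sample,
)
from callusqct.morphometry import results_to_frame
from callusqct.roi import BoneAxis
from callusqct.segmentation import SegmentationMasks


def masks_from_bool(bone, callus=None, pitch=(1.0, 1.0, 1.0)):
    if callus is None:
        callus = np.zeros_like(bone)
    return SegmentationMasks(
        bone=bone, callus=callus, background=~(bone | callus), voxel_pitch=pitch
    )


def straight_axis(masks):
    bone_slices = np.flatnonzero((masks.bone | masks.callus).any(axis=(0, 1)))
    pitch = np.asarray(masks.voxel_pitch)
    track = []
    for k in bone_slices:
        sl = (masks.bone | masks.callus)[:, :, k]
        track.append((int(k), np.argwhere(sl).mean(axis=0) * pitch[:2]))
    centre = np.array([0.0, 0.0, 0.0])
    return BoneAxis(point=centre, direction=np.array([0.0, 0.0, 1.0]), centroid_track=track)


class TestVolumeAndDensity:
    def test_empty_mask_zero_volume(self):
        assert compute_volume(np.zeros((4, 4, 4), dtype=bool), (1.0, 1.0, 1.0)) == 0.0

    def test_thousand_unit_voxels_is_one_ccm(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:1000] = True
        assert compute_volume(mask, (1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_phantom_volume_equals_truth(self, noiseless_phantom, noiseless_masks):
        spec, _, truth = noiseless_phantom
        cal = compute_volume(noiseless_masks.callus, (spec.voxel_pitch,) * 3)
        expected = truth.true_volumes["callus_cis"] + truth.true_volumes["callus_trans"]
        assert cal == pytest.approx(expected, abs=1e-12)

    def test_uniform_density(self):
        vol = CalibratedVolume(np.full((4, 4, 4), 700.0), (1, 1, 1))
        assert compute_density(vol, np.ones((4, 4, 4), dtype=bool)) == 700.0

    def test_two_halves_average(self):
        vals = np.full((4, 4, 4), 600.0)
        vals[2:] = 800.0
        vol = CalibratedVolume(vals, (1, 1, 1))
        assert compute_density(vol, np.ones((4, 4, 4), dtype=bool)) == 700.0

    def test_empty_mask_density_is_contract_error(self):
        vol = CalibratedVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            compute_density(vol, np.zeros((4, 4, 4), dtype=bool))


class TestPMOI:
    def _annulus_masks(self, d_outer, d_inner, pitch, n_slices=5):
        half = d_outer / 2 + 2 * pitch
        n = int(np.ceil(2 * half / pitch))
        c = (n - 1) / 2.0
        i = (np.arange(n) - c) * pitch
        r2 = i[:, None] ** 2 + i[None, :] ** 2
        ann = (r2 <= (d_outer / 2) ** 2) & (r2 > (d_inner / 2) ** 2)
        bone = np.repeat(ann[:, :, None], n_slices, axis=2)
        return masks_from_bool(bone, pitch=(pitch, pitch, pitch))

    def test_hollow_cylinder_matches_closed_form(self):
        D, d, pitch = 10.0, 6.0, 0.1
        masks = self._annulus_masks(D, d, pitch)
        profile = pmoi_profile(masks, straight_axis(masks))
        expected = np.pi * (D**4 - d**4) / 32.0  # 854.51 mm^4
        np.testing.assert_allclose(profile[:, 1], expected, rtol=0.02)

    def test_solid_square_matches_closed_form(self):
        a, pitch = 8.0, 0.1
        n = int(a / pitch)
        bone = np.zeros((n + 10, n + 10, 3), dtype=bool)
        bone[5 : 5 + n, 5 : 5 + n, :] = True
        masks = masks_from_bool(bone, pitch=(pitch, pitch, pitch))
        profile = pmoi_profile(masks, straight_axis(masks))
        np.testing.assert_allclose(profile[:, 1], a**4 / 6.0, rtol=0.02)

    def test_random_blob_matches_brute_force(self):
        """Independent oracle: explicit double loop over the slice voxels."""
        rng = np.random.default_rng(8)
        pitch = (0.7, 0.4, 1.0)
        bone = rng.random((15, 12, 4)) < 0.3
        bone[:, :, 2] = False  # an empty slice records J = 0
        masks = masks_from_bool(bone, pitch=pitch)
        profile = pmoi_profile(masks, straight_axis(masks))
        area = pitch[0] * pitch[1]
        for k in range(4):
            coords = []
            for i in range(15):
                for j in range(12):
                    if bone[i, j, k]:
                        coords.append((i * pitch[0], j * pitch[1]))
            if not coords:
                assert profile[k, 1] == 0.0
                continue
            coords = np.array(coords)
            cbar = coords.mean(axis=0)
            j_expected = float((((coords - cbar) ** 2).sum()) * area)
            assert profile[k, 1] == pytest.approx(j_expected, rel=1e-12)

    def test_translation_invariance(self):
        pitch = (1.0, 1.0, 1.0)
        blob = np.zeros((20, 20, 1), dtype=bool)
        blob[3:7, 4:9, 0] = True
        shifted = np.roll(blob, (6, 5), axis=(0, 1))
        j1 = pmoi_profile(masks_from_bool(blob, pitch=pitch), straight_axis(masks_from_bool(blob, pitch=pitch)))[0, 1]
        j2 = pmoi_profile(masks_from_bool(shifted, pitch=pitch), straight_axis(masks_from_bool(shifted, pitch=pitch)))[0, 1]
        assert j1 == pytest.approx(j2, rel=1e-12)

    def test_adding_distant_voxel_increases_j(self):
        pitch = (1.0, 1.0, 1.0)
        blob = np.zeros((30, 30, 1), dtype=bool)
        blob[12:18, 12:18, 0] = True
        base = pmoi_profile(masks_from_bool(blob, pitch=pitch), straight_axis(masks_from_bool(blob, pitch=pitch)))[0, 1]
        blob2 = blob.copy()
        blob2[1, 1, 0] = True  # far outside the radius of gyration
        grown = pmoi_profile(masks_from_bool(blob2, pitch=pitch), straight_axis(masks_from_bool(blob2, pitch=pitch)))[0, 1]
        assert grown > base

    def test_positions_are_percent_of_scan_length(self, noiseless_masks, bone_axis):
        profile = pmoi_profile(noiseless_masks, bone_axis)
        assert profile[:, 0].min() > 0.0 and profile[:, 0].max() < 100.0
        assert profile.shape[0] == noiseless_masks.shape[2]

    def test_larger_periosteal_callus_gives_larger_pmoi(self):
        """Group-level signature: the group with more periosteal callus has
        larger mean pMOI in the callus-bearing segment."""
        from callusqct import CallusCompartmentSpec, estimate_bone_axis, generate_phantom, segment
        from conftest import small_spec

        means = []
        for vol_ccm in (0.3, 0.9):
            spec = small_spec(
                callus_compartments=[
                    CallusCompartmentSpec("cis", vol_ccm, 700.0, 10.0),
                    CallusCompartmentSpec("trans", vol_ccm, 700.0, 10.0),
                ]
            )
            vol, truth = generate_phantom(spec)
            masks = segment(vol)
            profile = pmoi_profile(masks, estimate_bone_axis(masks))
            centre = (profile[:, 0] > 35) & (profile[:, 0] < 65)
            means.append(profile[centre, 1].mean())
        assert means[1] > means[0]


class TestSummarizeSample:
    def test_noiseless_phantom_all_fields_equal_truth(
        self, noiseless_phantom, noiseless_masks, bone_axis
    ):
        spec, vol, truth = noiseless_phantom
        wb = define_whole_bone_roi(vol, (0.0, vol.scan_length_mm), truth.cis_halfspace_normal)
        res = summarize_sample(vol, noiseless_masks, bone_axis, [wb])[0]
        assert res.callus_volume == pytest.approx(
            truth.true_volumes["callus_cis"] + truth.true_volumes["callus_trans"], abs=1e-12
        )
        assert res.bone_volume == pytest.approx(truth.true_volumes["cortical"], abs=1e-12)
        assert res.cis_callus_volume == pytest.approx(truth.true_volumes["callus_cis"], abs=1e-12)
        assert res.trans_callus_volume == pytest.approx(
            truth.true_volumes["callus_trans"], abs=1e-12
        )
        assert res.bone_density == pytest.approx(spec.cortical_density)
        # mean callus density = volume-weighted mean of the two compartments
        vc, vt = truth.true_volumes["callus_cis"], truth.true_volumes["callus_trans"]
        expected = (720.0 * vc + 715.0 * vt) / (vc + vt)
        assert res.callus_density == pytest.approx(expected, abs=1e-9)

    def test_cis_trans_sum_conserved(self, noiseless_phantom, noiseless_masks, bone_axis):
        _, vol, truth = noiseless_phantom
        gap = define_gap_roi(truth.screw_axial_positions, truth.gap_bounds,
                             truth.cis_halfspace_normal)
        res = summarize_sample(vol, noiseless_masks, bone_axis, [gap])[0]
        assert res.cis_callus_volume + res.trans_callus_volume == pytest.approx(
            res.callus_volume, abs=vol.voxel_volume_mm3 / 1000.0
        )

    def test_callus_free_phantom_flags_missing_density(self):
        from callusqct import estimate_bone_axis, generate_phantom, segment
        from conftest import small_spec

        spec = small_spec(callus_compartments=[])
        vol, truth = generate_phantom(spec)
        masks = segment(vol)
        axis = estimate_bone_axis(masks)
        wb = define_whole_bone_roi(vol, (0.0, vol.scan_length_mm))
        res = summarize_sample(vol, masks, axis, [wb])[0]
        assert res.callus_volume == 0.0
        assert res.callus_density is None

    def test_gap_values_bounded_by_whole_bone(
        self, noiseless_phantom, noiseless_masks, bone_axis
    ):
        _, vol, truth = noiseless_phantom
        wb = define_whole_bone_roi(vol, (0.0, vol.scan_length_mm))
        gap = define_gap_roi(truth.screw_axial_positions, truth.gap_bounds)
        res_wb, res_gap = summarize_sample(vol, noiseless_masks, bone_axis, [wb, gap])
        assert res_gap.callus_volume <= res_wb.callus_volume
        assert res_gap.bone_volume <= res_wb.bone_volume

    def test_results_frame_tidy(self, noiseless_phantom, noiseless_masks, bone_axis):
        _, vol, truth = noiseless_phantom
        wb = define_whole_bone_roi(vol, (0.0, vol.scan_length_mm))
        res = summarize_sample(vol, noiseless_masks, bone_axis, [wb])
        frame = results_to_frame({"s1": res})
        assert list(frame["sample"]) == ["s1"]
        assert "callus_volume_ccm" in frame.columns
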
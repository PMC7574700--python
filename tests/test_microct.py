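"""Density calibration and morphometry against analytic phantoms."""

import numpy as np
import pytest

from osteoquant.microct import (
    VoxelVolume,
    calibrate_density,
    cortical_morphometry,
    local_thickness,
    tissue_mineral_density,
    trabecular_morphometry,
)
from osteoquant.synthetic import forward_volume


def annulus(outer_mm=1.0, thickness_mm=0.5, voxel_um=20.0, n_slices=3):
    return forward_volume(
        "cortical",
        {"outer_radius_mm": outer_mm, "thickness_mm": thickness_mm,
         "n_slices": n_slices},
        voxel_um,
    )


class TestDensityCalibration:
    def test_identity_map(self):
        calib = calibrate_density((200.0, 800.0))
        assert calib.slope == pytest.approx(1.0)
        assert calib.intercept == pytest.approx(0.0)

    def test_two_point_line(self):
        calib = calibrate_density((1000.0, 4000.0))
        assert calib.slope == pytest.approx(0.2)
        assert calib.intercept == pytest.approx(0.0)

    def test_equal_grays_rejected(self):
        with pytest.raises(ValueError):
            calibrate_density((500.0, 500.0))

    def test_constant_density_tmd(self):
        """A volume of uniform calibrated density reports that density."""
        calib = calibrate_density((1000.0, 4000.0))
        gray = 1594.7 / calib.slope
        vol = VoxelVolume(
            np.full((4, 10, 10), gray), voxel_size_um=20.0, threshold=1.0
        )
        assert tissue_mineral_density(vol, calib) == pytest.approx(1594.7)


class TestCorticalMorphometry:
    def test_annulus_closed_forms(self):
        """R=1.0, r=0.5 mm: Ct.Ar = pi(R^2-r^2), J = pi(R^4-r^4)/2,
        Ct.Th = R - r, each within 2%."""
        res = cortical_morphometry(annulus())
        assert res.ct_ar_mm2 == pytest.approx(np.pi * 0.75, rel=0.02)
        assert res.ct_th_mm == pytest.approx(0.5, rel=0.02)
        assert res.j_mm4 == pytest.approx(np.pi * 0.9375 / 2.0, rel=0.02)

    def test_scaling_dimensions(self):
        """Doubling linear size: Ct.Ar x4, J x16."""
        a = cortical_morphometry(annulus(1.0, 0.5, 20.0))
        b = cortical_morphometry(annulus(2.0, 1.0, 20.0))
        assert b.ct_ar_mm2 == pytest.approx(4.0 * a.ct_ar_mm2, rel=0.02)
        assert b.j_mm4 == pytest.approx(16.0 * a.j_mm4, rel=0.03)

    def test_j_against_bruteforce_voxel_sum(self, rng):
        """J on a randomly perturbed annulus equals the direct sum of
        r^2 dA over the same mask about its centroid."""
        vol = annulus(n_slices=1)
        mask = vol.mask.copy()
        # random perturbation: flip a band of boundary voxels
        noise = rng.random(mask.shape) < 0.02
        mask ^= noise
        vox_mm = vol.voxel_size_um / 1000.0
        res = cortical_morphometry(VoxelVolume(mask, vol.voxel_size_um))
        yy, xx = np.nonzero(mask[0])
        r2 = (yy - yy.mean()) ** 2 + (xx - xx.mean()) ** 2
        j_oracle = float(np.sum(r2 * vox_mm**2) * vox_mm**2)
        assert res.j_mm4 == pytest.approx(j_oracle, rel=1e-9)

    def test_empty_slice_skipped_allempty_rejected(self):
        vol = annulus(n_slices=2)
        data = vol.mask.copy()
        data[1] = False
        res = cortical_morphometry(VoxelVolume(data, vol.voxel_size_um))
        assert any("empty" in f for f in res.flags)
        with pytest.raises(ValueError):
            cortical_morphometry(
                VoxelVolume(np.zeros((2, 5, 5), bool), vol.voxel_size_um)
            )

    def test_translation_and_rotation_invariance(self):
        vol = annulus(n_slices=1)
        base = cortical_morphometry(vol)
        shifted = np.pad(vol.mask, ((0, 0), (7, 0), (0, 11)))[:, :-0 or None]
        res_s = cortical_morphometry(VoxelVolume(shifted, vol.voxel_size_um))
        rotated = np.rot90(vol.mask, axes=(1, 2)).copy()
        res_r = cortical_morphometry(VoxelVolume(rotated, vol.voxel_size_um))
        for res in (res_s, res_r):
            assert res.ct_ar_mm2 == pytest.approx(base.ct_ar_mm2, rel=1e-9)
            assert res.j_mm4 == pytest.approx(base.j_mm4, rel=1e-9)
            assert res.ct_th_mm == pytest.approx(base.ct_th_mm, rel=1e-9)

    def test_j_minimal_about_centroid(self):
        """Parallel-axis: J about any shifted axis exceeds centroidal J."""
        vol = annulus(n_slices=1)
        mask = vol.mask[0]
        vox_mm = vol.voxel_size_um / 1000.0
        yy, xx = np.nonzero(mask)
        cy, cx = yy.mean(), xx.mean()
        j_centroid = np.sum((yy - cy) ** 2 + (xx - cx) ** 2)
        for dy, dx in [(5, 0), (0, 5), (3, -4)]:
            j_shift = np.sum((yy - cy - dy) ** 2 + (xx - cx - dx) ** 2)
            assert j_shift > j_centroid
        del vox_mm

    def test_voxel_refinement_converges(self):
        """Halving the voxel size moves Ct.Ar and J toward closed forms."""
        truth_ar = np.pi * 0.75
        truth_j = np.pi * 0.9375 / 2.0
        errs = []
        for vox in (40.0, 20.0, 10.0):
            res = cortical_morphometry(annulus(1.0, 0.5, vox, n_slices=1))
            errs.append(
                abs(res.ct_ar_mm2 - truth_ar) / truth_ar
                + abs(res.j_mm4 - truth_j) / truth_j
            )
        assert errs[2] < errs[0]


class TestTrabecularMorphometry:
    def test_solid_cube(self):
        vol = VoxelVolume(np.ones((20, 20, 20), bool), 10.0)
        res = trabecular_morphometry(vol)
        assert res.bv_tv_pct == 100.0
        assert res.tb_th_mm is None  # empty phase undefined
        assert res.flags

    def test_parallel_plates_closed_form(self):
        """Plates 0.10 mm / gaps 0.15 mm: BV/TV 40%, Tb.Th 0.10,
        Tb.Sp 0.15, Tb.N 4.0 within voxelization tolerance."""
        vol = forward_volume(
            "plates", {"edge_mm": 0.5, "plate_mm": 0.10, "gap_mm": 0.15}, 5.0
        )
        res = trabecular_morphometry(vol)
        assert res.bv_tv_pct == pytest.approx(40.0, abs=1.0)
        assert res.tb_th_mm == pytest.approx(0.10, abs=0.005)
        assert res.tb_sp_mm == pytest.approx(0.15, abs=0.005)
        assert res.tb_n_per_mm == pytest.approx(4.0, rel=0.05)

    def test_random_field_bvtv_equals_voxel_count(self, rng):
        """BV/TV of a thresholded field equals the foreground fraction."""
        vol = forward_volume(
            "field",
            {"edge_mm": 0.4, "bv_tv_pct": 46.14, "sigma_vox": 3.0},
            10.0,
            rng=rng,
        )
        res = trabecular_morphometry(vol)
        oracle = 100.0 * vol.mask.sum() / vol.mask.size
        assert res.bv_tv_pct == pytest.approx(oracle, abs=1e-9)
        assert res.bv_tv_pct == pytest.approx(46.14, abs=0.5)

    def test_field_thickness_calibration(self, rng):
        """Self-calibrated random field hits the target thickness (3%)."""
        vol = forward_volume(
            "field",
            {"edge_mm": 0.6, "bv_tv_pct": 46.14, "tb_th_mm": 0.095},
            10.0,
            rng=rng,
        )
        res = trabecular_morphometry(vol)
        assert res.tb_th_mm == pytest.approx(0.095, rel=0.05)

    def test_rotation_invariance(self, rng):
        vol = forward_volume(
            "plates", {"edge_mm": 0.25, "plate_mm": 0.05, "gap_mm": 0.075}, 5.0
        )
        base = trabecular_morphometry(vol)
        rot = VoxelVolume(
            np.rot90(vol.mask, axes=(0, 2)).copy(), vol.voxel_size_um
        )
        res = trabecular_morphometry(rot)
        assert res.bv_tv_pct == pytest.approx(base.bv_tv_pct)
        assert res.tb_th_mm == pytest.approx(base.tb_th_mm, rel=1e-9)


class TestLocalThickness:
    def test_slab_thickness(self):
        """An isolated slab of 10 voxels reads 10 voxels thick."""
        mask = np.zeros((30, 20, 20), bool)
        mask[10:20] = True
        th = local_thickness(mask, 1.0)
        assert th[mask].mean() == pytest.approx(10.0, abs=1.0)
        assert th[~mask].max() == 0.0

    def test_empty_mask(self):
        th = local_thickness(np.zeros((5, 5, 5), bool), 1.0)
        assert th.sum() == 0.0
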
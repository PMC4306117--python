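"""Unit tests for segmentation, component labelling and 3D morphometry."""

import numpy as np
import pytest

from plaquemorph.morphometry import (
    InclusionRecord,
    MorphometryParams,
    ThresholdConfig,
    VoxelVolume,
    _voxel_face_area,
    calibrate_grey_values,
    classify_inclusion,
    compute_cvf,
    equivalent_diameter,
    fit_calibration,
    label_components,
    measure_surface_area,
    measure_volume,
    principal_extents,
    run_morphometry,
    segment_volume,
    sphericity,
)

from conftest import digitised_sphere


# ---------------------------------------------------------------------------
# grey-value calibration


class TestCalibration:
    def test_two_points_interpolate_exactly(self):
        # air at 100 GV -> -1000, water at 600 GV -> 0 (clipped to 16-bit floor)
        refs = [("air", 100.0, -1000.0), ("water", 600.0, 0.0)]
        slope, intercept = fit_calibration(refs)
        assert slope * 600 + intercept == pytest.approx(0.0, abs=1e-9)
        assert slope * 100 + intercept == pytest.approx(-1000.0, abs=1e-9)
        vol = VoxelVolume(np.full((2, 2, 2), 600, dtype=np.uint16))
        assert calibrate_grey_values(vol, refs).grid.max() == 0

    def test_identity_references_leave_volume_unchanged(self):
        vol = VoxelVolume(np.arange(8, dtype=np.uint16).reshape(2, 2, 2) * 100)
        refs = [("a", 0.0, 0.0), ("b", 500.0, 500.0), ("c", 700.0, 700.0)]
        out = calibrate_grey_values(vol, refs)
        np.testing.assert_array_equal(out.grid, vol.grid)

    def test_three_point_fit_matches_closed_form_ols(self):
        # non-collinear points: compare against the textbook OLS solution
        refs = [("a", 100.0, -990.0), ("b", 600.0, 30.0), ("c", 1500.0, 1795.0)]
        x = np.array([r[1] for r in refs])
        y = np.array([r[2] for r in refs])
        slope_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept_oracle = y.mean() - slope_oracle * x.mean()
        slope, intercept = fit_calibration(refs)
        assert slope == pytest.approx(slope_oracle, rel=1e-12)
        assert intercept == pytest.approx(intercept_oracle, rel=1e-12)

    def test_duplicate_measured_values_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_calibration([("a", 500.0, 0.0), ("b", 500.0, 10.0)])


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentation:
    def test_class_assignment_and_band_boundaries(self):
        grid = np.array([[[100, 324, 700, 1249, 1250, 1800]]], dtype=np.uint16)
        tissue, calc = segment_volume(VoxelVolume(grid))
        np.testing.assert_array_equal(tissue[0, 0], [False, True, True, True, False, False])
        np.testing.assert_array_equal(calc[0, 0], [False, False, False, False, True, True])

    def test_masks_are_disjoint(self):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 3000, size=(10, 10, 10)).astype(np.uint16)
        tissue, calc = segment_volume(VoxelVolume(grid))
        assert not np.any(tissue & calc)

    def test_all_background_volume_flags_undefined_cvf(self):
        vol = VoxelVolume(np.full((5, 5, 5), 10, dtype=np.uint16))
        with pytest.warns(UserWarning, match="CVF undefined"):
            report = run_morphometry(vol)
        assert report.cvf is None and report.records == []

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(tissue_low=500, tissue_high=400, calc_low=1250)


# ---------------------------------------------------------------------------
# connected components


def _flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """Brute-force BFS component count, independent of scipy labelling."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) and mask[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
    return count


class TestLabelComponents:
    def test_two_separated_spheres_are_two_components(self):
        mask = np.zeros((20, 20, 40), dtype=bool)
        mask[8:12, 8:12, 5:9] = True
        mask[8:12, 8:12, 20:24] = True
        assert label_components(mask)[1] == 2

    def test_corner_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True
        assert label_components(mask, 26)[1] == 1
        assert label_components(mask, 6)[1] == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("density", [0.1, 0.3, 0.5])
    def test_random_masks_match_flood_fill_oracle(self, connectivity, density):
        rng = np.random.default_rng(42)
        for _ in range(5):
            mask = rng.random((12, 12, 12)) < density
            assert label_components(mask, connectivity)[1] == _flood_fill_count(
                mask, connectivity
            )


# ---------------------------------------------------------------------------
# measurements


class TestVolumeAndDiameter:
    def test_voxel_count_arithmetic(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        assert measure_volume(mask, 15.5) == pytest.approx(1000 * 3.723875e-6, rel=1e-4)
        assert measure_volume(np.ones((1, 1, 1), bool), 15.5) == pytest.approx(
            3.723875e-6, rel=1e-4
        )

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            measure_volume(np.zeros((3, 3, 3), bool), 15.5)

    def test_digitised_sphere_volume_within_5pc(self):
        r = 10
        mask = digitised_sphere(r)
        v = measure_volume(mask, 15.5)
        v_true = 4 / 3 * np.pi * (r * 15.5e-3) ** 3
        assert v == pytest.approx(v_true, rel=0.05)

    def test_equivalent_diameter_inverts_sphere_volume(self):
        assert equivalent_diameter(np.pi / 6) == pytest.approx(1000.0, rel=1e-12)

    def test_equivalent_diameter_monotone(self):
        vols = [1e-6, 5e-6, 1e-4, 1e-2]
        ds = [equivalent_diameter(v) for v in vols]
        assert ds == sorted(ds)


class TestSurfaceArea:
    def test_digitised_sphere_within_3pc(self):
        r = 10
        a = measure_surface_area(digitised_sphere(r), 1000.0)  # 1000 um voxels: mm^2 == voxel faces
        assert a == pytest.approx(4 * np.pi * r**2, rel=0.03)

    def test_voxel_face_counting_overshoots_sphere_area(self):
        # motivates meshing: raw face counting reads a sphere ~1.5x too large
        r = 10
        faces = _voxel_face_area(digitised_sphere(r))
        assert 1.3 < faces / (4 * np.pi * r**2) < 1.7

    def test_large_box_within_5pc(self):
        box = np.zeros((66, 48, 36), dtype=bool)
        box[3:63, 3:45, 3:33] = True  # 60 x 42 x 30 voxels
        a_true = 2 * (60 * 42 + 42 * 30 + 30 * 60)
        assert measure_surface_area(box, 1000.0) == pytest.approx(a_true, rel=0.05)

    def test_small_box_edge_rounding_bias_is_negative_and_bounded(self):
        # sharp edges are rounded by the smoothing: small boxes read low
        box = np.zeros((26, 20, 16), dtype=bool)
        box[3:23, 3:17, 3:13] = True
        a_true = 2 * (20 * 14 + 14 * 10 + 10 * 20)
        a = measure_surface_area(box, 1000.0)
        assert 0.85 * a_true < a < a_true

    def test_axis_permutation_invariance(self):
        mask = np.zeros((20, 14, 9), dtype=bool)
        mask[3:17, 3:11, 3:6] = True
        a = measure_surface_area(mask, 1000.0)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            assert measure_surface_area(np.transpose(mask, perm), 1000.0) == pytest.approx(
                a, rel=1e-6
            )

    def test_thin_component_falls_back_to_face_area(self):
        mask = np.zeros((5, 5, 1), dtype=bool)
        mask[1:4, 1:4, 0] = True
        flags = []
        a = measure_surface_area(mask, 1000.0, _flags=flags)
        assert "voxel_face_area_fallback" in flags
        assert a == pytest.approx(_voxel_face_area(mask[1:4, 1:4, :]), rel=1e-9)


class TestSphericity:
    def test_unit_sphere_is_one(self):
        assert sphericity(4 * np.pi / 3, 4 * np.pi) == pytest.approx(1.0, rel=1e-12)

    def test_unit_cube_closed_form(self):
        assert sphericity(1.0, 6.0) == pytest.approx((np.pi / 6) ** (1 / 3), abs=5e-4)

    def test_linear_in_inverse_area(self):
        assert sphericity(2.0, 3.0) == pytest.approx(2 * sphericity(2.0, 6.0), rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            sphericity(1.0, -1.0)


class TestPrincipalExtents:
    def test_axis_aligned_box(self):
        mask = np.zeros((16, 10, 8), dtype=bool)
        mask[3:13, 3:7, 3:5] = True  # 10 x 4 x 2 voxels
        l, w, t = principal_extents(mask, 15.5)
        assert (l, w, t) == pytest.approx((10 * 15.5, 4 * 15.5, 2 * 15.5), rel=1e-6)

    def test_rotated_box_within_15pc(self):
        # re-voxelise a 10 x 4 x 2 box rotated 45 degrees about z
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        n = 24
        z, y, x = np.mgrid[:n, :n, :n].astype(float)
        # half-voxel offset keeps the box faces between voxel centres
        zc, yc, xc = z - n / 2 + 0.5, y - n / 2 + 0.5, x - n / 2 + 0.5
        u = c * xc + s * yc
        v = -s * xc + c * yc
        mask = (np.abs(u) <= 5) & (np.abs(v) <= 2) & (np.abs(zc) <= 1)
        l, w, t = principal_extents(mask, 1.0)
        assert l == pytest.approx(10, rel=0.15)
        assert w == pytest.approx(4, rel=0.15)
        assert t == pytest.approx(2, rel=0.15)

    def test_sphere_is_isotropic(self):
        l, w, t = principal_extents(digitised_sphere(8), 1.0)
        assert l / t < 1.1

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        assert principal_extents(mask, 15.5) == (15.5, 15.5, 15.5)


# ---------------------------------------------------------------------------
# classification and CVF


def _record(d_um, psi, l, w, t):
    return InclusionRecord(
        label=1,
        voxel_count=100,
        volume_mm3=np.pi / 6 * (d_um / 1000) ** 3,
        surface_area_mm2=1.0,
        sphericity=psi,
        equivalent_diameter_um=d_um,
        length_um=l,
        width_um=w,
        thickness_um=t,
        centroid_mm=(0, 0, 0),
    )


class TestClassification:
    def test_small_round_particle_is_spherical(self):
        assert classify_inclusion(_record(150, 0.95, 160, 150, 150)) == "spherical"

    def test_plate_with_strong_aspect_ratios_is_sheet(self):
        assert classify_inclusion(_record(450, 0.45, 2000, 800, 100)) == "sheet"

    def test_large_lumpy_mass_is_irregular(self):
        assert classify_inclusion(_record(600, 0.6, 700, 500, 400)) == "irregular"

    def test_rule_order_spherical_takes_precedence(self):
        # small, round AND flat-ish: the spherical rule fires first
        assert classify_inclusion(_record(200, 0.9, 500, 200, 90)) == "spherical"

    def test_max_extent_convention(self):
        params = MorphometryParams(diameter_convention="max_extent")
        rec = _record(250, 0.95, 400, 240, 230)  # longest extent over the cut-off
        assert classify_inclusion(rec, params) == "irregular"


class TestCVF:
    def test_limits(self):
        assert compute_cvf(0.0, 5.0) == 0.0
        assert compute_cvf(2.0, 2.0) == 0.5

    def test_zero_total_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_cvf(0.0, 0.0)


# ---------------------------------------------------------------------------
# pipeline on the small phantom


class TestRunMorphometry:
    def test_class_counts_match_ground_truth(self, small_phantom):
        _, volume, truth = small_phantom
        report = run_morphometry(volume)
        assert report.class_counts == {"spherical": 3, "sheet": 1, "irregular": 1}
        assert len(report.records) == len(truth)

    def test_voxel_conservation(self, small_phantom):
        _, volume, _ = small_phantom
        report = run_morphometry(volume)
        _, calc = segment_volume(volume)
        total = sum(r.voxel_count for r in report.records)
        assert total == int(calc.sum())

    def test_scale_equivariance(self, small_phantom):
        # doubling the voxel size scales V by 8, A by 4 and leaves psi alone;
        # class labels persist once the absolute size cut-off is scaled too
        _, volume, _ = small_phantom
        r1 = run_morphometry(volume)
        r2 = run_morphometry(
            VoxelVolume(volume.grid, volume.voxel_size_um * 2),
            params=MorphometryParams(diameter_max_um=600.0),
        )
        for a, b in zip(r1.records, r2.records):
            assert b.volume_mm3 == pytest.approx(8 * a.volume_mm3, rel=1e-9)
            assert b.surface_area_mm2 == pytest.approx(4 * a.surface_area_mm2, rel=1e-6)
            assert b.sphericity == pytest.approx(a.sphericity, rel=1e-6)
            assert b.geometry_class == a.geometry_class

    def test_cvf_matches_mask_counts(self, small_phantom):
        _, volume, _ = small_phantom
        report = run_morphometry(volume)
        tissue, calc = segment_volume(volume)
        assert report.cvf == pytest.approx(calc.sum() / (calc.sum() + tissue.sum()))
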
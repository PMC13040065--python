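"""Geometric IDP extraction against analytic oracles on spheres and slabs."""

import numpy as np
import pytest

from fetalmorph import idps as I
from fetalmorph.growth import TBV_REFERENCE_MODEL
from fetalmorph.synthetic import PhantomSpec, generate_phantom
from fetalmorph.volume import LOBES, LabelVolume

from conftest import make_ball


def euler_characteristic(mesh: I.SurfaceMesh) -> int:
    v, f = len(mesh.vertices), len(mesh.faces)
    return v - f * 3 // 2 + f


class TestStructureVolume:
    def test_empty_structure_is_zero(self):
        vol = LabelVolume(np.zeros((5, 5, 5), dtype=np.int16), (0.6,) * 3)
        assert I.structure_volume(vol, "CB") == 0.0

    def test_cube_volume_is_count_times_voxel_volume(self):
        grid = np.zeros((12, 12, 12), dtype=np.int16)
        grid[1:11, 1:11, 1:11] = 3  # 1000 WM voxels
        vol = LabelVolume(grid, (0.6,) * 3)
        assert I.structure_volume(vol, "WM") == pytest.approx(1000 * 0.216)

    @pytest.mark.parametrize("r_vox", [5, 10, 15, 25])
    def test_digital_ball_volume_within_two_percent(self, r_vox):
        ball, _ = make_ball(r_vox)
        vol = LabelVolume(ball.astype(np.int16), (0.6,) * 3)
        analytic = 4.0 / 3.0 * np.pi * (r_vox * 0.6) ** 3
        assert abs(I.structure_volume(vol, "TB") - analytic) / analytic < 0.02

    def test_ball_volume_error_decreases_with_radius(self):
        errs = []
        for r_vox in (5, 12, 25):
            ball, _ = make_ball(r_vox)
            measured = ball.sum() * 0.216
            analytic = 4.0 / 3.0 * np.pi * (r_vox * 0.6) ** 3
            errs.append(abs(measured - analytic) / analytic)
        assert errs[0] >= errs[-1]

    def test_unknown_structure_rejected(self):
        vol = LabelVolume(np.zeros((3, 3, 3), dtype=np.int16), (0.6,) * 3)
        with pytest.raises(KeyError):
            I.structure_volume(vol, "cerebrum")


class TestSurface:
    def test_ball_mesh_closed_genus_zero(self):
        ball, _ = make_ball(20)
        mesh = I.extract_surface(ball, (0.6,) * 3)
        assert euler_characteristic(mesh) == 2

    def test_ball_area_within_three_percent(self):
        ball, _ = make_ball(20)
        mesh = I.extract_surface(ball, (0.6,) * 3)
        analytic = 4.0 * np.pi * (20 * 0.6) ** 2
        assert abs(I.mesh_surface_area(mesh) - analytic) / analytic < 0.03

    def test_area_error_decreases_with_radius(self):
        errs = []
        for r_vox in (10, 20, 30):
            ball, _ = make_ball(r_vox)
            mesh = I.extract_surface(ball, (0.6,) * 3)
            analytic = 4.0 * np.pi * (r_vox * 0.6) ** 2
            errs.append(abs(I.mesh_surface_area(mesh) - analytic) / analytic)
        assert errs[0] >= errs[-1]

    def test_border_touching_mask_still_closed(self):
        mesh = I.extract_surface(np.ones((8, 8, 8), dtype=bool), (0.6,) * 3)
        assert euler_characteristic(mesh) == 2

    def test_hollow_shell_has_two_closed_components(self):
        _, rr = make_ball(20)
        shell = (rr <= 12.0) & (rr > 8.0)
        mesh = I.extract_surface(shell, (0.6,) * 3)
        assert euler_characteristic(mesh) == 4

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            I.extract_surface(np.zeros((4, 4, 4), dtype=bool))

    def test_right_triangle_area(self):
        mesh = I.SurfaceMesh(
            vertices=np.array([[0, 0, 0], [3, 0, 0], [0, 4, 0]], dtype=float),
            faces=np.array([[0, 1, 2]]),
        )
        assert I.mesh_surface_area(mesh) == pytest.approx(6.0)

    def test_area_scaling_law(self):
        ball, _ = make_ball(12)
        mesh = I.extract_surface(ball, (0.6,) * 3)
        scaled = I.SurfaceMesh(vertices=mesh.vertices * 2.0, faces=mesh.faces)
        assert I.mesh_surface_area(scaled) == pytest.approx(
            4.0 * I.mesh_surface_area(mesh)
        )


class TestDepth:
    def test_spherical_depth_matches_radius_minus_rho(self):
        ball, rr = make_ball(25)
        R = 25 * 0.6
        cop = ball & (rr > R - 3.0)
        dm = I.depth_map(ball, cop, (0.6,) * 3)
        err = np.abs(dm.values[cop] - (R - rr[cop]))
        assert err.max() <= 0.6 * np.sqrt(3)

    def test_boundary_voxels_within_one_diagonal(self):
        ball, rr = make_ball(15)
        boundary = ball & (rr > 15 * 0.6 - 0.6)
        dm = I.depth_map(ball, boundary, (0.6,) * 3)
        assert dm.values[boundary].max() <= 2 * 0.6 * np.sqrt(3)

    def test_target_outside_brain_rejected(self):
        ball, rr = make_ball(10)
        outside = ~ball
        with pytest.raises(I.ContainmentError):
            I.depth_map(ball, outside, (0.6,) * 3)

    def test_brain_filling_grid_rejected(self):
        full = np.ones((6, 6, 6), dtype=bool)
        with pytest.raises(ValueError, match="unbounded"):
            I.depth_map(full, full, (0.6,) * 3)


class TestThickness:
    def test_flat_slab_recovers_thickness(self):
        t = 5
        cop = np.zeros((30, 30, 30), dtype=bool)
        wm = np.zeros_like(cop)
        cop[10 : 10 + t] = True
        wm[10 + t : 25] = True
        tm = I.thickness_map(cop, wm, spacing_mm=(0.6,) * 3)
        assert abs(tm.masked_values().mean() - t * 0.6) <= 0.3

    def test_one_voxel_shell_measures_about_one_spacing(self):
        _, rr = make_ball(20)
        R = 20 * 0.6
        shell = (rr <= R) & (rr > R - 0.6)
        wm = rr <= R - 0.6
        tm = I.thickness_map(shell, wm, spacing_mm=(0.6,) * 3)
        assert abs(tm.masked_values().mean() - 0.6) <= 0.3

    def test_empty_cortex_rejected(self):
        with pytest.raises(ValueError):
            I.thickness_map(
                np.zeros((5, 5, 5), dtype=bool), np.ones((5, 5, 5), dtype=bool)
            )

    def test_no_wm_adjacency_rejected(self):
        cop = np.zeros((10, 10, 10), dtype=bool)
        wm = np.zeros_like(cop)
        cop[1:3] = True
        wm[7:9] = True
        wm[3:7] = False  # gap between cortex and white matter
        with pytest.raises(I.ContainmentError):
            I.thickness_map(cop, wm)


class TestSummaries:
    def test_constant_depth_mean_is_constant(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4] = True
        dm = I.DepthMap(values=np.full((6, 6, 6), 2.5), mask=mask)
        s = I.lobe_summary(mask, depth=dm, spacing_mm=(0.6,) * 3)
        assert s["mean_depth"] == pytest.approx(2.5)

    def test_whole_cop_lobe_volume_equals_copv(self, phantom22):
        cop = phantom22.mask("CoP")
        s = I.lobe_summary(cop, spacing_mm=phantom22.spacing_mm)
        assert s["volume"] == pytest.approx(I.structure_volume(phantom22, "CoP"))

    def test_mixture_of_equal_halves_averages(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0], mask[1] = True, True
        values = np.zeros((4, 4, 4))
        values[0], values[1] = 1.0, 3.0
        dm = I.DepthMap(values=values, mask=mask)
        s = I.lobe_summary(mask, depth=dm, spacing_mm=(0.6,) * 3)
        assert s["mean_depth"] == pytest.approx(2.0)

    def test_empty_lobe_is_missing_not_zero(self):
        s = I.lobe_summary(np.zeros((3, 3, 3), dtype=bool), spacing_mm=(0.6,) * 3)
        assert np.isnan(s["volume"])

    @pytest.mark.parametrize(
        "depths,expected",
        [([3.0, 3.0, 3.0], 3.0), ([1.0, 2.0, 100.0], 2.0), ([1, 2, 3, 4], 2.5)],
    )
    def test_sylvian_fissure_depth_is_median(self, depths, expected):
        n = len(depths)
        values = np.zeros((n, 1, 1))
        values[:, 0, 0] = depths
        mask = np.ones((n, 1, 1), dtype=bool)
        dm = I.DepthMap(values=values, mask=mask)
        assert I.sylvian_fissure_depth(dm, mask) == pytest.approx(expected)

    def test_empty_insula_is_missing(self):
        dm = I.DepthMap(values=np.zeros((3, 3, 3)), mask=np.zeros((3, 3, 3), bool))
        assert np.isnan(I.sylvian_fissure_depth(dm, np.zeros((3, 3, 3), bool)))


class TestExtractAll:
    def test_all_28_measures_finite_on_phantom(self, idp_record22):
        assert set(idp_record22.measures) == set(I.IDP_NAMES)
        for name in I.IDP_NAMES:
            assert np.isfinite(idp_record22.measures[name]), name

    def test_lobe_volumes_sum_to_copv(self, idp_record22):
        lobes = sum(idp_record22.measures[f"{l}V"] for l in LOBES)
        assert lobes == pytest.approx(idp_record22.measures["CoPV"], abs=0.216)

    def test_tbv_matches_growth_curve(self, idp_record22):
        target = float(np.asarray(TBV_REFERENCE_MODEL.mean(22.0)).item()) * 1000.0
        assert abs(idp_record22.measures["TBV"] - target) / target < 0.02

    def test_missing_labels_flagged_not_fatal(self):
        grid = np.zeros((20, 20, 20), dtype=np.int16)
        grid[5:15, 5:15, 5:15] = 1  # TB only
        vol = LabelVolume(grid, (0.6,) * 3)
        rec = I.extract_all_idps(vol)
        assert rec.measures["TBV"] > 0
        assert np.isnan(rec.measures["CoPSA"])


class TestRelativeVolumes:
    def test_direct_arithmetic(self):
        rec = I.IDPRecord(
            measures={"TBV": 100.0, "CoPV": 10.0, "ILV": 2.0, "PLV": 4.0}
        )
        rel = I.relative_volumes(rec)
        assert rel.lobe_over_copv["rILV"] == pytest.approx(0.2)
        assert rel.lobe_over_copv["rPLV"] == pytest.approx(0.4)
        assert rel.rilv_over_rplv == pytest.approx(0.5)

    def test_equal_lobes_unit_ratio(self):
        rec = I.IDPRecord(measures={"TBV": 50.0, "CoPV": 10.0, "ILV": 3.0, "PLV": 3.0})
        assert I.relative_volumes(rec).rilv_over_rplv == pytest.approx(1.0)

    def test_partitioning_lobes_sum_to_one(self, idp_record22):
        rel = I.relative_volumes(idp_record22)
        assert sum(rel.lobe_over_copv.values()) == pytest.approx(1.0, abs=1e-6)

    def test_zero_parietal_gives_missing_ratio(self):
        rec = I.IDPRecord(measures={"TBV": 50.0, "CoPV": 10.0, "ILV": 3.0, "PLV": 0.0})
        assert np.isnan(I.relative_volumes(rec).rilv_over_rplv)

    def test_nonpositive_tbv_rejected(self):
        with pytest.raises(ValueError):
            I.relative_volumes(I.IDPRecord(measures={"TBV": 0.0, "CoPV": 1.0}))


class TestScaleEquivariance:
    def test_volumes_areas_depths_scale_with_spacing(self):
        # same voxel lattice read at doubled spacing: s = 2
        vol1 = generate_phantom(PhantomSpec(ga_weeks=20.0, spacing_mm=1.0, grid_size=100))
        vol2 = LabelVolume(vol1.grid, (2.0,) * 3, label_map=dict(vol1.label_map))
        assert I.structure_volume(vol2, "TB") == pytest.approx(
            8.0 * I.structure_volume(vol1, "TB")
        )
        m1 = I.extract_surface(vol1.mask("TB"), vol1.spacing_mm)
        m2 = I.extract_surface(vol2.mask("TB"), vol2.spacing_mm)
        assert I.mesh_surface_area(m2) == pytest.approx(
            4.0 * I.mesh_surface_area(m1), rel=1e-6
        )
        d1 = I.depth_map(vol1.mask("TB"), vol1.mask("CoP"), vol1.spacing_mm)
        d2 = I.depth_map(vol2.mask("TB"), vol2.mask("CoP"), vol2.spacing_mm)
        np.testing.assert_allclose(
            d2.masked_values(), 2.0 * d1.masked_values(), rtol=1e-9
        )
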
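"""Phantom geometry, rasterization and activity assignment."""

from __future__ import annotations

import numpy as np
import pytest

from sirtiq import ActivitySetup, VoxelGrid, build_geometry, rasterize, realized_ratio
from sirtiq.phantom import (GeometryError, LABEL_BACKGROUND, LABEL_LUNG,
                            LABEL_OUTSIDE, LabelVolume, RasterizationError,
                            assign_activity, sphere_label)
from sirtiq.setups import TABLE_SETUPS, consistent_setups, get_setup


class TestBuildGeometry:
    def test_standard_defaults(self):
        g = build_geometry("standard")
        assert g.sphere_diameters_mm == (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
        assert g.obese_shell_thickness_mm == 0.0
        # coplanar ring centered on the lung insert axis
        ys = {c[1] for c in g.sphere_centers_mm}
        assert len(ys) == 1
        for cz, _, cx in g.sphere_centers_mm:
            assert np.hypot(cz, cx) == pytest.approx(57.2, abs=1e-9)

    def test_obese_adds_30mm_shell(self):
        assert build_geometry("obese").obese_shell_thickness_mm == 30.0

    def test_overrides_applied_and_validated(self):
        g = build_geometry("standard", {"body_length_mm": 200.0})
        assert g.body_length_mm == 200.0
        with pytest.raises(GeometryError):
            build_geometry("standard", {"body_length_mm": -1.0})
        # two coincident spheres overlap
        centers = tuple((0.0, 0.0, float(10 * i)) for i in range(6))
        with pytest.raises(GeometryError):
            build_geometry("standard", {"sphere_centers_mm": centers})

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_geometry("slim")


def _single_sphere_geometry():
    """Small phantom with the 37 mm sphere at the center, for fine grids."""
    centers = [(0.0, 0.0, 0.0)]
    for k in range(5):
        theta = np.deg2rad(72.0 * k)
        centers.append((30.0 * np.sin(theta), 0.0, 30.0 * np.cos(theta)))
    return build_geometry("standard", {
        "body_axes_mm": (55.0, 55.0), "body_length_mm": 60.0,
        "sphere_diameters_mm": (37.0, 4.0, 4.0, 4.0, 4.0, 4.0),
        "sphere_centers_mm": tuple(centers),
        "lung_insert_diameter_mm": 6.0, "lung_insert_length_mm": 60.0,
    })


class TestRasterize:
    def test_partition_and_label_set(self, geometry, grid, labels):
        assert set(np.unique(labels.labels)) <= set(range(10))
        counts = np.bincount(labels.labels.ravel(), minlength=10)
        assert counts.sum() == np.prod(grid.shape)

    @pytest.mark.parametrize("voxel_mm, tol_pct", [(1.0, 2.0), (0.5, 0.5)])
    def test_sphere_volume_converges(self, voxel_mm, tol_pct):
        g = _single_sphere_geometry()
        n = int(np.ceil(120.0 / voxel_mm))
        ny = int(np.ceil(64.0 / voxel_mm))
        grid = VoxelGrid.centered((n, ny, n), voxel_mm)
        lab = rasterize(g, grid)
        analytic = 4.0 / 3.0 * np.pi * 18.5**3  # 26 522 mm^3
        measured = lab.volume_mm3(sphere_label(0))
        assert abs(measured / analytic - 1.0) < tol_pct / 100.0

    def test_phantom_exceeding_grid_raises(self, geometry):
        small = VoxelGrid.centered((20, 20, 20), 2.4)
        with pytest.raises(RasterizationError, match="extent"):
            rasterize(geometry, small)

    def test_sphere_precedence_over_lung(self):
        # the 37 mm center sphere overlaps the lung insert axis: sphere wins
        g = _single_sphere_geometry()
        grid = VoxelGrid.centered((60, 40, 60), 2.0)
        lab = rasterize(g, grid)
        center_label = lab.labels[lab.grid.world_to_index((0.0, 0.0, 0.0))]
        assert center_label == sphere_label(0)


class TestAssignActivity:
    def test_spheres_only_background_zero(self, labels):
        setup = ActivitySetup(698.0, 0.0)
        act = assign_activity(labels, setup)
        bg = labels.labels == LABEL_BACKGROUND
        assert (act.concentration_kBq_per_ml[bg] == 0.0).all()
        assert (act.concentration_kBq_per_ml[labels.labels == LABEL_LUNG] == 0.0).all()
        assert (act.concentration_kBq_per_ml[labels.labels == LABEL_OUTSIDE] == 0.0).all()

    def test_uniform_filling(self, labels):
        act = assign_activity(labels, ActivitySetup(50.0, 50.0, 1.0))
        inside = (labels.labels == LABEL_BACKGROUND) | (
            (labels.labels >= 2) & (labels.labels <= 7))
        assert (act.concentration_kBq_per_ml[inside] == 50.0).all()

    def test_total_activity_hand_sum_on_toy_grid(self):
        grid = VoxelGrid.centered((1, 3, 1), 10.0)  # 1 ml voxels
        lab = LabelVolume(grid, np.array([[[0], [1], [2]]], dtype=np.uint8))
        act = assign_activity(lab, ActivitySetup(80.0, 10.0))
        # 0*1 + 10*1 + 80*1 kBq = 90 kBq = 0.09 MBq
        assert act.total_activity_MBq() == pytest.approx(0.09, rel=1e-12)

    def test_conservation_on_phantom(self, labels):
        setup = ActivitySetup(338.8, 39.6, 8.0)
        act = assign_activity(labels, setup)
        v_sphere = sum(labels.volume_ml(sphere_label(i)) for i in range(6))
        v_bg = labels.volume_ml(LABEL_BACKGROUND)
        expected = (338.8 * v_sphere + 39.6 * v_bg) / 1000.0
        assert act.total_activity_MBq() == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ActivitySetup(-1.0, 0.0)


class TestRealizedRatio:
    @pytest.mark.parametrize("c_s, c_bg, expected", [
        (719.2, 85.7, 8.39), (589.5, 74.4, 7.92), (386.6, 91.5, 4.23),
        (213.7, 52.4, 4.08), (338.8, 39.6, 8.56),
    ])
    def test_tabulated_pairs(self, c_s, c_bg, expected):
        assert realized_ratio(ActivitySetup(c_s, c_bg), ndigits=2) == expected

    def test_equal_concentrations_give_one(self):
        assert realized_ratio(ActivitySetup(123.4, 123.4), ndigits=2) == 1.0

    def test_zero_background_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            realized_ratio(ActivitySetup(698.0, 0.0))


class TestPackagedSetups:
    def test_inconsistent_row_is_flagged(self):
        rec = get_setup("tc99m", "8to1_repeat")
        assert not rec.consistent  # 419.6 / 44.6 = 9.41, tabulated 7.86
        assert rec not in consistent_setups()

    def test_all_other_rows_self_consistent(self):
        others = [r for r in TABLE_SETUPS if r.name != "8to1_repeat" or r.isotope != "tc99m"]
        assert all(r.consistent for r in others)
        for rec in others:
            if rec.tabulated_ratio is not None:
                assert realized_ratio(rec.setup, ndigits=2) == rec.tabulated_ratio
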
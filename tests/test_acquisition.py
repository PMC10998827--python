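"""Planar/SPECT simulation: count scaling, dead time, determinism, noise."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import sirtiq
from sirtiq import (ActivitySetup, ActivityVolume, ISOTOPES, VoxelGrid,
                    decay_correct, default_camera, matched_time, simulate_planar,
                    simulate_spect)
from sirtiq.acquisition import FWHM_TO_SIGMA, apply_correlated_noise
from sirtiq.metrics import cv_bg


def point_source(activity_MBq: float = 146.0) -> ActivityVolume:
    grid = VoxelGrid.centered((5, 5, 5), 2.4)
    conc = np.zeros(grid.shape)
    conc[2, 2, 2] = activity_MBq * 1000.0 / grid.voxel_volume_ml
    return ActivityVolume(grid, conc)


class TestMatchedTime:
    def test_projection_time_rule(self):
        # 20 s scaled by the Ho/Tc emission-probability ratio -> 1.5 s
        assert round(matched_time(20.0, 0.89, 0.067), 1) == 1.5

    def test_planar_time_rule(self):
        assert matched_time(300.0, 0.89, 0.067) == pytest.approx(22.58, abs=0.005)

    def test_identity(self):
        assert matched_time(17.0, 0.4, 0.4) == 17.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            matched_time(-1.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            matched_time(10.0, 0.0, 0.5)


class TestDecayCorrect:
    def test_one_half_life(self):
        assert decay_correct(100.0, ISOTOPES["tc99m"], 6.0) == pytest.approx(50.0)

    def test_zero_elapsed(self):
        assert decay_correct(42.0, ISOTOPES["ho166"], 0.0) == 42.0

    def test_two_half_lives(self):
        assert decay_correct(100.0, ISOTOPES["ho166"], 53.6) == pytest.approx(25.0)


class TestSimulatePlanar:
    def test_zero_activity_gives_empty_images(self):
        grid = VoxelGrid.centered((5, 5, 5), 2.4)
        act = ActivityVolume(grid, np.zeros(grid.shape))
        cam = default_camera("tc99m")
        pp, sw = simulate_planar(act, cam, ISOTOPES["tc99m"], seed=3)
        assert pp.counts.sum() == 0 and sw.counts.sum() == 0

    def test_point_source_count_scaling(self):
        # mean total counts ~ sensitivity x activity x duration (Poisson mean)
        act = point_source(146.0)
        cam = default_camera("tc99m", scatter_fraction=0.0, uniform_haze_fraction=0.0)
        totals = [simulate_planar(act, cam, ISOTOPES["tc99m"], "anterior", 300.0,
                                  seed=s)[0].counts.sum() for s in range(20)]
        target = 93.1 * 146.0 * 300.0  # 4 077 780
        se = math.sqrt(target / len(totals))
        assert abs(np.mean(totals) - target) < 3 * se

    def test_dead_time_factor_closed_form(self):
        # one-voxel source, no scatter: expected total = E * exp(-tau * E / T)
        act = point_source(100.0)
        iso = ISOTOPES["tc99m"]
        tau = 5e-6
        cam0 = default_camera("tc99m", scatter_fraction=0.0, uniform_haze_fraction=0.0)
        cam = default_camera("tc99m", scatter_fraction=0.0, uniform_haze_fraction=0.0,
                             dead_time_tau_s=tau)
        pp0, _ = simulate_planar(act, cam0, iso, "anterior", 300.0, seed=None,
                                 sample_noise=False)
        pp, _ = simulate_planar(act, cam, iso, "anterior", 300.0, seed=None,
                                sample_noise=False)
        expected_rate = pp0.counts.sum() / 300.0
        assert pp.counts.sum() == pytest.approx(
            pp0.counts.sum() * math.exp(-tau * expected_rate), rel=1e-12)

    def test_reproducibility_bit_identical(self, ho_8to1, labels):
        _, act = ho_8to1
        cam = default_camera("ho166")
        a = simulate_planar(act, cam, ISOTOPES["ho166"], seed=7, labels=labels)
        b = simulate_planar(act, cam, ISOTOPES["ho166"], seed=7, labels=labels)
        c = simulate_planar(act, cam, ISOTOPES["ho166"], seed=8, labels=labels)
        assert (a[0].counts == b[0].counts).all() and (a[1].counts == b[1].counts).all()
        assert (a[0].counts != c[0].counts).any()

    def test_attenuation_reduces_counts(self, ho_8to1, labels):
        _, act = ho_8to1
        cam = default_camera("ho166")
        iso = ISOTOPES["ho166"]
        free, _ = simulate_planar(act, cam, iso, seed=None, sample_noise=False)
        att, _ = simulate_planar(act, cam, iso, seed=None, sample_noise=False,
                                 labels=labels)
        assert att.counts.sum() < 0.6 * free.counts.sum()

    def test_missing_seed_rejected_when_sampling(self):
        act = point_source()
        with pytest.raises(ValueError, match="seed"):
            simulate_planar(act, default_camera("tc99m"), ISOTOPES["tc99m"], seed=None)


class TestSimulateSpect:
    def test_noiseless_equals_double_filtered_activity(self, tc_8to1):
        _, act = tc_8to1
        cam = default_camera("tc99m", residual_scatter_fraction=0.0)
        vol = simulate_spect(act, cam, ISOTOPES["tc99m"], seed=None, sample_noise=False)
        vox = np.asarray(act.grid.voxel_size_mm)
        ref = gaussian_filter(act.concentration_kBq_per_ml.astype(float),
                              cam.system_fwhm_mm * FWHM_TO_SIGMA / vox, mode="constant")
        ref = gaussian_filter(ref, 9.0 * FWHM_TO_SIGMA / vox, mode="constant")
        np.testing.assert_allclose(vol.values, ref, rtol=0, atol=1e-12)

    def test_blur_tails_decrease_away_from_sphere(self, labels, geometry):
        # spheres-only: background receives only monotone blur tails
        act = sirtiq.assign_activity(labels, ActivitySetup(698.0, 0.0))
        cam = default_camera("tc99m", residual_scatter_fraction=0.0)
        vol = simulate_spect(act, cam, ISOTOPES["tc99m"], seed=None, sample_noise=False)
        cz, cy, cx = geometry.sphere_centers_mm[5]  # 37 mm sphere
        radii = np.arange(22.0, 50.0, 4.0)
        vals = [vol.values[vol.grid.world_to_index((cz, cy + r, cx))] for r in radii]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_cv_scales_inverse_sqrt_time(self, tc_8to1, geometry):
        rec, act = tc_8to1
        cam = default_camera("tc99m")
        iso = ISOTOPES["tc99m"]
        cvs = {}
        for t in (10.0, 20.0):
            vals = []
            for seed in range(5):
                vol = simulate_spect(act, cam, iso, t, 120, seed=100 + seed)
                vals.append(sirtiq.analyze_volume(vol, geometry, rec.setup).cv_bg_percent)
            cvs[t] = np.median(vals)
        assert cvs[20.0] / cvs[10.0] == pytest.approx(1.0 / math.sqrt(2.0), rel=0.15)

    def test_reproducibility(self, tc_8to1):
        _, act = tc_8to1
        cam = default_camera("tc99m")
        a = simulate_spect(act, cam, ISOTOPES["tc99m"], seed=5)
        b = simulate_spect(act, cam, ISOTOPES["tc99m"], seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestCorrelatedNoise:
    def test_zero_sigma_is_identity(self):
        rng = np.random.default_rng(0)
        vals = np.full((10, 10, 10), 5.0)
        out = apply_correlated_noise(vals, 0.0, rng, 1.5)
        np.testing.assert_array_equal(out, vals)

    def test_relative_sd_at_reference_level(self):
        rng = np.random.default_rng(1)
        vals = np.full((40, 40, 40), 10.0)
        out = apply_correlated_noise(vals, 0.08, rng, 0.0, ref_level=10.0)
        assert cv_bg(out) == pytest.approx(8.0, rel=0.05)

    def test_poisson_weighting_quiets_hot_voxels(self):
        rng = np.random.default_rng(2)
        lo = np.full((30, 30, 30), 10.0)
        hi = np.full((30, 30, 30), 90.0)
        out_lo = apply_correlated_noise(lo, 0.1, rng, 0.0, ref_level=10.0)
        out_hi = apply_correlated_noise(hi, 0.1, np.random.default_rng(2), 0.0,
                                        ref_level=10.0)
        assert cv_bg(out_hi) < 0.5 * cv_bg(out_lo)
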
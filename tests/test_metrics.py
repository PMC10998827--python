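"""Image-quality metric arithmetic, invariances, and the evaluate pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sirtiq
from sirtiq import SpectVolume, analyze_volume
from sirtiq.metrics import (apparent_lung_shunt, cnr, conjugate_view_counts, crc,
                            cv_bg, evaluate, lung_count_error)
from sirtiq.segmentation import build_sphere_masks, place_standard_vois


class TestCrc:
    @pytest.mark.parametrize("mean_s, mean_bg, ratio, expected", [
        (80.0, 10.0, 8.0, 100.0),      # perfect recovery
        (10.0, 10.0, 8.0, 0.0),        # no contrast
        (62.0, 10.0, 8.0, 100 * (6.2 - 1) / 7),  # 74.2857...
    ])
    def test_values(self, mean_s, mean_bg, ratio, expected):
        assert crc(mean_s, mean_bg, ratio) == pytest.approx(expected, rel=1e-12)

    def test_ratio_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            crc(10.0, 5.0, 1.0)


class TestLungError:
    @pytest.mark.parametrize("lung, bg, expected", [
        (0.0, 7.0, 0.0), (7.0, 7.0, 100.0), (3.0, 10.0, 30.0)])
    def test_values(self, lung, bg, expected):
        assert lung_count_error(lung, bg) == expected

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            lung_count_error(1.0, 0.0)


class TestCvBg:
    def test_population_sd_example(self):
        # population SD sqrt(8/3) over mean 10 -> 16.3299...%
        assert cv_bg(np.array([8.0, 10.0, 12.0])) == pytest.approx(16.3299, abs=1e-3)

    def test_constant_collection_is_zero(self):
        assert cv_bg(np.full(100, 4.2)) == 0.0

    @given(st.floats(min_value=1e-3, max_value=1e4))
    def test_scale_invariance(self, c):
        vals = np.array([1.0, 2.0, 3.5, 0.5])
        assert cv_bg(vals * c) == pytest.approx(cv_bg(vals), rel=1e-9)


class TestCnr:
    def test_examples(self):
        assert cnr(10.0, 10.0, 2.0) == 0.0
        assert cnr(62.0, 10.0, 2.0) == 26.0
        assert cnr(4.0, 10.0, 2.0) == -3.0  # cold sphere, sign preserved

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            cnr(10.0, 5.0, 0.0)


class TestApparentLungShunt:
    @pytest.mark.parametrize("lung, liver, expected", [
        (0.0, 100.0, 0.0), (13.0, 87.0, 13.0), (5.0, 5.0, 50.0)])
    def test_values(self, lung, liver, expected):
        assert apparent_lung_shunt(lung, liver) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            apparent_lung_shunt(0.0, 0.0)

    def test_conjugate_views_geometric_mean(self):
        assert conjugate_view_counts([4.0, 9.0]) == pytest.approx(6.0)
        assert conjugate_view_counts([5.0]) == 5.0


class TestEvaluate:
    def test_ideal_volume_perfect_metrics(self, ideal_volume, geometry, ho_8to1):
        rec, _ = ho_8to1
        result = analyze_volume(ideal_volume, geometry, rec.setup)
        for sphere in result.per_sphere.values():
            assert sphere.evaluable
            assert sphere.crc_percent == pytest.approx(100.0, abs=1.0)
        assert result.cv_bg_percent == pytest.approx(0.0, abs=1e-9)
        assert result.lung_error_percent == 0.0

    def test_scale_invariance_and_offset_behavior(self, tc_volume, geometry, tc_8to1):
        rec, _ = tc_8to1
        base = analyze_volume(tc_volume, geometry, rec.setup)
        scaled = SpectVolume(tc_volume.grid, tc_volume.values * 3.25)
        res_s = analyze_volume(scaled, geometry, rec.setup)
        assert res_s.cv_bg_percent == pytest.approx(base.cv_bg_percent, rel=1e-9)
        assert res_s.lung_error_percent == pytest.approx(base.lung_error_percent, rel=1e-9)
        for d in base.per_sphere:
            if base.per_sphere[d].evaluable:
                assert res_s.per_sphere[d].crc_percent == pytest.approx(
                    base.per_sphere[d].crc_percent, rel=1e-9)
                assert res_s.per_sphere[d].cnr == pytest.approx(
                    base.per_sphere[d].cnr, rel=1e-9)
        # adding a constant: CNR untouched (same difference, same SD), CRC moves
        offset = SpectVolume(tc_volume.grid, tc_volume.values + 7.0)
        res_o = analyze_volume(offset, geometry, rec.setup)
        d = 37.0
        assert res_o.per_sphere[d].cnr == pytest.approx(
            base.per_sphere[d].cnr, rel=1e-6)
        assert res_o.per_sphere[d].crc_percent < base.per_sphere[d].crc_percent

    def test_crc_matches_independent_mask_sums(self, tc_volume, geometry, tc_8to1):
        # oracle: recompute VOI means by direct mask-weighted sums
        rec, _ = tc_8to1
        vois = place_standard_vois(geometry, tc_volume.grid)
        build_sphere_masks(tc_volume, geometry, vois)
        result = evaluate(tc_volume, vois, rec.setup)
        pooled = np.zeros(tc_volume.grid.shape, dtype=bool)
        for m in vois.background_masks:
            pooled |= m
        mean_bg = tc_volume.values[pooled].sum() / pooled.sum()
        ratio = rec.setup.c_spheres_kBq_per_ml / rec.setup.c_background_kBq_per_ml
        for d, mask in vois.sphere_masks.items():
            if mask is None:
                continue
            mean_s = tc_volume.values[mask].sum() / mask.sum()
            expected = 100.0 * ((mean_s / mean_bg) - 1.0) / (ratio - 1.0)
            assert result.per_sphere[d].crc_percent == pytest.approx(expected, rel=1e-12)

    def test_spheres_only_setup_has_no_crc(self, labels, geometry):
        rec = sirtiq.get_setup("tc99m", "spheres_only")
        act = sirtiq.assign_activity(labels, rec.setup)
        cam = sirtiq.default_camera("tc99m")
        vol = sirtiq.simulate_spect(act, cam, sirtiq.ISOTOPES["tc99m"], seed=4)
        result = analyze_volume(vol, geometry, rec.setup)
        assert all(s.crc_percent is None for s in result.per_sphere.values())

    def test_crc_more_stable_than_cnr_across_seeds(self, tc_8to1, geometry):
        # contrast is count-statistics-stable; noise-driven CNR is not
        rec, act = tc_8to1
        cam = sirtiq.default_camera("tc99m")
        iso = sirtiq.ISOTOPES["tc99m"]
        crcs, cnrs = [], []
        for seed in range(8):
            vol = sirtiq.simulate_spect(act, cam, iso, 20.0, 120, seed=300 + seed)
            res = analyze_volume(vol, geometry, rec.setup)
            crcs.append(res.per_sphere[37.0].crc_percent)
            cnrs.append(res.per_sphere[37.0].cnr)
        rel_spread = lambda v: np.std(v) / np.mean(v)  # noqa: E731
        assert rel_spread(crcs) < rel_spread(cnrs)
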
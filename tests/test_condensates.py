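"""Condensate aggregation, detection, shell profiles and timecourses."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from nucleomech import synthetic
from nucleomech.condensates import (aggregation_timecourse, count_condensates,
                                    detect_condensates, relative_aggregation,
                                    shell_masks_iterated_erosion, shell_profile,
                                    signed_boundary_distance,
                                    subtract_background)
from nucleomech.containers import CondensateScene

from conftest import random_blob_mask


def uniform_scene(radius_px=60, value=100.0, size=151, pixel_size=0.1):
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    nuc = np.hypot(yy - c, xx - c) <= radius_px
    img = np.where(nuc, value, 0.0)
    return CondensateScene(intensity=img, nucleus_mask=nuc,
                           condensate_mask=np.zeros_like(nuc),
                           pixel_size=pixel_size)


class TestBackground:
    def test_zero_background_unchanged(self):
        sc = uniform_scene()
        out = subtract_background(sc, method="provided", value=0.0)
        assert np.array_equal(out.intensity, sc.intensity)

    def test_generator_offset_removed(self):
        ds = synthetic.gen_condensate_image(aggregate_fraction=0.25,
                                            camera_offset=100.0, seed=3)
        out = subtract_background(ds.payload,
                                  method="outside_nucleus_percentile")
        assert out.background_value == pytest.approx(100.0, rel=0.01)

    def test_clipping_never_negative(self):
        sc = uniform_scene(value=50.0)
        out = subtract_background(sc, method="provided", value=80.0)
        assert out.intensity.min() == 0.0

    def test_full_frame_nucleus_needs_value(self):
        img = np.full((8, 8), 10.0)
        sc = CondensateScene(intensity=img, nucleus_mask=np.ones((8, 8), bool),
                             condensate_mask=np.zeros((8, 8), bool),
                             pixel_size=0.1)
        with pytest.raises(ValueError):
            subtract_background(sc, method="outside_nucleus_percentile")


class TestDetection:
    def test_spotless_image_zero_count(self):
        ds = synthetic.gen_condensate_image(aggregate_fraction=0.0, seed=2)
        det = detect_condensates(ds.payload)
        assert count_condensates(det)[0] == 0

    def test_well_separated_spots_counted_with_centroids(self):
        ds = synthetic.gen_condensate_image(n_spots=5, aggregate_fraction=0.3,
                                            min_separation_sigma=12, seed=8)
        det = detect_condensates(ds.payload)
        n, _ = count_condensates(det)
        assert n == 5
        labels, _ = ndimage.label(det.condensate_mask)
        cents = ndimage.center_of_mass(det.condensate_mask, labels,
                                       range(1, n + 1))
        half = (det.intensity.shape[0] - 1) // 2
        px = ds.truth.params["pixel_size"]
        truth = [(half + dy / px, half + dx / px)
                 for dy, dx in ds.truth.extras["spot_centres_um"]]
        for cy, cx in cents:
            assert min(np.hypot(cy - ty, cx - tx) for ty, tx in truth) < 1.0

    def test_merged_spots_counted_once(self):
        # two spots closer than the detection footprint fuse into one blob
        ds = synthetic.gen_condensate_image(n_spots=2, aggregate_fraction=0.3,
                                            min_separation_sigma=3.0, seed=4)
        det = detect_condensates(ds.payload)
        labels, n = ndimage.label(det.condensate_mask)
        # oracle: connected components of the thresholded image itself
        assert count_condensates(det)[0] == n
        assert n <= 2

    def test_empty_nucleus_rejected(self):
        sc = uniform_scene()
        bad = replace(sc, nucleus_mask=np.zeros_like(sc.nucleus_mask))
        with pytest.raises(ValueError):
            detect_condensates(bad)


class TestRelativeAggregation:
    def test_condensate_equals_nucleus_gives_one(self):
        sc = uniform_scene()
        sc = replace(sc, condensate_mask=sc.nucleus_mask.copy())
        assert relative_aggregation(sc).relative_aggregation == 1.0

    def test_empty_condensate_gives_zero(self):
        assert relative_aggregation(uniform_scene()).relative_aggregation == 0.0

    @pytest.mark.parametrize("frac", [0.1, 0.25, 0.4, 0.5])
    def test_true_mask_recovery(self, frac):
        ds = synthetic.gen_condensate_image(aggregate_fraction=frac, seed=21)
        res = relative_aggregation(ds.payload)
        assert res.relative_aggregation == pytest.approx(frac, rel=0.10)

    def test_detector_mask_recovery_high_contrast(self):
        for frac in (0.1, 0.25, 0.5):
            ds = synthetic.gen_condensate_image(aggregate_fraction=frac,
                                                n_spots=4,
                                                min_separation_sigma=12,
                                                seed=31)
            det = detect_condensates(ds.payload, min_contrast=1.0)
            r = relative_aggregation(det).relative_aggregation
            assert r == pytest.approx(frac, rel=0.10)

    def test_intensity_scale_invariance(self):
        ds = synthetic.gen_condensate_image(aggregate_fraction=0.3, seed=9)
        sc = ds.payload
        r1 = relative_aggregation(sc).relative_aggregation
        r2 = relative_aggregation(
            replace(sc, intensity=sc.intensity * 7.3)).relative_aggregation
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_nesting_monotonicity(self):
        ds = synthetic.gen_condensate_image(aggregate_fraction=0.3, seed=10)
        sc = ds.payload
        grown = ndimage.binary_dilation(sc.condensate_mask, iterations=3)
        r_small = relative_aggregation(sc).relative_aggregation
        r_big = relative_aggregation(
            replace(sc, condensate_mask=grown)).relative_aggregation
        assert r_big >= r_small

    def test_mask_outside_nucleus_clipped_and_flagged(self):
        sc = uniform_scene()
        cm = np.zeros_like(sc.nucleus_mask)
        cm[0:5, 0:5] = True          # entirely outside the nucleus
        clipped = CondensateScene(intensity=sc.intensity,
                                  nucleus_mask=sc.nucleus_mask,
                                  condensate_mask=cm, pixel_size=0.1)
        assert not clipped.condensate_mask.any()
        assert "condensate_mask_clipped_to_nucleus" in clipped.flags


class TestShellProfile:
    def test_uniform_interior_ratios_one(self):
        sc = uniform_scene(radius_px=60)
        prof = shell_profile(sc, dilation=0.0)
        assert np.allclose(prof.shells.ratio, 1.0, atol=0.01)

    def test_peripheral_rim_concentrates_signal(self):
        sc = uniform_scene(radius_px=60, value=0.0)
        sd = signed_boundary_distance(sc.nucleus_mask, sc.pixel_size)
        rim = (sd > -0.15) & (sd <= 0.0)
        img = np.where(rim, 1000.0, 0.0)
        sc = replace(sc, intensity=img)
        prof = shell_profile(sc, dilation=0.4).shells.set_index("shell_index")
        # rim sits in the first band inside the boundary: index 4 when
        # dilation=0.4 and thickness=0.15 (bands 1-2 outside, 3 straddles)
        assert prof.loc[4, "ratio"] > 5.0
        inner = prof.loc[prof.index >= 8, "ratio"]
        assert np.all(inner < 0.05)

    def test_pixel_size_thicker_than_shell_rejected(self):
        sc = uniform_scene(pixel_size=0.2)
        with pytest.raises(ValueError):
            shell_profile(sc, shell_thickness=0.15)

    def test_small_nucleus_truncated_profile(self):
        sc = uniform_scene(radius_px=10)   # 1 µm radius, 20 shells won't fit
        prof = shell_profile(sc, n_shells=20)
        assert prof.truncated

    def test_shells_disjoint_and_nested_on_random_blobs(self):
        """Pixel audit: every pixel in at most one band, bands inside the
        dilated nucleus, areas conserved."""
        for seed in range(25):
            mask = random_blob_mask(seed)
            sc = CondensateScene(intensity=np.ones_like(mask, float),
                                 nucleus_mask=mask,
                                 condensate_mask=np.zeros_like(mask),
                                 pixel_size=0.1)
            sd = signed_boundary_distance(mask, 0.1)
            prof = shell_profile(sc, dilation=0.4, n_shells=20)
            counts = np.zeros_like(mask, dtype=int)
            total = 0
            for i, area in zip(prof.shells.shell_index, prof.shells.area_px):
                hi = 0.4 - (i - 1) * 0.15
                lo = 0.4 - i * 0.15
                band = (sd > lo) & (sd <= hi)
                counts += band
                total += area
                assert band.sum() == area
            assert counts.max() <= 1
            dilated = sd <= 0.4
            assert total <= dilated.sum()
            assert not (counts.astype(bool) & ~dilated).any()

    def test_iterated_erosion_cross_check(self):
        """Distance-transform bands match the literal dilate/erode shells.

        Compared at a calibration where the physical steps are whole pixels
        (0.05 µm px: 0.15 µm = 3 px, 0.4 µm = 8 px) so the two
        constructions quantize identically.
        """
        mask = random_blob_mask(3, pixel_size=0.05)
        shells = shell_masks_iterated_erosion(mask, 0.05, dilation=0.4,
                                              n_shells=20)
        stack = np.array(shells)
        assert stack.sum(axis=0).max() <= 1
        sd = signed_boundary_distance(mask, 0.05)
        band_union = stack.any(axis=0)
        dist_union = (sd > 0.4 - 20 * 0.15) & (sd <= 0.4)
        inter = (band_union & dist_union).sum()
        union = (band_union | dist_union).sum()
        assert inter / union > 0.9


class TestTimecourse:
    def test_static_scene_constant_series(self):
        sc = synthetic.gen_condensate_image(aggregate_fraction=0.3,
                                            seed=5).payload
        tc = aggregation_timecourse([sc] * 4)
        assert tc.rel_aggregation.nunique() == 1

    def test_fraction_ramp_monotone(self):
        scenes = [synthetic.gen_condensate_image(aggregate_fraction=f,
                                                 seed=40 + i).payload
                  for i, f in enumerate(np.linspace(0.1, 0.5, 7))]
        tc = aggregation_timecourse(scenes)
        assert np.all(np.diff(tc.rel_aggregation) > 0)

    def test_histogram_matching_flattens_bleach(self):
        """Bleach decays the signal over a constant camera offset; matching
        to frame 0 restores a flat aggregation series."""
        base = synthetic.gen_condensate_image(aggregate_fraction=0.3,
                                              camera_offset=50.0,
                                              seed=50).payload
        scenes = []
        for t in range(8):
            decayed = (base.intensity - 50.0) * np.exp(-0.08 * t) + 50.0
            scenes.append(replace(base, intensity=decayed))
        raw = aggregation_timecourse(scenes, bleach="none")
        fixed = aggregation_timecourse(scenes, bleach="histogram_matching")
        drift_raw = abs(raw.rel_aggregation.iloc[-1]
                        / raw.rel_aggregation.iloc[0] - 1)
        drift_fix = abs(fixed.rel_aggregation.iloc[-1]
                        / fixed.rel_aggregation.iloc[0] - 1)
        assert drift_raw > 0.10          # bleach visibly corrupts the series
        assert drift_fix < 0.05          # matching restores it
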
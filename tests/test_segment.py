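"""Segmentation: contrast, diffusion, histogram thresholds, region growing,
label cleanup and the two full chains."""

import numpy as np
import pytest
from scipy import ndimage

from biofilmct import (DiffusionSettings, ThresholdSet, VolumeImage,
                       clean_labels, compute_histogram, curvature_diffusion,
                       enhance_contrast, find_thresholds,
                       seeded_region_growing, segment_volume)
from biofilmct.core import (AIR, BIOFILM, LIQUID, OUTSIDE, SOLID, LabelVolume,
                            column_mask)


def vol(values, spacing=(1.0, 1.0, 1.0)):
    return VolumeImage(np.asarray(values, dtype=float), spacing)


class TestEnhanceContrast:
    def test_saturated_fraction_matches_request(self):
        rng = np.random.default_rng(0)
        v = vol(rng.normal(100, 20, (40, 40, 40)))
        out = enhance_contrast(v, 0.004)
        sat = np.mean((out.values == 0.0) | (out.values == 255.0))
        assert 0.004 <= sat <= 0.006

    def test_constant_input_flagged(self):
        out = enhance_contrast(vol(np.full((8, 8, 8), 3.0)), 0.004)
        assert np.unique(out.values).size == 1
        assert "degenerate" in out.metadata["enhance_contrast"]

    def test_rank_order_preserved_for_unclipped(self):
        rng = np.random.default_rng(1)
        v = vol(rng.uniform(0, 1, (20, 20, 20)))
        out = enhance_contrast(v, 0.01)
        inner = (out.values > 0) & (out.values < 255)
        a, b = v.values[inner].ravel(), out.values[inner].ravel()
        order = np.argsort(a)
        assert np.all(np.diff(b[order]) >= 0)


class TestCurvatureDiffusion:
    def test_uniform_volume_unchanged(self):
        v = vol(np.full((16, 16, 16), 5.0))
        out = curvature_diffusion(v)
        assert np.allclose(out.values, 5.0)

    def test_zero_iterations_is_identity(self):
        rng = np.random.default_rng(2)
        v = vol(rng.normal(0, 1, (12, 12, 12)))
        out = curvature_diffusion(v, DiffusionSettings(iterations=0))
        assert np.array_equal(out.values, v.values)

    def test_noisy_step_smoothed_without_edge_shift(self):
        rng = np.random.default_rng(3)
        base = np.zeros((32, 32, 32))
        base[:, :, 16:] = 100.0
        noisy = base + rng.normal(0, 10, base.shape)
        out = curvature_diffusion(vol(noisy))
        flat = (slice(None), slice(None), slice(0, 12))
        assert noisy[flat].var() / out.values[flat].var() >= 2.0
        profile = out.values.mean(axis=(0, 1))
        crossing = int(np.argmax(profile >= 50.0))
        assert abs(crossing - 16) <= 1

    def test_discrete_max_principle(self):
        rng = np.random.default_rng(4)
        v = vol(rng.normal(50, 20, (16, 16, 16)))
        out = curvature_diffusion(v)
        assert out.values.min() >= v.values.min() - 1e-6
        assert out.values.max() <= v.values.max() + 1e-6

    def test_unstable_time_step_rejected(self):
        with pytest.raises(ValueError, match="time_step"):
            DiffusionSettings(time_step=0.5)


class TestHistogram:
    def test_counts_sum_to_mask_size(self):
        rng = np.random.default_rng(5)
        v = vol(rng.uniform(0, 255, (24, 24, 24)))
        mask = column_mask(v.shape)
        h = compute_histogram(v, mask)
        assert h.counts.sum() == mask.sum()

    def test_two_delta_volume_two_bins(self):
        vals = np.full((16, 16, 16), 50.0)
        vals[:8] = 200.0
        h = compute_histogram(vol(vals), np.ones(vals.shape, bool))
        assert np.count_nonzero(h.counts) == 2
        assert h.counts[50] + h.counts[200] == vals.size

    def test_trimodal_mixture_modes_recovered(self):
        rng = np.random.default_rng(6)
        parts = [rng.normal(60, 6, 40000), rng.normal(140, 8, 30000),
                 rng.normal(210, 6, 30000)]
        vals = np.clip(np.concatenate(parts), 0, 255)[:97336]
        v = vol(vals.reshape(46, 46, 46))
        h = compute_histogram(v, np.ones(v.shape, bool))
        assert len(h.peak_modes) == 3
        for mode, mean in zip(h.peak_modes, (60, 140, 210)):
            assert abs(mode - mean) <= 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            compute_histogram(vol(np.zeros((4, 4, 4))),
                              np.zeros((4, 4, 4), bool))


def shoulder_mixture_density(x):
    """Closed-form liquid-peak + biofilm-shoulder + solid-peak mixture."""
    def g(x, m, s):
        return np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    return 0.55 * g(x, 60, 8) + 0.2 * g(x, 88, 11) + 0.25 * g(x, 200, 9)


class TestFindThresholds:
    def test_printed_sensitivity_triplet(self):
        ts = ThresholdSet.from_center(73, 0.12)
        assert (ts.low, ts.center, ts.high) == (64, 73, 82)

    def test_center_matches_analytic_inflection_midpoint(self):
        # frozen oracle: inflection pair of the closed-form mixture density
        # between the liquid mode and the shoulder, computed by dense
        # evaluation of its second derivative
        xs = np.arange(0, 256, 0.01)
        d2 = np.gradient(np.gradient(shoulder_mixture_density(xs)))
        lo = int(60 / 0.01)
        c1 = xs[lo + np.argmax(d2[lo:] >= 0)]
        c2_i = lo + int(np.argmax(d2[lo:] >= 0))
        c2 = xs[c2_i + np.argmax(d2[c2_i:] < 0)]
        oracle_center = 0.5 * (c1 + c2)

        rng = np.random.default_rng(7)
        n = 200000
        comp = rng.choice(3, n, p=[0.55, 0.2, 0.25])
        vals = np.where(comp == 0, rng.normal(60, 8, n),
                        np.where(comp == 1, rng.normal(88, 11, n),
                                 rng.normal(200, 9, n)))
        vals = np.clip(vals, 0, 255)[:195112].reshape(58, 58, 58)
        h = compute_histogram(vol(vals), np.ones(vals.shape, bool))
        ts = find_thresholds(h)
        assert not ts.fallback_used
        assert abs(ts.center - oracle_center) <= 2

    def test_separated_bimodal_uses_valley_fallback(self):
        vals = np.concatenate([np.full(5000, 50.0), np.full(5000, 200.0)])
        v = vol(vals.reshape(10, 10, 100))
        h = compute_histogram(v, np.ones(v.shape, bool))
        ts = find_thresholds(h)
        assert ts.fallback_used
        assert 55 < ts.center < 195

    def test_unimodal_rejected(self):
        rng = np.random.default_rng(8)
        v = vol(np.clip(rng.normal(128, 5, (16, 16, 16)), 0, 255))
        h = compute_histogram(v, np.ones(v.shape, bool))
        with pytest.raises(ValueError, match="unimodal"):
            find_thresholds(h)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="low < center < high"):
            ThresholdSet(center=10, low=12, high=14)


class TestSeededRegionGrowing:
    def test_uniform_region_fully_captured(self):
        v = np.full((24, 24, 24), 200.0)
        v[8:16, 8:16, 8:16] = 100.0
        region = seeded_region_growing(v, [(12, 12, 12)], tolerance=5.0)
        expected = v == 100.0
        assert np.array_equal(region, expected)

    def test_cupping_ramp_tracked_without_leak(self):
        n = 48
        zz, yy, xx = np.mgrid[:n, :n, :n]
        r = np.sqrt((zz - 23.5) ** 2 + (yy - 23.5) ** 2 + (xx - 23.5) ** 2)
        solid = r <= 18
        v = np.full((n, n, n), 200.0)
        v[solid] = 95.0 + 10.0 * (r[solid] / 18.0)  # radial drift < tolerance
        region = seeded_region_growing(v, [(24, 24, 24)], tolerance=15.0)
        assert (region & solid).sum() / solid.sum() >= 0.99
        assert not (region & ~solid).any()

    def test_zero_tolerance_stays_within_true_region(self):
        rng = np.random.default_rng(9)
        v = np.full((16, 16, 16), 100.0)
        v[4:12, 4:12, 4:12] = 50.0 + rng.normal(0, 1, (8, 8, 8))
        v[8, 8, 8] = 50.0
        region = seeded_region_growing(v, [(8, 8, 8)], tolerance=0.0)
        assert region[8, 8, 8]
        assert not (region & (v == 100.0)).any()

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            seeded_region_growing(np.zeros((4, 4, 4)), [], 1.0)


class TestCleanLabels:
    def _base(self):
        codes = np.full((9, 9, 9), LIQUID, dtype=np.uint8)
        codes[:, :2, :] = SOLID
        return LabelVolume(codes, (1, 1, 1))

    def test_clean_input_unchanged(self):
        lab = self._base()
        out = clean_labels(lab, closing_radius=0, min_component_vox=5)
        assert np.array_equal(out.codes, lab.codes)

    def test_isolated_biofilm_voxel_merged_into_liquid(self):
        lab = self._base()
        lab.codes[5, 5, 5] = BIOFILM
        out = clean_labels(lab, closing_radius=0, min_component_vox=5)
        assert out.codes[5, 5, 5] == LIQUID

    def test_air_always_merged_into_liquid(self):
        lab = self._base()
        lab.codes[4:7, 4:7, 4:7] = AIR
        out = clean_labels(lab)
        assert not (out.codes == AIR).any()
        assert np.all(out.codes[4:7, 4:7, 4:7] == LIQUID)

    def test_idempotent(self, biofilm_labels):
        once = clean_labels(biofilm_labels)
        twice = clean_labels(once)
        assert np.array_equal(once.codes, twice.codes)


def trimodal_volume(seed=10, n=48):
    """Synthetic preprocessed gray volume: liquid 60, biofilm patches 115,
    solid balls 190, mild noise; gray values in 8-bit range."""
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.mgrid[:n, :n, :n]
    mask = column_mask((n, n, n))
    v = np.zeros((n, n, n))
    codes = np.full((n, n, n), OUTSIDE, dtype=np.uint8)
    codes[mask] = LIQUID
    v[mask] = 60.0
    for _ in range(10):
        c = rng.uniform(10, n - 10, 3)
        r = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        ball = (r <= rng.uniform(6, 9)) & mask
        codes[ball] = SOLID
        v[ball] = 190.0
        shell = (r <= rng.uniform(8, 11)) & mask & (codes == LIQUID) \
            & (rng.random() < 0.8)
        codes[shell] = BIOFILM
        v[shell] = 115.0
    v += rng.normal(0, 4, v.shape)
    v[~mask] = 0.0
    return VolumeImage(np.clip(v, 0, 255), (1, 1, 1)), codes, mask


class TestSegmentVolume:
    def test_feso4_recovers_fractions(self):
        v, truth, mask = trimodal_volume()
        labels = segment_volume(v, "feso4",
                                ThresholdSet.from_center(88, 0.12),
                                mask=mask)
        n = mask.sum()
        for code in (SOLID, LIQUID, BIOFILM):
            got = (labels.codes == code).sum() / n
            want = (truth == code).sum() / n
            assert abs(got - want) <= 0.03

    def test_output_label_set_is_valid(self):
        v, _, mask = trimodal_volume(seed=11)
        labels = segment_volume(v, "feso4", mask=mask)
        assert set(np.unique(labels.codes)) <= {OUTSIDE, SOLID, LIQUID,
                                                BIOFILM}

    def test_threshold_band_gives_nested_biofilm_masks(self):
        # lower threshold -> more biofilm; nesting is exact before
        # component-level cleanup
        v, _, mask = trimodal_volume(seed=12)
        no_clean = {"closing_radius": 0, "min_component_vox": 0}
        masks = {}
        for name, thr in (("low", 78), ("center", 88), ("high", 98)):
            lab = segment_volume(v, "feso4",
                                 ThresholdSet(thr, thr - 1, thr + 1),
                                 solid_params={"threshold": 160},
                                 cleanup=no_clean, mask=mask)
            masks[name] = lab.codes == BIOFILM
        assert np.all(masks["high"] <= masks["center"])
        assert np.all(masks["center"] <= masks["low"])

    def test_unknown_mode_rejected(self):
        v, _, mask = trimodal_volume(seed=13)
        with pytest.raises(ValueError, match="mode"):
            segment_volume(v, "xenon", mask=mask)
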
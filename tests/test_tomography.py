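"""Projection simulation and filtered back-projection."""

import numpy as np
import pytest

from biofilmct import (ProjectionSet, ScanGeometry, VolumeImage, add_noise,
                       apply_beam_hardening, apply_phase_contrast,
                       count_projections, fbp_reconstruct, forward_project,
                       to_line_integrals)
from conftest import disk_volume


def geometry(n=64, nz=1, step=1.0, rng=180.0, inclusive=False):
    return ScanGeometry(angle_step_deg=step, angular_range_deg=rng,
                        endpoint_inclusive=inclusive, detector_width_px=n,
                        detector_height_px=nz, effective_pixel_um=1.0)


@pytest.mark.parametrize("step,rng,inclusive,expected", [
    (0.25, 360.0, True, 1441),
    (1.0, 180.0, False, 180),
    (0.7, 360.0, True, 515),
])
def test_count_projections(step, rng, inclusive, expected):
    assert count_projections(step, rng, inclusive) == expected


def test_count_projections_rejects_bad_step():
    with pytest.raises(ValueError):
        count_projections(0.0, 360.0, True)
    with pytest.raises(ValueError):
        count_projections(200.0, 180.0, True)


class TestForwardProject:
    def test_zero_attenuation_gives_flat_field(self):
        vol = VolumeImage(np.zeros((2, 32, 32)), (1, 1, 1))
        proj = forward_project(vol, geometry(32, 2))
        assert np.allclose(proj.frames, proj.geometry.flat_field_intensity)

    def test_central_ray_matches_chord_length(self):
        r_disk, mu = 20.0, 0.02
        vol = disk_volume(64, r_disk, mu)
        proj = forward_project(vol, geometry(64, 1))
        p = to_line_integrals(proj)
        central = p.frames[:, 0, :].max(axis=1)
        assert np.allclose(central, 2 * r_disk * mu, rtol=0.02)

    def test_sinogram_halfturn_symmetry(self):
        # odd detector size keeps the s -> -s detector flip an exact
        # index reversal
        rng = np.random.default_rng(0)
        n = 49
        yy, xx = np.mgrid[:n, :n]
        c = (n - 1) / 2
        smooth = np.zeros((n, n))
        for _ in range(4):
            cy, cx, s = rng.uniform(12, 36, 2).tolist() + [rng.uniform(3, 6)]
            smooth += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
        smooth[np.hypot(yy - c, xx - c) > n / 2 - 2] = 0.0
        vol = VolumeImage(smooth[None] * 0.02, (1, 1, 1))
        geom = geometry(n, 1, step=1.0, rng=360.0)
        p = to_line_integrals(forward_project(vol, geom))
        a0 = p.frames[0, 0, :]
        a180 = p.frames[180, 0, :]
        assert np.allclose(a180, a0[::-1], atol=0.02 * a0.max() + 1e-9)

    def test_linearity_in_line_integral_domain(self):
        rng = np.random.default_rng(1)
        a = disk_volume(32, 10, 0.01)
        b = VolumeImage(a.values * 0 + 0, (1, 1, 1))
        bvals = np.zeros((1, 32, 32))
        bvals[0, 10:20, 12:22] = rng.uniform(0, 0.02, (10, 10))
        bvals[0][np.hypot(*np.mgrid[:32, :32] - 15.5) > 13] = 0
        b = VolumeImage(bvals, (1, 1, 1))
        geom = geometry(32, 1)
        pa = to_line_integrals(forward_project(a, geom)).frames
        pb = to_line_integrals(forward_project(b, geom)).frames
        pab = to_line_integrals(forward_project(
            VolumeImage(a.values + b.values, (1, 1, 1)), geom)).frames
        assert np.allclose(pab, pa + pb, atol=1e-9)


class TestPhaseContrast:
    def test_zero_strength_is_identity(self):
        vol = disk_volume(32, 10, 0.02)
        proj = forward_project(vol, geometry(32, 1))
        out = apply_phase_contrast(proj, 0.0)
        assert np.array_equal(out.frames, proj.frames)

    def test_constant_frame_unchanged(self):
        geom = geometry(16, 1, step=90.0, rng=360.0)
        frames = np.full((4, 1, 16), 3.0)
        proj = ProjectionSet(frames, [0, 90, 180, 270], geom)
        out = apply_phase_contrast(proj, 0.5)
        assert np.allclose(out.frames, 3.0)

    def test_step_edge_gets_one_fringe_pair(self):
        geom = geometry(32, 1, step=360.0, rng=360.0)
        frames = np.ones((1, 1, 32))
        frames[0, 0, 16:] = 0.5
        proj = ProjectionSet(frames, [0.0], geom)
        out = apply_phase_contrast(proj, 0.05)
        d = out.frames[0, 0] - frames[0, 0]
        # exactly one overshoot/undershoot pair bracketing the edge
        assert np.flatnonzero(d > 1e-12).tolist() == [15]
        assert np.flatnonzero(d < -1e-12).tolist() == [16]

    def test_negative_strength_rejected(self):
        vol = disk_volume(16, 5, 0.01)
        proj = forward_project(vol, geometry(16, 1))
        with pytest.raises(ValueError):
            apply_phase_contrast(proj, -1.0)


class TestBeamHardening:
    def test_zero_coefficient_is_identity(self):
        proj = forward_project(disk_volume(32, 10, 0.02), geometry(32, 1))
        out = apply_beam_hardening(proj, 0.0)
        assert np.array_equal(out.frames, proj.frames)

    def test_compression_is_monotone(self):
        proj = forward_project(disk_volume(32, 12, 0.03), geometry(32, 1))
        out = apply_beam_hardening(proj, 0.2)
        t_in = to_line_integrals(proj).frames[:, 0, :]
        t_out = to_line_integrals(out).frames[:, 0, :]
        order = np.argsort(t_in.ravel())
        diffs = np.diff(t_out.ravel()[order])
        assert np.all(diffs >= -1e-9)

    def test_cupping_after_reconstruction(self):
        n, r_disk = 64, 24.0
        vol = disk_volume(n, r_disk, 0.05)
        proj = forward_project(vol, geometry(n, 1))
        hard = apply_beam_hardening(proj, 0.15)
        rec = fbp_reconstruct(hard).values[0]
        yy, xx = np.mgrid[:n, :n]
        rr = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2)
        inner = rec[rr <= r_disk / 3]
        outer = rec[(rr > 2 * r_disk / 3) & (rr <= r_disk)]
        assert inner.mean() < outer.mean()

    def test_nonmonotone_coefficient_rejected(self):
        proj = forward_project(disk_volume(32, 12, 0.1), geometry(32, 1))
        with pytest.raises(ValueError, match="non-monotone"):
            apply_beam_hardening(proj, 0.5)


class TestNoise:
    def test_poisson_relative_std(self):
        geom = geometry(400, 1, step=1.0, rng=360.0)
        frames = np.ones((360, 1, 400))
        proj = ProjectionSet(frames, np.arange(360.0), geom)
        out = add_noise(proj, photon_count=1.0e4, read_noise_std=0.0,
                        drift_amplitude=0.0, seed=3)
        rel = out.frames.std()
        assert rel == pytest.approx(1.0 / np.sqrt(1.0e4), rel=0.1)

    def test_deterministic_given_seed(self):
        proj = forward_project(disk_volume(32, 10, 0.02), geometry(32, 1))
        a = add_noise(proj, 1e4, 0.01, 0.05, seed=7)
        b = add_noise(proj, 1e4, 0.01, 0.05, seed=7)
        assert np.array_equal(a.frames, b.frames)

    def test_infinite_photons_no_drift_is_identity(self):
        proj = forward_project(disk_volume(32, 10, 0.02), geometry(32, 1))
        out = add_noise(proj, np.inf, 0.0, 0.0, seed=0)
        assert np.array_equal(out.frames, proj.frames)


class TestFBP:
    def test_zero_sinogram_gives_zero_volume(self):
        geom = geometry(32, 1)
        frames = np.zeros((180, 1, 32))
        proj = ProjectionSet(frames, np.arange(180.0), geom, "line-integral")
        rec = fbp_reconstruct(proj)
        assert np.allclose(rec.values, 0.0, atol=1e-12)

    def test_uniform_disk_nrmse(self):
        vol = disk_volume(64, 20, 0.02)
        proj = forward_project(vol, geometry(64, 1))
        rec = fbp_reconstruct(proj)
        yy, xx = np.mgrid[:64, :64]
        sup = np.hypot(yy - 31.5, xx - 31.5) <= 20
        err = rec.values[0][sup] - vol.values[0][sup]
        nrmse = np.sqrt(np.mean(err ** 2)) / vol.values[0][sup].mean()
        assert nrmse < 0.10

    def test_impulse_peaks_at_source_voxel(self):
        n = 48
        vals = np.zeros((1, n, n))
        vals[0, 20, 30] = 1.0
        proj = forward_project(VolumeImage(vals, (1, 1, 1)), geometry(n, 1))
        rec = fbp_reconstruct(proj)
        assert np.unravel_index(np.argmax(rec.values[0]), (n, n)) == (20, 30)

    def test_roundtrip_correlation_on_smooth_phantom(self):
        rng = np.random.default_rng(5)
        n = 48
        yy, xx = np.mgrid[:n, :n]
        img = np.zeros((n, n))
        for _ in range(5):
            cy, cx = rng.uniform(10, 38, 2)
            img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 40.0)
        img[np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) > n / 2 - 2] = 0
        vol = VolumeImage(img[None] * 0.02, (1, 1, 1))
        rec = fbp_reconstruct(forward_project(vol, geometry(n, 1)))
        sup = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) <= n / 2 - 2
        corr = np.corrcoef(rec.values[0][sup], vol.values[0][sup])[0, 1]
        assert corr > 0.95

    def test_too_few_angles_rejected(self):
        geom = geometry(32, 1)
        proj = ProjectionSet(np.zeros((1, 1, 32)), [0.0], geom,
                             "line-integral")
        with pytest.raises(ValueError, match="angles"):
            fbp_reconstruct(proj)
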
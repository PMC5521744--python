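"""Projection simulation and filtered back-projection.

Geometry is parallel-beam and slice-wise: the rotation axis is z (the
streamwise column axis), each z slice is projected independently, and cone-
beam magnification is absorbed into ``effective_pixel_um``.  FBP is exact in
this geometry, which is the single largest simplification relative to a
laboratory cone-beam scanner and is documented in the methods note.

Conventions: frames are detector images indexed (z, detector-column); the
intensity domain follows Beer-Lambert, I = I0 * exp(-p), with p the line
integral of the per-voxel attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import iradon, radon

from .core import VolumeImage

__all__ = [
    "ScanGeometry",
    "ProjectionSet",
    "count_projections",
    "projection_angles",
    "forward_project",
    "apply_phase_contrast",
    "apply_beam_hardening",
    "add_noise",
    "fbp_reconstruct",
    "to_line_integrals",
]

#: floor applied to I/I0 before taking logs, for noise robustness
LOG_FLOOR = 1e-6


@dataclass
class ScanGeometry:
    """Acquisition description.

    ``metadata`` (kV, uA, SOD, STD, ...) is descriptive only; it does not
    alter the simulated parallel-beam physics.
    """

    angle_step_deg: float = 0.25
    angular_range_deg: float = 360.0
    endpoint_inclusive: bool = True
    detector_width_px: int = 96
    detector_height_px: int = 96
    effective_pixel_um: float = 104.2
    flat_field_intensity: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.angle_step_deg <= 0:
            raise ValueError("angle step must be positive")
        if self.angle_step_deg > self.angular_range_deg:
            raise ValueError("angle step exceeds angular range")
        if self.effective_pixel_um <= 0 or self.flat_field_intensity <= 0:
            raise ValueError("pixel size and flat field must be positive")

    @property
    def n_projections(self) -> int:
        return count_projections(self.angle_step_deg, self.angular_range_deg,
                                 self.endpoint_inclusive)

    @property
    def angles_deg(self) -> np.ndarray:
        return projection_angles(self.angle_step_deg, self.angular_range_deg,
                                 self.endpoint_inclusive)


@dataclass
class ProjectionSet:
    """Stack of detector frames, one per rotation angle."""

    frames: np.ndarray            # (n_angles, height, width)
    angles_deg: np.ndarray
    geometry: ScanGeometry
    domain: str = "intensity"     # or "line-integral"

    def __post_init__(self) -> None:
        self.frames = np.ascontiguousarray(self.frames, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_angles, height, width)")
        if len(self.frames) != len(self.angles_deg):
            raise ValueError("one frame per angle required")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.domain == "intensity" and self.frames.min() < 0:
            raise ValueError("intensity frames must be non-negative")

    def copy(self) -> "ProjectionSet":
        return ProjectionSet(self.frames.copy(), self.angles_deg.copy(),
                             self.geometry, self.domain)


def count_projections(step_deg: float, range_deg: float,
                      endpoint_inclusive: bool) -> int:
    """Number of projections for a given angular step and range.

    360 deg at 0.25 deg steps, endpoint included, gives 1441 projections.
    """
    if step_deg <= 0:
        raise ValueError("angle step must be positive")
    if step_deg > range_deg:
        raise ValueError("angle step exceeds angular range")
    return int(math.floor(range_deg / step_deg + 1e-9)) + (
        1 if endpoint_inclusive else 0)


def projection_angles(step_deg: float, range_deg: float,
                      endpoint_inclusive: bool) -> np.ndarray:
    n = count_projections(step_deg, range_deg, endpoint_inclusive)
    return np.arange(n) * step_deg


def forward_project(volume: VolumeImage, geometry: ScanGeometry) -> ProjectionSet:
    """Slice-wise parallel-beam line integrals, returned in intensity domain.

    Line integrals are in units of (attenuation per voxel) x (voxel
    traversals), matching :func:`fbp_reconstruct` output units.
    """
    vals = volume.values
    if vals.size == 0:
        raise ValueError("empty volume")
    nz, ny, nx = vals.shape
    if ny != nx:
        raise ValueError("slices must be square (column centered in grid)")
    if geometry.detector_width_px != nx:
        raise ValueError(
            f"detector width {geometry.detector_width_px} must match the "
            f"volume cross-section {nx}")
    angles = geometry.angles_deg
    frames = np.empty((len(angles), nz, nx), dtype=np.float64)
    for iz in range(nz):
        sino = radon(vals[iz], theta=angles, circle=True)  # (det, n_angles)
        frames[:, iz, :] = sino.T
    intensity = geometry.flat_field_intensity * np.exp(-frames)
    return ProjectionSet(intensity, angles, geometry, "intensity")


def apply_phase_contrast(proj: ProjectionSet, strength: float) -> ProjectionSet:
    """Near-field edge-enhancement surrogate: I <- I - strength * lap(I).

    Free-space propagation over a long source-to-detector distance renders
    refraction visible as bright/dark fringes at phase boundaries; to leading
    order this is a transverse-Laplacian perturbation of each frame, which is
    exactly the signal the Lorentzian pre-reconstruction filter acts on.
    """
    if strength < 0:
        raise ValueError("phase-contrast strength must be non-negative")
    if proj.domain != "intensity":
        raise ValueError("phase contrast applies to intensity frames")
    out = proj.copy()
    if strength == 0:
        return out
    for i in range(len(out.frames)):
        lap = ndimage.laplace(out.frames[i], mode="nearest")
        out.frames[i] = out.frames[i] - strength * lap
    np.clip(out.frames, 0.0, None, out=out.frames)
    return out


def apply_beam_hardening(proj: ProjectionSet, coefficient: float) -> ProjectionSet:
    """Quadratic surrogate for polychromatic beam hardening.

    Line integrals t are compressed to t' = t - c*t^2, under-measuring long
    high-attenuation paths; after FBP this yields the classic cupping
    artifact.  Fails if the compression would be non-monotone over the data
    range (t_max >= 1/(2c)).
    """
    if coefficient < 0:
        raise ValueError("coefficient must be non-negative")
    if proj.domain != "intensity":
        raise ValueError("beam hardening applies to intensity frames")
    out = proj.copy()
    if coefficient == 0:
        return out
    i0 = proj.geometry.flat_field_intensity
    t = -np.log(np.clip(out.frames / i0, LOG_FLOOR, None))
    t_max = float(t.max())
    if t_max >= 1.0 / (2.0 * coefficient):
        raise ValueError(
            f"beam-hardening coefficient {coefficient} is non-monotone over "
            f"the data range (max line integral {t_max:.3f})")
    t2 = t - coefficient * t * t
    out.frames = i0 * np.exp(-t2)
    return out


def add_noise(proj: ProjectionSet, photon_count: float, read_noise_std: float,
              drift_amplitude: float, seed: int) -> ProjectionSet:
    """Poisson photon noise + Gaussian read noise + smooth source drift.

    ``photon_count`` is the expected flat-field count per pixel; the per-angle
    multiplicative source drift is a smooth random modulation of relative
    amplitude ``drift_amplitude`` (the slow source-intensity variation of a
    microfocus tube over a multi-hour scan).  ``photon_count = inf`` disables
    photon and read noise.
    """
    if photon_count <= 0:
        raise ValueError("photon_count must be positive")
    if read_noise_std < 0 or drift_amplitude < 0:
        raise ValueError("noise amplitudes must be non-negative")
    if proj.domain != "intensity":
        raise ValueError("noise applies to intensity frames")
    out = proj.copy()
    rng = np.random.default_rng(seed)
    n = len(out.frames)
    if drift_amplitude > 0:
        raw = rng.standard_normal(n)
        smooth = ndimage.gaussian_filter1d(raw, sigma=max(2.0, n / 20.0),
                                           mode="wrap")
        smooth /= max(np.abs(smooth).max(), 1e-12)
        drift = 1.0 + drift_amplitude * smooth
        out.frames *= drift[:, None, None]
    if np.isfinite(photon_count):
        i0 = proj.geometry.flat_field_intensity
        counts = rng.poisson(photon_count * out.frames / i0)
        out.frames = counts.astype(np.float64) * (i0 / photon_count)
        if read_noise_std > 0:
            out.frames += rng.normal(0.0, read_noise_std, out.frames.shape)
        np.clip(out.frames, 0.0, None, out=out.frames)
    return out


def to_line_integrals(proj: ProjectionSet) -> ProjectionSet:
    """Convert intensity frames to line integrals p = -log(I/I0)."""
    if proj.domain == "line-integral":
        return proj.copy()
    i0 = proj.geometry.flat_field_intensity
    p = -np.log(np.clip(proj.frames / i0, LOG_FLOOR, None))
    out = ProjectionSet(p, proj.angles_deg.copy(), proj.geometry,
                        "line-integral")
    return out


def fbp_reconstruct(proj: ProjectionSet, geometry: ScanGeometry | None = None,
                    filter_name: str = "shepp-logan") -> VolumeImage:
    """Slice-wise filtered back-projection.

    The ramp filter is apodized with the chosen window (default Shepp-Logan,
    a mild apodization that keeps desk-scale reconstructions quantitative;
    'hann' is available for noisier data).  Output voxel spacing equals the
    effective detector pixel.
    """
    geometry = geometry or proj.geometry
    if len(proj.angles_deg) < 2:
        raise ValueError("at least 2 projection angles required")
    li = to_line_integrals(proj)
    n_angles, nz, nx = li.frames.shape
    recon = np.empty((nz, nx, nx), dtype=np.float64)
    for iz in range(nz):
        sino = li.frames[:, iz, :].T  # (det, n_angles)
        recon[iz] = iradon(sino, theta=proj.angles_deg, circle=True,
                           filter_name=filter_name,
                           output_size=nx)
    um = geometry.effective_pixel_um
    return VolumeImage(recon, (um, um, um), "reconstructed-gray",
                       {"filter_name": filter_name,
                        "n_angles": int(n_angles)})
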
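"""Affine registration of paired tomograms.

Two scans of the same column (different contrast agents, different detector
resolutions) are compared voxel-wise only after alignment.  Registration is
intensity-based on the solid phase — the phase the two scans agree on —
with a mean-squared-error metric minimized by regular-step gradient descent
over a 12-parameter affine transform, multi-resolution (2-level pyramid),
identity-initialized.  The optimization is delegated to SimpleITK, which
implements exactly this optimizer/metric pair; masks are Gaussian-smoothed
(sigma = 1 voxel) first so the binary metric has a usable gradient.

Array convention: all arrays are (z, y, x); the stored transform maps fixed
voxel coordinates to moving voxel coordinates in (z, y, x) order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import LabelVolume, VolumeImage

__all__ = [
    "AffineTransform",
    "resample",
    "register_affine",
    "apply_transform",
]


@dataclass
class AffineTransform:
    """Affine map p_moving = linear @ (p_fixed - center) + center + translation,
    all in fixed-image voxel coordinates, (z, y, x) order."""

    linear: np.ndarray                       # 3x3
    translation: np.ndarray                  # 3
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.linear)) < 1e-8:
            raise ValueError("transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def map_points(self, pts_zyx: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts_zyx, dtype=np.float64)
        return (self.linear @ (pts - self.center).T).T + self.center \
            + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation, self.center,
                               {"inverse_of": True})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "linear": self.linear.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
            "metadata": self.metadata,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["linear"]), np.array(d["translation"]),
                   np.array(d["center"]), d.get("metadata", {}))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(obj: VolumeImage | LabelVolume,
             target_spacing_um: tuple[float, float, float],
             interpolation: str | None = None) -> VolumeImage | LabelVolume:
    """Resample onto a grid with the requested voxel spacing.

    Labels use nearest-neighbour (no new codes); intensities use linear.
    """
    if any(s <= 0 for s in target_spacing_um):
        raise ValueError("target spacing must be positive")
    is_labels = isinstance(obj, LabelVolume)
    if interpolation is None:
        interpolation = "nearest" if is_labels else "linear"
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    src_spacing = np.asarray(obj.spacing_um, dtype=float)
    tgt_spacing = np.asarray(target_spacing_um, dtype=float)
    zoom = src_spacing / tgt_spacing
    if np.allclose(zoom, 1.0):
        return obj.copy()
    order = 0 if interpolation == "nearest" else 1
    data = obj.codes if is_labels else obj.values
    out = ndimage.zoom(data, zoom, order=order, grid_mode=True,
                       mode="grid-constant", cval=0)
    if is_labels:
        return LabelVolume(out.astype(np.uint8), tuple(target_spacing_um),
                           dict(obj.code_map), None)
    return VolumeImage(out, tuple(target_spacing_um),
                       obj.intensity_semantics, dict(obj.metadata))


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _to_sitk(arr: np.ndarray, smooth_sigma: float) -> sitk.Image:
    a = np.asarray(arr, dtype=np.float32)
    if smooth_sigma > 0:
        a = ndimage.gaussian_filter(a, smooth_sigma)
    return sitk.GetImageFromArray(a)


def register_affine(fixed: np.ndarray, moving: np.ndarray,
                    smooth_sigma: float = 1.0,
                    learning_rate: float = 1.0,
                    min_step: float = 1e-4,
                    max_iterations: int = 300,
                    relaxation_factor: float = 0.5,
                    pyramid_levels: int = 2) -> AffineTransform:
    """Register two solid-phase masks (or gray volumes) of equal spacing.

    Returns the affine transform mapping fixed voxel coordinates to moving
    voxel coordinates, with a convergence record in ``metadata``.  Fails if
    the masks do not overlap at the identity initialization.
    """
    fixed = np.asarray(fixed)
    moving = np.asarray(moving)
    if fixed.shape != moving.shape and fixed.ndim != 3:
        raise ValueError("expected 3D inputs")
    if not (fixed > 0).any() or not (moving > 0).any():
        raise ValueError("empty mask passed to registration")
    if not ((fixed > 0) & (moving > 0)).any():
        raise ValueError("masks do not overlap at initialization; "
                         "pre-align before registering")
    f = _to_sitk(fixed, smooth_sigma)
    m = _to_sitk(moving, smooth_sigma)
    tx = sitk.CenteredTransformInitializer(
        f, m, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=learning_rate, minStep=min_step,
        numberOfIterations=max_iterations,
        relaxationFactor=relaxation_factor)
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (pyramid_levels - 1 - i) for i in range(pyramid_levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(tx, inPlace=True)
    out = reg.Execute(f, m)

    # sitk works in (x, y, z) physical coordinates; with unit spacing and no
    # rotation of the direction matrix these are voxel coordinates reversed.
    a_xyz = np.array(out.GetMatrix()).reshape(3, 3)
    t_xyz = np.array(out.GetTranslation())
    c_xyz = np.array(out.GetCenter())
    flip = np.eye(3)[::-1]
    linear = flip @ a_xyz @ flip
    return AffineTransform(
        linear, t_xyz[::-1], c_xyz[::-1],
        metadata={
            "final_metric": float(reg.GetMetricValue()),
            "iterations": int(reg.GetOptimizerIteration()),
            "stop_condition": reg.GetOptimizerStopConditionDescription(),
        })


def apply_transform(obj: VolumeImage | LabelVolume, transform: AffineTransform,
                    interpolation: str | None = None,
                    output_shape: tuple[int, int, int] | None = None
                    ) -> VolumeImage | LabelVolume:
    """Resample ``obj`` (the moving image) onto the fixed grid through the
    transform.  Labels use nearest-neighbour interpolation (no new codes)."""
    is_labels = isinstance(obj, LabelVolume)
    if interpolation is None:
        interpolation = "nearest" if is_labels else "linear"
    order = 0 if interpolation == "nearest" else 1
    data = obj.codes if is_labels else obj.values
    shape = output_shape or data.shape
    # output voxel p_fixed samples input at linear@(p-c)+c+t
    matrix = transform.linear
    offset = (transform.center + transform.translation
              - matrix @ transform.center)
    out = ndimage.affine_transform(
        data.astype(np.float64) if not is_labels else data,
        matrix, offset=offset, output_shape=shape, order=order,
        mode="constant", cval=0)
    if is_labels:
        return LabelVolume(out.astype(np.uint8), tuple(obj.spacing_um),
                           dict(obj.code_map), obj.column_diameter_vox)
    return VolumeImage(out, tuple(obj.spacing_um), obj.intensity_semantics,
                       dict(obj.metadata))
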
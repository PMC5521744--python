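"""Core volumetric containers and the fixed phase code map.

All volumes are numpy arrays indexed ``(z, y, x)`` with ``z`` the streamwise
axis of the column (flow direction = increasing ``z``).  Label volumes carry
one integer phase code per voxel; everything outside the inscribed column
cylinder is code 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Fixed phase code map shared by every stage of the pipeline.
PHASE_CODES: dict[str, int] = {
    "outside": 0,
    "solid": 1,
    "liquid": 2,
    "biofilm": 3,
    "air": 4,
}
PHASE_NAMES: dict[int, str] = {v: k for k, v in PHASE_CODES.items()}

OUTSIDE = PHASE_CODES["outside"]
SOLID = PHASE_CODES["solid"]
LIQUID = PHASE_CODES["liquid"]
BIOFILM = PHASE_CODES["biofilm"]
AIR = PHASE_CODES["air"]


def column_mask(shape: tuple[int, int, int], diameter_vox: float | None = None) -> np.ndarray:
    """Boolean mask of the inscribed column cylinder (axis = z).

    If ``diameter_vox`` is omitted, the cylinder inscribed in the (y, x)
    cross-section is used.
    """
    nz, ny, nx = shape
    if diameter_vox is None:
        diameter_vox = min(ny, nx)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[:ny, :nx]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= (diameter_vox / 2.0) ** 2
    return np.broadcast_to(disk, shape).copy()


@dataclass
class LabelVolume:
    """Per-voxel phase codes on a regular grid.

    ``codes`` is a 3D uint8 array; ``spacing_um`` is the voxel size per axis
    (z, y, x).  ``code_map`` is the fixed phase map (kept on the instance so
    sidecar files are self-describing).
    """

    codes: np.ndarray
    spacing_um: tuple[float, float, float]
    code_map: dict[str, int] = field(default_factory=lambda: dict(PHASE_CODES))
    column_diameter_vox: float | None = None

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes)
        if self.codes.ndim != 3:
            raise ValueError("label volume must be 3D")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.codes.shape  # type: ignore[return-value]

    def mask(self) -> np.ndarray:
        """In-column mask (voxels that are not 'outside')."""
        return self.codes != OUTSIDE

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.codes.copy(), tuple(self.spacing_um),
                           dict(self.code_map), self.column_diameter_vox)


@dataclass
class VolumeImage:
    """3D scalar field (attenuation or reconstructed gray values)."""

    values: np.ndarray
    spacing_um: tuple[float, float, float]
    intensity_semantics: str = "attenuation"  # or "reconstructed-gray"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.values.copy(), tuple(self.spacing_um),
                           self.intensity_semantics, dict(self.metadata))


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar persistence
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_labels(labels: LabelVolume, path: str | Path, extra: dict | None = None) -> None:
    """Write a LabelVolume as 8-bit multi-page TIFF (one page per z slice)
    plus a JSON sidecar with spacing, code map and any extra metadata."""
    path = Path(path)
    tifffile.imwrite(path, labels.codes.astype(np.uint8))
    side = {
        "kind": "labels",
        "spacing_um": list(labels.spacing_um),
        "code_map": labels.code_map,
        "column_diameter_vox": labels.column_diameter_vox,
    }
    if extra:
        side.update(_jsonable(extra))
    _sidecar_path(path).write_text(json.dumps(side, indent=2))


def load_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    codes = tifffile.imread(path)
    side = json.loads(_sidecar_path(path).read_text())
    return LabelVolume(
        codes.astype(np.uint8),
        tuple(side["spacing_um"]),
        {k: int(v) for k, v in side["code_map"].items()},
        side.get("column_diameter_vox"),
    )


def save_volume(volume: VolumeImage, path: str | Path, extra: dict | None = None) -> None:
    """Write a VolumeImage as 32-bit float multi-page TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.values.astype(np.float32))
    side = {
        "kind": "volume",
        "spacing_um": list(volume.spacing_um),
        "intensity_semantics": volume.intensity_semantics,
        "metadata": _jsonable(volume.metadata),
    }
    if extra:
        side.update(_jsonable(extra))
    _sidecar_path(path).write_text(json.dumps(side, indent=2))


def load_volume(path: str | Path) -> VolumeImage:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    side = json.loads(_sidecar_path(path).read_text())
    return VolumeImage(values, tuple(side["spacing_um"]),
                       side.get("intensity_semantics", "attenuation"),
                       side.get("metadata", {}))
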
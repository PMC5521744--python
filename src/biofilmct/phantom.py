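"""Synthetic porous-medium / biofilm phantoms.

Emulates a cylindrical column (10 mm inner diameter in the emulated study)
wet-packed with ~2.5 mm spherical grains at ~40 % porosity and colonized by
a corrugated biofilm coating, under two contrast-agent regimes:

* ``feso4`` — iron sulfate bound in the biofilm: liquid darkest, biofilm
  slightly brighter, solid brightest; strong within-biofilm heterogeneity.
* ``baso4`` — barium sulfate suspension marking the liquid: liquid brightest,
  solid intermediate, biofilm darkest; the injection itself detaches biofilm,
  modelled by :func:`simulate_detachment`.

Everything here is deterministic given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (AIR, BIOFILM, LIQUID, OUTSIDE, SOLID, LabelVolume,
                   VolumeImage, column_mask)

__all__ = [
    "PhantomSpec",
    "DetachmentReport",
    "generate_grain_pack",
    "grow_biofilm",
    "simulate_detachment",
    "assign_attenuation",
    "PorosityError",
]


class PorosityError(RuntimeError):
    """Raised when the requested porosity cannot be reached by the packer."""


#: sphere centers may sit up to this fraction of a grain diameter beyond the
#: column wall; the protruding cap is truncated (grains pressed to the wall)
_WALL_OVERLAP_FRAC = 0.45


@dataclass
class PhantomSpec:
    """Geometry and composition of the synthetic column.

    Defaults mirror the emulated experiment scaled onto a desk-size grid:
    a 10 mm column at ~104 um voxels is 96 voxels across, and 2.5 mm grains
    are 24 voxels — the same 4:1 column-to-grain ratio as the real packing.
    """

    column_diameter_vox: int = 96
    column_length_vox: int = 96
    voxel_size_um: float = 104.2
    grain_diameter_vox: float = 24.0
    target_porosity: float = 0.40
    biofilm_fraction: float = 0.10
    biofilm_heterogeneity: float = 0.15
    air_bubble_count: int = 0
    seed: int = 0
    #: lattice jitter as a fraction of the grain diameter (packing disorder)
    pack_jitter: float = 0.06
    #: tolerance on the achieved porosity before the packer gives up
    porosity_tolerance: float = 0.03

    def __post_init__(self) -> None:
        if self.column_diameter_vox <= 0 or self.column_length_vox <= 0:
            raise ValueError("column dimensions must be positive")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")
        if not 0 < self.target_porosity <= 1:
            raise ValueError("target_porosity must be in (0, 1]")
        if self.grain_diameter_vox >= self.column_diameter_vox:
            raise ValueError("grain diameter must be smaller than the column")
        if not 0 <= self.biofilm_fraction < 1:
            raise ValueError("biofilm_fraction must be in [0, 1)")
        if self.biofilm_heterogeneity < 0:
            raise ValueError("biofilm_heterogeneity must be non-negative")
        if self.air_bubble_count < 0:
            raise ValueError("air_bubble_count must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.column_length_vox, self.column_diameter_vox,
                self.column_diameter_vox)

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return (self.voxel_size_um,) * 3


@dataclass
class DetachmentReport:
    """Bookkeeping of a detachment event (voxel counts are exact)."""

    biofilm_before: int
    biofilm_after: int
    removed: int
    redeposited: int
    #: (source centroid zyx, destination centroid zyx, patch size)
    patches: list[tuple[tuple[float, float, float],
                        tuple[float, float, float], int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# grain packing
# ---------------------------------------------------------------------------

def _lattice_candidates(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal-close-packed candidate centers covering the column.

    A purely random sequential addition of hard spheres jams near 38 % solid,
    well short of the ~60 % of a wet-packed column, so candidates are seeded
    from a jittered HCP lattice; jitter-induced overlaps are then relaxed by
    a few pair-repulsion sweeps so that the hard-sphere constraint holds
    while the packing stays disordered and dense enough to reach the target.
    """
    g = spec.grain_diameter_vox
    nz, ny, nx = spec.shape
    dz = g * math.sqrt(6.0) / 3.0
    dy = g * math.sqrt(3.0) / 2.0
    centers = []
    k = 0
    z = -g / 4.0
    while z < nz + g / 4.0:
        j = 0
        y = (g / 2.0) * (k % 2)
        while y < ny:
            x0 = (g / 2.0) * (j % 2 + (2.0 / 3.0) * (k % 2))
            x = x0
            while x < nx:
                centers.append((z, y, x))
                x += g
            j += 1
            y += dy
        k += 1
        z += dz
    pts = np.asarray(centers, dtype=float)
    pts += rng.uniform(-spec.pack_jitter * g, spec.pack_jitter * g, pts.shape)
    # keep only centers inside the column before relaxing, so boundary
    # spheres relax outward freely instead of piling up against a wall
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    col_r = spec.column_diameter_vox / 2.0
    rad = np.hypot(pts[:, 1] - cy, pts[:, 2] - cx)
    keep = (rad <= col_r + _WALL_OVERLAP_FRAC * g) \
        & (pts[:, 0] > -g / 2.0) & (pts[:, 0] < nz + g / 2.0)
    return _relax_overlaps(pts[keep], spec)


def _relax_overlaps(pts: np.ndarray, spec: PhantomSpec,
                    sweeps: int = 60) -> np.ndarray:
    """Push overlapping sphere pairs apart until the hard-sphere constraint
    (center distance >= grain diameter) holds."""
    from scipy.spatial import cKDTree

    g = spec.grain_diameter_vox
    for _ in range(sweeps):
        target = g * (1.0 + 1e-3)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(target, output_type="ndarray")
        if len(pairs) == 0:
            break
        disp = np.zeros_like(pts)
        delta = pts[pairs[:, 0]] - pts[pairs[:, 1]]
        dist = np.linalg.norm(delta, axis=1)
        dist = np.where(dist < 1e-9, 1e-9, dist)
        push = (target - dist) / 2.0 * 1.05
        vec = delta / dist[:, None] * push[:, None]
        np.add.at(disp, pairs[:, 0], vec)
        np.add.at(disp, pairs[:, 1], -vec)
        pts = pts + disp
    return pts


def generate_grain_pack(spec: PhantomSpec) -> LabelVolume:
    """Pack non-overlapping spheres into the column until the liquid fraction
    reaches ``target_porosity``.

    Grains may be truncated by the column wall (wet-packed cross-section).
    Raises :class:`PorosityError` if insertion stalls above
    ``target + porosity_tolerance``, reporting the achieved porosity.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    codes = np.full(spec.shape, OUTSIDE, dtype=np.uint8)
    mask = column_mask(spec.shape, spec.column_diameter_vox)
    codes[mask] = LIQUID
    n_col = int(mask.sum())
    g = spec.grain_diameter_vox
    radius = g / 2.0
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    col_r = spec.column_diameter_vox / 2.0

    cand = _lattice_candidates(spec, rng)
    # keep candidates near or inside the column (wall truncation allowed)
    rad = np.hypot(cand[:, 1] - cy, cand[:, 2] - cx)
    cand = cand[(rad <= col_r + _WALL_OVERLAP_FRAC * g)
                & (cand[:, 0] > -radius) & (cand[:, 0] < nz + radius)]
    cand = cand[rng.permutation(len(cand))]

    porosity = 1.0
    accepted: list[np.ndarray] = []
    solid = np.zeros(spec.shape, dtype=bool)
    # sub-voxel slack: voxelization cannot resolve overlaps below 0.1% of g
    min_d2 = (g * (1.0 - 1e-3)) ** 2
    for c in cand:
        if porosity <= spec.target_porosity:
            break
        if accepted:
            d2 = np.sum((np.asarray(accepted) - c) ** 2, axis=1)
            if d2.min() < min_d2:
                continue
        accepted.append(c)
        z0 = max(0, int(math.floor(c[0] - radius)))
        z1 = min(nz, int(math.ceil(c[0] + radius)) + 1)
        y0 = max(0, int(math.floor(c[1] - radius)))
        y1 = min(ny, int(math.ceil(c[1] + radius)) + 1)
        x0 = max(0, int(math.floor(c[2] - radius)))
        x1 = min(nx, int(math.ceil(c[2] + radius)) + 1)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        ball = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius ** 2
        solid[z0:z1, y0:y1, x0:x1] |= ball
        porosity = 1.0 - np.count_nonzero(solid & mask) / n_col

    if porosity > spec.target_porosity + spec.porosity_tolerance:
        raise PorosityError(
            f"grain packing stalled at porosity {porosity:.3f}, "
            f"target {spec.target_porosity:.3f} is unreachable"
        )
    codes[solid & mask] = SOLID
    labels = LabelVolume(codes, spec.spacing_um,
                         column_diameter_vox=spec.column_diameter_vox)
    if spec.air_bubble_count:
        _add_air_bubbles(labels, spec, rng)
    return labels


def _add_air_bubbles(labels: LabelVolume, spec: PhantomSpec,
                     rng: np.random.Generator) -> None:
    """Replace small ellipsoidal liquid pockets by air (in place)."""
    liquid_idx = np.argwhere(labels.codes == LIQUID)
    if len(liquid_idx) == 0:
        return
    nz, ny, nx = labels.shape
    zz, yy, xx = np.mgrid[:nz, :ny, :nx]
    for _ in range(spec.air_bubble_count):
        c = liquid_idx[rng.integers(len(liquid_idx))]
        semi = rng.uniform(1.5, 3.5, size=3)
        ell = (((zz - c[0]) / semi[0]) ** 2 + ((yy - c[1]) / semi[1]) ** 2
               + ((xx - c[2]) / semi[2]) ** 2) <= 1.0
        labels.codes[ell & (labels.codes == LIQUID)] = AIR


# ---------------------------------------------------------------------------
# biofilm growth
# ---------------------------------------------------------------------------

# the coating is patchy: thickness noise of relative std ~1 leaves part of
# the grain surface bare and concentrates the same biofilm volume in thicker
# patches — both closer to real corrugated morphology and necessary for the
# patches to be resolvable against partial-volume blurring at voxel scale
_CORRUGATION_REL_STD = 1.0    # relative std of the local coating thickness
_CORRUGATION_SCALE_VOX = 4.0  # correlation length of the thickness noise


def _coating(dist: np.ndarray, liquid: np.ndarray, thick: np.ndarray,
             t: float, solid_adjacent: np.ndarray) -> np.ndarray:
    """Biofilm candidate mask at base thickness ``t``, pruned to the
    components that touch a solid surface through biofilm (26-connected)."""
    bf = liquid & (dist <= t * thick)
    if not bf.any():
        return bf
    lab, n = ndimage.label(bf, structure=np.ones((3, 3, 3), dtype=bool))
    touching = np.unique(lab[bf & solid_adjacent])
    touching = touching[touching > 0]
    keep = np.isin(lab, touching)
    return keep


def grow_biofilm(labels: LabelVolume, spec: PhantomSpec) -> LabelVolume:
    """Coat solid surfaces with biofilm of randomized local thickness until
    ``spec.biofilm_fraction`` of the column volume is biofilm.

    The coating is a constrained dilation of the solid surface: a liquid voxel
    becomes biofilm when its Euclidean distance to the nearest solid voxel is
    below a spatially corrugated thickness field.  Components not connected
    to a solid surface are pruned, so every biofilm voxel reaches solid via a
    26-connected path through biofilm.
    """
    out = labels.copy()
    if spec.biofilm_fraction == 0:
        return out
    solid = out.codes == SOLID
    liquid = out.codes == LIQUID
    if not solid.any() or not liquid.any():
        raise ValueError("grow_biofilm requires both solid and liquid voxels")
    mask = out.mask()
    n_col = int(mask.sum())
    target_vox = spec.biofilm_fraction * n_col
    if target_vox > liquid.sum():
        raise ValueError(
            f"biofilm_fraction {spec.biofilm_fraction} exceeds available "
            f"liquid fraction {liquid.sum() / n_col:.3f}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x62F]))
    noise = ndimage.gaussian_filter(
        rng.standard_normal(out.shape), _CORRUGATION_SCALE_VOX)
    noise /= max(noise.std(), 1e-12)
    thick = np.clip(1.0 + _CORRUGATION_REL_STD * noise, 0.05, None)

    dist = ndimage.distance_transform_edt(~solid)
    solid_adjacent = ndimage.binary_dilation(
        solid, structure=np.ones((3, 3, 3), dtype=bool)) & liquid

    lo, hi = 0.0, float(dist[liquid].max()) + 1.0
    best = None
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        bf = _coating(dist, liquid, thick, mid, solid_adjacent)
        n_bf = int(bf.sum())
        if best is None or abs(n_bf - target_vox) < abs(best[1] - target_vox):
            best = (bf, n_bf)
        if abs(n_bf - target_vox) <= max(1, 0.005 * n_col):
            break
        if n_bf < target_vox:
            lo = mid
        else:
            hi = mid
    out.codes[best[0]] = BIOFILM
    return out


# ---------------------------------------------------------------------------
# detachment (BaSO4 injection perturbation)
# ---------------------------------------------------------------------------

def simulate_detachment(labels: LabelVolume, washout_fraction: float,
                        redeposit_fraction: float, seed: int,
                        patch_radius_vox: float = 3.0,
                        ) -> tuple[LabelVolume, DetachmentReport]:
    """Stochastic geometric perturbation emulating shear/abrasion detachment
    during contrast-suspension injection.

    ``washout_fraction`` of the biofilm voxels are stripped preferentially
    from the outer (liquid-facing) layers — basal layers, which have higher
    shear strength, are retained.  ``redeposit_fraction`` of the original
    biofilm volume is re-placed as roughly spherical patches at liquid sites
    strictly downstream (larger z) of the centroid of the material they came
    from.  The rest of the removed material leaves the column (becomes
    liquid).  Exact voxel bookkeeping is returned alongside the labels.
    """
    if not 0 <= washout_fraction <= 1 or not 0 <= redeposit_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if redeposit_fraction > washout_fraction:
        raise ValueError("cannot redeposit more than was washed out")
    out = labels.copy()
    bf_idx = np.argwhere(out.codes == BIOFILM)
    n_bf = len(bf_idx)
    if washout_fraction > 0 and n_bf == 0:
        raise ValueError("no biofilm present to detach")
    report = DetachmentReport(n_bf, n_bf, 0, 0)
    if washout_fraction == 0 or n_bf == 0:
        return out, report

    rng = np.random.default_rng(seed)
    n_remove = int(round(washout_fraction * n_bf))
    n_redep = int(round(redeposit_fraction * n_bf))

    # outer layers first: largest distance to solid, random tie-break
    solid = out.codes == SOLID
    dist = ndimage.distance_transform_edt(~solid)
    score = dist[tuple(bf_idx.T)] + rng.uniform(0, 1e-3, n_bf)
    order = np.argsort(-score)
    removed = bf_idx[order[:n_remove]]
    out.codes[tuple(removed.T)] = LIQUID

    placed_total = 0
    patches: list[tuple[tuple[float, float, float],
                        tuple[float, float, float], int]] = []
    if n_redep > 0:
        nz = out.shape[0]
        patch_target = max(1, min(n_redep, int(
            4.0 / 3.0 * math.pi * patch_radius_vox ** 3)))
        chunks = np.array_split(removed[rng.permutation(len(removed))],
                                max(1, int(math.ceil(n_redep / patch_target))))
        for chunk in chunks:
            if placed_total >= n_redep or len(chunk) == 0:
                break
            want = min(len(chunk), n_redep - placed_total)
            src_centroid = chunk.mean(axis=0)
            z_min = int(math.floor(src_centroid[0])) + 2
            liquid_idx = np.argwhere(out.codes == LIQUID)
            liquid_idx = liquid_idx[liquid_idx[:, 0] >= z_min + patch_radius_vox]
            if len(liquid_idx) == 0:
                continue  # no room downstream; material leaves the column
            center = liquid_idx[rng.integers(len(liquid_idx))]
            # nearest liquid voxels to the chosen center form the patch
            d2 = np.sum((liquid_idx - center) ** 2, axis=1)
            sel = liquid_idx[np.argsort(d2)[:want]]
            sel = sel[sel[:, 0] > src_centroid[0]]  # strictly downstream
            if len(sel) == 0:
                continue
            out.codes[tuple(sel.T)] = BIOFILM
            placed_total += len(sel)
            patches.append((tuple(src_centroid), tuple(sel.mean(axis=0)),
                            int(len(sel))))
        del nz

    report.removed = n_remove
    report.redeposited = placed_total
    report.biofilm_after = int(np.count_nonzero(out.codes == BIOFILM))
    report.patches = patches
    return out, report


# ---------------------------------------------------------------------------
# attenuation assignment
# ---------------------------------------------------------------------------

#: mean linear attenuation per voxel traversal, arbitrary consistent units.
#: feso4: biofilm slightly brighter than liquid (iron bound in the EPS);
#: baso4: liquid brightest (suspension fills the pores), biofilm darkest.
ATTENUATION = {
    "feso4": {OUTSIDE: 0.0, AIR: 0.004, LIQUID: 0.010, BIOFILM: 0.013,
              SOLID: 0.018},
    # the barium suspension is strongly attenuating (high-Z): the liquid
    # stands far above the solid, and the unstained biofilm (mostly water)
    # sits well below it — wide separations are what make this regime give
    # "clear contrast" despite thin-film partial-volume blurring
    "baso4": {OUTSIDE: 0.0, AIR: 0.002, BIOFILM: 0.005, SOLID: 0.013,
              LIQUID: 0.026},
}

_HETEROGENEITY_SCALE_VOX = 2.0


def assign_attenuation(labels: LabelVolume, contrast_mode: str,
                       spec: PhantomSpec) -> VolumeImage:
    """Map phase codes to linear attenuation coefficients.

    In ``feso4`` mode the biofilm carries a multiplicative smooth random
    field of relative std ``spec.biofilm_heterogeneity`` (the heterogeneous
    iron loading of the EPS); phase mean ordering is preserved:
    liquid < biofilm < solid (feso4) and biofilm < solid < liquid (baso4).
    """
    if contrast_mode not in ATTENUATION:
        raise ValueError(f"unknown contrast_mode {contrast_mode!r}")
    table = ATTENUATION[contrast_mode]
    mu = np.zeros(labels.shape, dtype=np.float64)
    for code, value in table.items():
        mu[labels.codes == code] = value
    if spec.biofilm_heterogeneity > 0:
        mode_id = {"feso4": 1, "baso4": 2}[contrast_mode]
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 0xA77, mode_id]))
        noise = ndimage.gaussian_filter(
            rng.standard_normal(labels.shape), _HETEROGENEITY_SCALE_VOX)
        noise /= max(noise.std(), 1e-12)
        noise -= noise.mean()
        fld = np.clip(1.0 + spec.biofilm_heterogeneity * noise, 0.05, None)
        bf = labels.codes == BIOFILM
        mu[bf] *= fld[bf]
    return VolumeImage(mu, labels.spacing_um, "attenuation",
                       {"contrast_mode": contrast_mode,
                        "units": "attenuation per voxel traversal (arbitrary)"})
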
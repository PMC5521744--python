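"""Multiphase segmentation of reconstructed tomograms.

Two chains, one per contrast regime:

* ``feso4`` — contrast enhancement -> 3D curvature-driven diffusion ->
  gray-value histogram -> inflection-point threshold between the liquid peak
  and the biofilm shoulder (with a +/- sensitivity band) -> label cleanup.
* ``baso4`` — diffusion -> seeded region growing for the solid phase (robust
  to beam-hardening cupping) -> liquid/biofilm thresholding inside the
  non-solid mask -> label cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.morphology import ball

from .core import (AIR, BIOFILM, LIQUID, OUTSIDE, SOLID, LabelVolume,
                   VolumeImage, column_mask)

__all__ = [
    "DiffusionSettings",
    "HistogramModel",
    "ThresholdSet",
    "enhance_contrast",
    "curvature_diffusion",
    "compute_histogram",
    "find_thresholds",
    "seeded_region_growing",
    "clean_labels",
    "segment_volume",
]

#: explicit-scheme stability bound for 3D second-order stencils
_MAX_TIME_STEP = 1.0 / 6.0


@dataclass
class DiffusionSettings:
    """Edge-preserving smoothing parameters.

    ``sharpness`` sets the edge-stopping gradient threshold (higher = more
    edge preservation); ``anisotropy`` blends mean-curvature flow against
    isotropic diffusion.  Defaults follow the conventional 5-iteration run
    with sharpness 0.9 and anisotropy 0.6.
    """

    iterations: int = 5
    sharpness: float = 0.9
    anisotropy: float = 0.6
    time_step: float = 0.15

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if not 0 <= self.sharpness <= 1 or not 0 <= self.anisotropy <= 1:
            raise ValueError("sharpness and anisotropy must lie in [0, 1]")
        if not 0 < self.time_step <= _MAX_TIME_STEP:
            raise ValueError(
                f"time_step must lie in (0, {_MAX_TIME_STEP:.4f}] for the "
                "explicit scheme to be stable")


@dataclass
class HistogramModel:
    """256-bin gray-value histogram with a smoothed curve and annotations."""

    bin_edges: np.ndarray          # 257 edges covering [0, 255]
    counts: np.ndarray
    smoothed: np.ndarray
    peak_modes: list[int]          # gray values of detected modes, ascending
    shoulder_interval: tuple[int, int] | None


@dataclass
class ThresholdSet:
    """Central inflection threshold plus the low/high sensitivity pair."""

    center: int
    low: int
    high: int
    offset_fraction: float = 0.12
    fallback_used: bool = False

    @classmethod
    def from_center(cls, center: int, offset_fraction: float = 0.12,
                    fallback_used: bool = False) -> "ThresholdSet":
        offset = max(1, round(offset_fraction * center))
        return cls(center=center, low=center - offset, high=center + offset,
                   offset_fraction=offset_fraction, fallback_used=fallback_used)

    def __post_init__(self) -> None:
        if not self.low < self.center < self.high:
            raise ValueError("thresholds must satisfy low < center < high")


# ---------------------------------------------------------------------------
# contrast enhancement
# ---------------------------------------------------------------------------

def enhance_contrast(volume: VolumeImage, saturate_fraction: float = 0.004
                     ) -> VolumeImage:
    """Linear rescale to [0, 255] with ``saturate_fraction`` of the voxels
    clipped symmetrically at the extremes; rank order is preserved for
    unclipped voxels."""
    if not 0 <= saturate_fraction <= 0.05:
        raise ValueError("saturate_fraction must lie in [0, 0.05]")
    v = volume.values
    out = volume.copy()
    lo = np.quantile(v, saturate_fraction / 2.0)
    hi = np.quantile(v, 1.0 - saturate_fraction / 2.0)
    if hi <= lo:  # constant (or near-constant) input
        out.values = np.full_like(v, 127.5)
        out.intensity_semantics = "reconstructed-gray"
        out.metadata = dict(out.metadata, enhance_contrast="degenerate-constant")
        return out
    out.values = np.clip((v - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    out.intensity_semantics = "reconstructed-gray"
    out.metadata = dict(out.metadata, saturate_fraction=saturate_fraction)
    return out


# ---------------------------------------------------------------------------
# curvature-driven diffusion
# ---------------------------------------------------------------------------

def _mean_curvature_motion(u: np.ndarray, eps: float) -> np.ndarray:
    """kappa * |grad u| via central differences (level-set curvature flow)."""
    uz, uy, ux = np.gradient(u)
    uzz, uzy, uzx = np.gradient(uz)
    _, uyy, uyx = np.gradient(uy)
    uxx = np.gradient(ux, axis=2)
    g2 = uz ** 2 + uy ** 2 + ux ** 2
    num = (ux ** 2 * (uyy + uzz) + uy ** 2 * (uxx + uzz)
           + uz ** 2 * (uxx + uyy)
           - 2.0 * (ux * uy * uyx + ux * uz * uzx + uy * uz * uzy))
    return num / (g2 + eps)


def curvature_diffusion(volume: VolumeImage,
                        settings: DiffusionSettings | None = None
                        ) -> VolumeImage:
    """Iterative 3D edge-preserving smoothing.

    Each explicit step applies an edge-stopping conductance
    g = exp(-(|grad u| / K)^2) to a blend of mean-curvature motion
    (weight = anisotropy) and isotropic diffusion (weight = 1 - anisotropy).
    K is (1 - sharpness) times the data range, so sharpness ~ 1 freezes
    strong edges.  The output is clamped to the input min/max (discrete
    maximum principle).
    """
    settings = settings or DiffusionSettings()
    out = volume.copy()
    if settings.iterations == 0:
        return out
    u = out.values
    vmin, vmax = float(u.min()), float(u.max())
    vrange = vmax - vmin
    if vrange == 0:
        return out
    k_edge = max((1.0 - settings.sharpness) * vrange, 1e-12 * vrange)
    eps = (1e-6 * vrange) ** 2
    for _ in range(settings.iterations):
        gz, gy, gx = np.gradient(u)
        gmag2 = gz ** 2 + gy ** 2 + gx ** 2
        conduct = np.exp(-gmag2 / (k_edge ** 2))
        lap = ndimage.laplace(u, mode="nearest")
        mcm = _mean_curvature_motion(u, eps)
        u = u + settings.time_step * conduct * (
            settings.anisotropy * mcm + (1.0 - settings.anisotropy) * lap)
        np.clip(u, vmin, vmax, out=u)
    out.values = u
    out.metadata = dict(out.metadata, diffusion_iterations=settings.iterations)
    return out


# ---------------------------------------------------------------------------
# histogram + thresholds
# ---------------------------------------------------------------------------

def compute_histogram(volume: VolumeImage, mask: np.ndarray,
                      smoothing_bandwidth: float = 2.0,
                      peak_prominence_frac: float = 0.02) -> HistogramModel:
    """256-bin gray-value histogram of the masked voxels.

    The smoothed curve (Gaussian kernel over bins) drives mode detection;
    the shoulder interval annotates the right flank of the lowest (liquid)
    mode up to the following valley.
    """
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.clip(np.round(volume.values[mask]), 0, 255).astype(np.intp)
    counts = np.bincount(vals, minlength=256)
    edges = np.arange(257) - 0.5
    smoothed = ndimage.gaussian_filter1d(counts.astype(np.float64),
                                         smoothing_bandwidth)
    peaks, _ = signal.find_peaks(
        smoothed, prominence=peak_prominence_frac * smoothed.max())
    modes = sorted(int(p) for p in peaks)
    shoulder = _shoulder_interval(smoothed, modes)
    return HistogramModel(edges, counts, smoothed, modes, shoulder)


def _shoulder_interval(smoothed: np.ndarray, modes: list[int]
                       ) -> tuple[int, int] | None:
    """Interval of the biofilm shoulder on the right flank of the liquid
    (lowest) mode: bracketed by the convex-onset inflection of the flank and
    the concave-onset inflection of the shoulder bump."""
    if len(modes) < 2:
        return None
    lo_m, hi_m = modes[0], modes[-1]
    d2 = np.gradient(np.gradient(smoothed))
    c1 = next((g for g in range(lo_m + 1, hi_m) if d2[g - 1] < 0 <= d2[g]),
              None)
    if c1 is None:
        return None
    c2 = next((g for g in range(c1 + 1, hi_m) if d2[g - 1] >= 0 > d2[g]),
              None)
    if c2 is None:
        c2 = c1
    # a shoulder is an elevated bridge on the peak flank; if the density
    # between the inflections collapses to ~zero the modes are simply
    # separated and there is no shoulder to split
    if smoothed[c1:c2 + 1].min() < 0.05 * smoothed[lo_m]:
        return None
    return (c1, c2)


def find_thresholds(hist: HistogramModel, offset_fraction: float = 0.12
                    ) -> ThresholdSet:
    """Central threshold between the liquid-phase peak and the biofilm
    shoulder, plus the sensitivity pair at center -/+
    round(offset_fraction * center).

    The center is the midpoint of the shoulder interval bracketed by the
    two inflection points of the smoothed histogram (liquid-flank convexity
    onset and shoulder-bump concavity onset); the sensitivity pair then
    spans roughly the lower and upper ends of the shoulder region.  Falls
    back to the inter-mode valley (``fallback_used=True``) when no
    inflection exists in the search window; fails on a unimodal histogram.
    """
    modes = hist.peak_modes
    if len(modes) < 2:
        raise ValueError("histogram is unimodal; cannot separate liquid and "
                         "solid modes")
    liquid_mode, solid_mode = modes[0], modes[-1]
    shoulder = hist.shoulder_interval
    if shoulder is None:
        shoulder = _shoulder_interval(hist.smoothed, modes)
    fallback = shoulder is None
    if fallback:  # no inflection: perfectly separated modes, use the valley
        center = liquid_mode + int(
            np.argmin(hist.smoothed[liquid_mode:solid_mode + 1]))
    else:
        center = (shoulder[0] + shoulder[1]) // 2
    return ThresholdSet.from_center(int(center), offset_fraction,
                                    fallback_used=fallback)


# ---------------------------------------------------------------------------
# seeded region growing
# ---------------------------------------------------------------------------

_CONN6 = ndimage.generate_binary_structure(3, 1)
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def seeded_region_growing(volume: VolumeImage | np.ndarray,
                          seeds: list[tuple[int, int, int]] | np.ndarray,
                          tolerance: float,
                          allowed: np.ndarray | None = None) -> np.ndarray:
    """6-connected flood from the seeds accepting voxels whose intensity
    stays within ``tolerance`` of the running region mean.

    The running mean tracks slow intensity drift (beam-hardening cupping)
    while sharp phase boundaries stop the growth.  Growth proceeds in
    frontier batches; the mean is updated after each batch.
    """
    v = volume.values if isinstance(volume, VolumeImage) else np.asarray(volume)
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    seeds = np.asarray(seeds, dtype=np.intp)
    if seeds.size == 0:
        raise ValueError("empty seed list")
    if seeds.ndim != 2 or seeds.shape[1] != 3:
        raise ValueError("seeds must be a list of (z, y, x) voxels")
    if np.any(seeds < 0) or np.any(seeds >= np.array(v.shape)):
        raise ValueError("seed out of bounds")
    region = np.zeros(v.shape, dtype=bool)
    region[tuple(seeds.T)] = True
    if allowed is not None:
        region &= allowed
        if not region.any():
            raise ValueError("no seed lies inside the allowed mask")
    total = float(v[region].sum())
    count = int(region.sum())
    while True:
        mean = total / count
        frontier = ndimage.binary_dilation(region, _CONN6) & ~region
        if allowed is not None:
            frontier &= allowed
        accept = frontier & (np.abs(v - mean) <= tolerance)
        n_new = int(accept.sum())
        if n_new == 0:
            break
        region |= accept
        total += float(v[accept].sum())
        count += n_new
    return region


# ---------------------------------------------------------------------------
# label cleanup
# ---------------------------------------------------------------------------

def clean_labels(labels: LabelVolume, closing_radius: int = 1,
                 min_component_vox: int = 27) -> LabelVolume:
    """Morphological cleanup shared by both chains, in a fixed order:
    per-phase closing (solid, biofilm, liquid priority) -> small disconnected
    liquid/biofilm components merged into their majority-neighbor phase ->
    all air components merged into the liquid phase.

    The pass is repeated until the labels stop changing (a handful of
    iterations in practice), which makes the operation idempotent.
    """
    out = _clean_pass(labels, closing_radius, min_component_vox)
    for _ in range(4):
        nxt = _clean_pass(out, closing_radius, min_component_vox)
        if np.array_equal(nxt.codes, out.codes):
            break
        out = nxt
    return out


def _clean_pass(labels: LabelVolume, closing_radius: int,
                min_component_vox: int) -> LabelVolume:
    out = labels.copy()
    mask = out.mask()
    codes = out.codes

    if closing_radius > 0:
        selem = ball(closing_radius)
        closed = {}
        for phase in (SOLID, BIOFILM, LIQUID):
            m = codes == phase
            if m.any():
                closed[phase] = ndimage.binary_closing(m, structure=selem)
        claimed = np.zeros(codes.shape, dtype=bool)
        for phase in (SOLID, BIOFILM, LIQUID):  # fixed priority
            if phase not in closed:
                continue
            new = closed[phase] & mask & ~claimed
            codes[new & (codes != AIR)] = phase
            claimed |= new

    # small disconnected liquid / biofilm segments -> majority neighbor
    for phase in (BIOFILM, LIQUID):
        m = codes == phase
        if not m.any():
            continue
        lab, n = ndimage.label(m, structure=_CONN26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        small_ids = np.nonzero((sizes > 0) & (sizes < min_component_vox))[0]
        small_ids = small_ids[small_ids > 0]
        for comp_id in small_ids:
            comp = lab == comp_id
            ring = ndimage.binary_dilation(comp, _CONN26) & ~comp & mask
            neigh = codes[ring]
            neigh = neigh[(neigh != phase) & (neigh != OUTSIDE)]
            if neigh.size == 0:
                continue
            majority = np.bincount(neigh).argmax()
            codes[comp] = majority

    # air bubbles -> liquid
    codes[codes == AIR] = LIQUID
    return out


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------

def _auto_seeds(v: np.ndarray, mask: np.ndarray, n_seeds: int = 10
                ) -> np.ndarray:
    """Automatic solid seeds for the baso4 chain: local maxima of the
    distance transform of a provisional mask that excludes the bright
    (liquid) voxels."""
    from skimage.filters import threshold_multiotsu
    vals = v[mask]
    t_lo, t_hi = threshold_multiotsu(vals, classes=3)
    provisional = mask & (v > t_lo) & (v <= t_hi)
    dist = ndimage.distance_transform_edt(provisional)
    flat = dist.ravel()
    order = np.argsort(-flat)[: max(n_seeds * 50, n_seeds)]
    picked: list[np.ndarray] = []
    coords = np.array(np.unravel_index(order, dist.shape)).T
    for c in coords:
        if len(picked) >= n_seeds:
            break
        if dist[tuple(c)] <= 1.0:
            break
        if picked and np.min(np.sum((np.array(picked) - c) ** 2, axis=1)) < 25:
            continue
        picked.append(c)
    if not picked:
        raise ValueError("no solid seed candidates found")
    return np.asarray(picked)


def segment_volume(volume: VolumeImage, mode: str,
                   thresholds: ThresholdSet | None = None,
                   solid_params: dict | None = None,
                   cleanup: dict | None = None,
                   mask: np.ndarray | None = None) -> LabelVolume:
    """Segment a preprocessed (enhanced + diffused) 8-bit volume into
    solid / liquid / biofilm inside the column mask.

    feso4: solid above a high histogram threshold, biofilm in
    [center, solid threshold), liquid below center.  baso4: solid by seeded
    region growing, then liquid (bright) vs biofilm (dark) thresholding
    inside the non-solid mask.  Both finish with :func:`clean_labels`.
    """
    if mode not in ("feso4", "baso4"):
        raise ValueError(f"unknown segmentation mode {mode!r}")
    v = volume.values
    if mask is None:
        mask = column_mask(v.shape)
    solid_params = dict(solid_params or {})
    cleanup = dict(cleanup or {})

    hist = compute_histogram(volume, mask)
    if thresholds is None:
        thresholds = find_thresholds(hist)

    codes = np.full(v.shape, OUTSIDE, dtype=np.uint8)
    if mode == "feso4":
        solid_thr = solid_params.get("threshold")
        if solid_thr is None:
            # biofilm/solid boundary: Otsu over the voxels above the center
            from skimage.filters import threshold_otsu
            upper = v[mask & (v >= thresholds.center)]
            solid_thr = float(threshold_otsu(upper))
        solid = mask & (v >= solid_thr)
        biofilm = mask & ~solid & (v >= thresholds.center)
        liquid = mask & ~solid & ~biofilm
        codes[solid] = SOLID
        codes[biofilm] = BIOFILM
        codes[liquid] = LIQUID
    else:
        seeds = solid_params.get("seeds")
        if seeds is None:
            seeds = _auto_seeds(v, mask, solid_params.get("n_seeds", 10))
        tol = solid_params.get("tolerance")
        if tol is None:
            # stay well inside the gap between the solid level and the
            # nearest other class (leakage across blurred boundaries is the
            # dominant failure mode of intensity flooding)
            from skimage.filters import threshold_multiotsu
            t_lo, t_hi = threshold_multiotsu(v[mask], classes=3)
            mid_modes = [m for m in hist.peak_modes if t_lo < m < t_hi]
            solid_level = (float(mid_modes[0]) if mid_modes else
                           float(np.median(v[tuple(np.asarray(seeds).T)])))
            tol = 0.4 * min(solid_level - t_lo, t_hi - solid_level)
            tol = max(tol, 1.0)
        solid = seeded_region_growing(v, seeds, tol, allowed=mask)
        rest = mask & ~solid
        split = solid_params.get("liquid_threshold")
        if split is None:
            from skimage.filters import threshold_otsu
            split = threshold_otsu(v[rest]) if rest.any() else 128.0
        # partial-volume boundary shell: the conservative growing tolerance
        # leaves interface voxels with intermediate gray outside the region;
        # reclaim those that are adjacent to solid and closer in intensity
        # to the solid level than to either of the other class levels
        solid_level = float(np.median(v[solid])) if solid.any() else 0.0
        bright = rest & (v >= split)
        liq_level = float(np.median(v[bright])) if bright.any() else 255.0
        # reclaim the partial-volume shell: down to the growing tolerance on
        # the dark side, and 40% of the way toward the liquid level on the
        # bright side — biofilm patches (well below the tolerance band)
        # are not swallowed
        near_solid = ((v >= solid_level - tol)
                      & (v < solid_level + 0.4 * (liq_level - solid_level)))
        for _ in range(4):
            shell = (ndimage.binary_dilation(solid, _CONN26) & ~solid
                     & mask & near_solid)
            if not shell.any():
                break
            solid |= shell
        rest = mask & ~solid
        codes[solid] = SOLID
        codes[rest & (v >= split)] = LIQUID
        codes[rest & (v < split)] = BIOFILM
    labels = LabelVolume(codes, volume.spacing_um)
    return clean_labels(labels, **cleanup)
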
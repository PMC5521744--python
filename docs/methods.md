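# Methods

`biofilmct` simulates and analyses laboratory X-ray micro-CT experiments on
biofilm-colonized granular columns. It exists so that every stage of the
imaging-and-quantification chain — radiograph formation, Lorentzian
pre-reconstruction filtering, filtered back-projection, multiphase
segmentation, affine registration of paired scans, and volumetric
morphometrics — can be exercised and validated against a phantom whose
ground truth is known exactly.

## The physical setting being emulated

A PMMA column of 10 mm inner diameter is wet-packed with 2.5 mm spherical
ion-exchange grains (initial porosity φ ≈ 0.40) and colonized by a biofilm
under continuous flow (5 mL/min, Darcy velocity q = Q/A ≈ 1.06 mm/s, pore
velocity v_p = q/φ ≈ 2.65 mm/s, Re = qd/ν ≈ 2.65, Pe = qd/D ≈ 1000). Two
contrast regimes distinguish biofilm from pore water, whose attenuation it
nearly matches:

* **FeSO₄ regime** — iron sulfate (56 mg/L FeSO₄ = 0.37 mmol/L; 20.6 mg/L
  Fe, 35.4 mg/L SO₄) is supplied during growth and binds into the EPS
  matrix, so the *biofilm* is marked: slightly brighter than the liquid,
  with strong internal heterogeneity. Contrast is weak, so the scan uses a
  long propagation distance (edge-enhancing refraction fringes) and the
  radiographs are low-pass filtered before reconstruction.
* **BaSO₄ regime** — a barium sulfate suspension injected after growth
  marks the *liquid* (brightest phase; biofilm darkest). The high-Z
  suspension causes beam-hardening cupping, and its injection shears off
  part of the biofilm.

## Pipeline stages

### Phantom (`phantom.py`)

Grain pack: candidate sphere centers on a jittered hexagonal-close-packed
lattice, relaxed by pair-repulsion sweeps until the hard-sphere constraint
holds, then inserted in random order with overlap rejection until the
target porosity is reached. Pure random sequential addition was tried first
and jams near 38 % solid — far below the ~60 % solid of a wet packing — so
lattice seeding is load-bearing, not cosmetic. Sphere centers may sit up to
0.45 d beyond the wall (truncated caps); without that the wall shell, 44 %
of the cross-section at column/grain = 4, cannot be filled. The achieved
porosity is reported, and the packer fails loudly naming it if the target
is out of reach (tolerance 0.03).

Biofilm: a constrained dilation of the grain surface. A liquid voxel turns
to biofilm when its Euclidean distance to solid falls below a spatially
correlated random thickness field; the base thickness is bisected until the
requested biofilm fraction (default 0.10 of column volume) is met within
0.005. Components not 26-connected to a grain surface are pruned. The
thickness field has relative std 1.0 and correlation length 4 voxels,
giving *patchy* coverage: part of the surface bare, the rest carrying
patches several voxels thick. The study gives no thickness distribution;
patchiness is chosen because (a) observed biofilm is corrugated and patchy,
and (b) a uniform 2-voxel film partial-volumes to the gray level of its
substrate and is unresolvable at any threshold — a film phantom would make
every segmentation test meaningless.

Detachment (BaSO₄ injection surrogate): removes a washout fraction
(default 0.5) of biofilm voxels ordered by distance from the solid — outer,
liquid-facing layers first, basal layers retained — and re-places a
redeposit fraction (default 0.2) as roughly spherical patches at liquid
sites strictly downstream (larger z) of the centroid of the removed
material they came from. Voxel bookkeeping is exact
(removed = before − after + redeposited) and returned as a report. This is
a stochastic geometric perturbation, not a mechanical model: no shear
fields, no adhesion kinetics.

Attenuation: per-phase mean linear attenuation per voxel traversal
(arbitrary consistent units). FeSO₄: liquid 0.010 < biofilm 0.013 < solid
0.018, with a multiplicative smooth random field (relative std =
`biofilm_heterogeneity`, default 0.15) on the biofilm. BaSO₄: biofilm
0.005 < solid 0.013 < liquid 0.026 — wide separations, as expected from a
high-Z suspension against unstained, mostly-water biofilm.

### Tomography (`tomography.py`)

Geometry is **parallel-beam and slice-wise**: the rotation axis is the
streamwise z axis, each z slice is projected independently
(`skimage.transform.radon`), and cone-beam magnification is absorbed into
the effective pixel size. This is the largest simplification in the
package: FBP is exact in this geometry, so reconstruction-error budgets
measure the pipeline, not cone-beam artifacts. Intensities follow
Beer–Lambert, I = I₀·exp(−∫µ).

Degradations applied in physical order on intensity frames:

* **Edge fringes** (long-propagation surrogate): I ← I − s·∇²I per frame.
  One overshoot/undershoot pair per edge, the signal the Lorentzian filter
  acts on. Default s = 0.1 for the long-distance scan, 0 for the short
  one — propagation distance is what creates fringes.
* **Beam hardening**: line integrals compressed, t′ = t − c·t² (default
  c = 0.12, BaSO₄ scan only), rejected as an error if non-monotone over the
  data range. Yields the classic cupping after FBP.
* **Noise**: per-pixel Poisson at an expected flat-field count (default
  1e5, representative of a multi-frame-averaged flat-panel acquisition),
  optional Gaussian read noise, and a smooth per-angle multiplicative
  source drift (default amplitude 5 %). Deterministic given a seed; all
  other stages are noise-free by construction.

Reconstruction: slice-wise ramp-filtered back-projection
(`skimage.transform.iradon`), line-integral conversion with an intensity
floor of 1e-6·I₀ before the log. Default apodization is Shepp–Logan: at
desk-scale grids (64–96 px) a Hann window costs ~10 % NRMSE on a uniform
disk, right at the accuracy budget, while Shepp–Logan keeps it near 7 %
with nearly the same noise behavior.

### Lorentzian filter (`preprocess.py`)

Each radiograph's 2-D Fourier transform is multiplied by
1/(α|k⊥|² + 1) and transformed back: unit DC gain (the image mean is
conserved exactly), zero phase (edges are not displaced), attenuation
monotone in |k⊥| and in α. It derives from single-distance phase-retrieval
theory but is used strictly as an image-processing step, always on
projections before reconstruction, never on slices.

α is quoted in a stated frequency convention, because its numeric value is
meaningless without one. Two are supported: `dft-grid` (default; k = 2π ×
integer cycle count across the frame) and `rad-per-pixel`. Under the
default convention α = 1.5e-6 places the half-power radius at ≈ 130 cycles,
i.e. strong noise suppression with intact edges on detector-sized
(~2000 px) radiographs, which is the regime the default emulates. The
convention-free way to choose α for any other frame size or noise level is
the diagnostics workflow (`filter_diagnostics`): filter a reference frame
over an α ladder and read off the flat-region noise ratio (want ≥ 2) and
the edge-gradient-peak shift (want ≤ 1 px); over-blurring is monotone in α,
so the smallest α meeting the noise target is the choice.

Frames with odd side length are reflection-padded one row/column before the
FFT and cropped after, and the mean is restored exactly — zero-padding was
rejected because it biases the DC term.

Normalization: each frame is scaled by one constant so its reference
statistic (whole-frame mean, or an air-annulus mean at the detector
margins) matches the stack-wide mean, removing source drift while
preserving within-frame contrast ratios exactly.

### Segmentation (`segment.py`)

FeSO₄ chain: linear contrast enhancement to [0, 255] with 0.4 % symmetric
saturation → 3-D curvature-driven diffusion → 256-bin histogram of the
in-column voxels → thresholds → cleanup.

The diffusion step is an explicit scheme,
u ← u + Δt·g(|∇u|)·[a·κ|∇u| + (1−a)·∇²u], with edge-stopping conductance
g = exp(−(|∇u|/K)²), K = (1 − sharpness)·range. Defaults: 5 iterations,
sharpness 0.9, anisotropy a = 0.6, Δt = 0.15 (stability bound 1/6,
enforced). The output is clamped to the input range (discrete maximum
principle). The commercial filter this emulates documents only its
parameter names and its observable contract — noise down ≥ 2×, edges within
1 voxel — which is what the tests pin.

Thresholds: the liquid peak carries the biofilm as a right-hand shoulder.
The smoothed histogram's second derivative gives two inflections between
the liquid mode and the shoulder bump — convexity onset of the flank and
concavity onset of the shoulder; the central threshold is their midpoint,
and the sensitivity pair sits at center ∓ round(0.12·center), spanning
roughly the shoulder's ends (a center of 73 gives the triplet 64/73/82).
The offset default is 0.12 rather than the nominal "about 10 %" because
0.12 is what reproduces that printed triplet. If the inter-mode density
collapses (no shoulder), the valley is used and flagged `fallback_used`.
The solid/biofilm boundary is Otsu over the voxels above the center; the
sensitivity band varies only the liquid/biofilm split, sharing one solid
threshold, so the three biofilm masks are nested (lower threshold → more
biofilm — the shaded-band construction of the streamwise profiles).

BaSO₄ chain: the solid is grown by 6-connected seeded region growing
accepting voxels within a tolerance of the running region mean — robust to
the slow radial cupping drift but stopped by phase boundaries. Seeds are
automatic (distance-transform maxima of the multi-Otsu middle class);
tolerance defaults to 0.4 × the distance from the solid mode to the nearest
class cut. The conservative tolerance leaves the partial-volume shell
outside the region, so interface voxels adjacent to the solid and with gray
between the solid level and 40 % of the way to the liquid level are
reclaimed (bounded to 4 dilation passes). Liquid (bright) and biofilm
(dark) are then split by Otsu inside the non-solid mask.

Cleanup (both chains): per-phase morphological closing (ball radius 1,
priority solid > biofilm > liquid), 26-connected liquid/biofilm components
below 27 voxels merged into their majority neighbor, and all air merged
into liquid (bubbles formed during flushing are not a phase of interest).
The pass repeats to a fixed point, making the operation idempotent. The
order closing → component merge → bubble merge is a fixed choice.

### Registration (`register.py`)

Paired tomograms are aligned on their **solid phases** — the phase the two
regimes agree on — by a 12-parameter affine transform minimizing mean
squared error, optimized by regular-step gradient descent (step halving on
metric increase) with a 2-level multi-resolution pyramid and identity
initialization. Masks are Gaussian-smoothed (σ = 1 voxel) first so the
binary metric has a usable gradient. The optimization is delegated to
SimpleITK, which implements exactly this optimizer/metric pair; transforms
are stored in (z, y, x) voxel coordinates with a convergence record.
Resolution matching uses `resample` (nearest for labels — no new codes —
linear for intensities). Recovery accuracy on phantom masks: known
translations to ≈ 0.03 voxels, 4° rotation + translation to < 0.1 voxel
mean displacement, degrading gracefully to ≤ 1 voxel under 5 % label-flip
noise.

### Quantification (`quantify.py`)

Voxel-count phase fractions (exact rational arithmetic on counts; no
partial-volume weighting) over the in-column domain; per-slice streamwise
profiles with the biofilm sensitivity band; conditional overlap tables
P(A|B) = |A∩B|/|B| over the intersection of both registered column masks,
with joint counts retained, per-conditioning-phase sums exactly 1, and
absent conditioning phases flagged undefined rather than reported as 0.
The worked numbers (Darcy/pore velocity, Re, Pe, FeSO₄ speciation from
fixed formula masses Fe 55.845 / S 32.065 / O 15.999 g/mol) are pure
functions reported at full precision; the Pe default diffusivity
2.65e-9 m²/s is an inference consistent with Pe ≈ 1000, not an
independently sourced constant. Wall shear for a power-law fluid in an
idealized cylindrical pore follows Rabinowitsch–Mooney,
τ_w = K·((3n+1)/(4n)·8u/d)ⁿ; the suspension-vs-water ratio helper is a
demonstration with user-supplied (K, n), since the suspension's rheological
constants are not pinned here.

### Orchestration (`pipeline.py`)

One serializable `RunConfig` drives three scenarios: `feso4` (filter ON,
inflection thresholding + band), `baso4` (filter OFF, hardening ON, seeded
growing), `paired-comparison` (both scans of one phantom, detachment before
the second, registration, overlap tables). Per-stage seeds derive from the
global seed by a stable CRC hash of the stage name; identical config + seed
reproduces byte-identical outputs. All intermediates are written
(projections, filtered projections, reconstructions, label volumes,
profiles, transform) with SHA-256 checksums in a manifest, so any
diagnostic figure-style comparison is recoverable from disk.

## Desk-scale choices and what they mean

The study conditions are emulated at 96³ voxels (≈ 104 µm/voxel), 180
projections over 360°, against the real ~2000² × 1441-projection scans at
9–21 µm. Three scenario defaults exist specifically because of that scale
gap, and would be relaxed at realistic resolution:

* **Matched-resolution paired scans.** Real grains span ~278 voxels, ours
  32; resampling a 2× coarser second scan makes interface partial-volume
  voxels ~40 % of the solid and caps solid-phase overlap near 0.85 for any
  method. The coarser-second-scan path (`scan2_downsample = 2`) exists and
  is tested, but the default comparison is at matched resolution.
* **Whole-voxel repositioning between scans.** Sub-voxel or rotational
  repositioning costs boundary-shell overlap through nearest-neighbour
  resampling alone; rotation recovery is instead verified directly on the
  registration module (4°, < 1 voxel mean displacement).
* **32-voxel grains** (column/grain 3 instead of the packing's 4), so grain
  surfaces span enough voxels for phase statistics to measure the method
  rather than voxelization.

What passing tests show: the chain recovers known phase fractions through
simulated projection, filtering, reconstruction and segmentation (every
FeSO₄ phase within 3 points, BaSO₄ solid within 4), preserves the
detachment signature as asymmetric biofilm overlap, and keeps solid-phase
overlap above 90 % both ways. What they do not show: performance on real
cone-beam data, real detector physics (scatter, blur, rings), real biofilm
microstructure, or any chemistry — the phantom is a geometric emulation
whose noise and contrast levels are stated, fixed choices.

## Numerical conventions

Arrays are (z, y, x), z streamwise, downstream = increasing z. Angles are
degrees at interfaces, radians internally; rotation is about z. Label codes:
0 outside, 1 solid, 2 liquid, 3 biofilm, 4 air; voxels outside the inscribed
column cylinder are always 0. Intensity frames are non-negative; the
line-integral conversion floors I/I₀ at 1e-6. Connectivity: 26 for
component analysis and coating connectivity, 6 for region growing
(conservative growth, permissive merging). Phase fractions and overlap
probabilities are computed on integer counts; their unit-sum invariants are
exact, not approximate.
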
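# Methods

This note documents the models and procedures `nisslsplit` implements, the
parameters that matter, the synthetic test bed, and the numerical choices
made where the design was genuinely open.

## Imaging model and gray ordering

The package assumes reflected bright-field imaging of a resin-embedded,
thionine-stained brain, sectioned and imaged at ~1 µm axial sampling.
Nucleic-acid-rich material takes up stain and appears **dark**; the vessel
lumen retains no stain and appears **bright**; unstained neuropil
(parenchyma) sits in between. The resulting intensity ordering —

vessel  >  plaque rim  >  parenchyma  >  process band  >  soma / plaque core / tract

— is the entire basis of virtual channel splitting. Amyloid plaques are
distinctive because they violate monotonicity locally: a dark core is
surrounded by a rim *paler than the parenchyma*, so a line profile through
a plaque looks like a "W". All detectors are intensity-ordering based;
none are learned.

Axis 0 is the sectioning (depth) axis; axes 1–2 are in-plane. Spacing in
µm is carried on every `Volume` and always supplied by the caller: TIFF
spacing tags are dialect-ridden, so a tag/config disagreement only logs a
warning and the config wins.

## Preprocessing

Steps run in a fixed order — background, periodic noise, contrast — and
each can be switched off.

**Background correction** estimates a smooth per-slice multiplicative
field and divides it out, then rescales so the *global* median is
preserved. The field is estimated from block-wise medians (block = 1/8 of
the `window_um` parameter, default 250 µm): a median over a block rejects
any structure occupying less than half of it, and, being an average of
~10³ voxels, is essentially noise-free. This matters: a morphological
(closing/opening) estimator carries an additive noise-envelope bias of
several gray levels, which is *not* removed by a multiplicative division
and leaks a slice-gain-dependent error into the corrected stack. Residual
dips/bumps from structures larger than one block (tracts, the largest
plaques) are removed by a 3×3 closing/opening on the coarse block grid
before Gaussian smoothing (σ = window/4) and bilinear upsampling.
`window_um` should exceed the largest genuine structure; default 250 µm
against ~50–70 µm tracts/plaques.

A wholly flat slice is handled without division by zero; like every other
slice its values end up on the common global-median scale (a flat slice
has no internal structure to preserve, and leaving it on its own gain
would defeat the slice-gain correction the step exists for).

**Periodic-noise removal** runs per slice in the 2D Fourier domain. A
"narrow peak" is a bin whose magnitude exceeds `peak_factor` (default 8)
times the local spectral floor (9×9 median of the magnitude spectrum),
outside a 3-bin guard disk around DC. Up to `max_peaks` peaks are zeroed
together with their conjugates in a ±1-bin notch. Only notched bins are
modified, so stripe-free content passes through bit-for-bit up to
rounding; the local-median criterion keeps smoothly decaying natural
spectra (which are large at low frequency but not *narrow*) untouched.

**Contrast enhancement** is a global percentile stretch to the full bit
range, defaults p_low = 0.05, p_high = 99.95. The bounds are deliberately
extreme: vessels occupy only a fraction of a percent of a brain volume,
and a conventional 0.5/99.5 stretch would saturate the entire vessel
population together with the plaque-rim tail into one clipped value,
destroying the vessel/rim separation the bright band needs. With 0.05/
99.95 at most the top 0.05 % of voxels clip. A degenerate histogram yields
constant mid-gray with a warning, never NaN.

## Band thresholds

`t_dark` and `t_bright` are intensity quantiles of the full histogram
(everything in the frame is tissue in this modality). The defaults
(`dark_quantile = 0.09`, `bright_quantile = 0.9975`) are matched to the
composition of the default phantom: the Nissl-dark population (somata,
plaque cores, tracts) occupies ≈ 10 % of the volume and the vessel lumen
≈ 0.25 %, so these quantiles land in the histogram gaps on either side.
For other data the quantiles should be set from the same reasoning —
slightly above the dark-voxel fraction, and at one minus the expected
vessel fraction; every downstream threshold that is not a quantile is
expressed *relative* to measured contrasts precisely so that this is the
only data-dependent calibration.

## Channel extraction

**Vessels.** Seeds are voxels at/above the `seed_quantile` intensity
(clamped to the bright band, so a volume with no bright content yields an
empty mask with a warning, not an error). Growth is flood fill of
`{v ≥ t_bright − grow_tolerance}` restricted to seed-containing
26-components — provably identical to brute-force BFS flood fill, which
the tests exercise on random fixtures. Components below
`min_component_um3` (default 250 µm³) are dropped. 26-connectivity is used
everywhere: thin bright vessels at 1 µm sampling fragment under
6-connectivity.

**Plaques.** The center–surround score at a voxel is
`mean(annulus rim_inner..rim_outer) − mean(ball core_radius)`, computed
with spacing-aware kernels via shared-FFT convolution; border voxels use
shrunken in-bounds neighbourhoods, and the score is invariant to adding a
constant to the volume. The base kernel (core 5 µm, annulus 5.5–6.5 µm)
only responds to plaques of matching size, so `detect_plaques` sweeps it
over a geometric scale pyramid spanning
`min_diameter_um/2 … max_diameter_um/2` (ratio 1.15) and takes the
voxelwise maximum. The step ratio is chosen against the width of the
annulus "sweet range": with a rim of ~0.4× core radius, an annulus of
1.1–1.3× core radius stays fully inside the rim for a ≈ 1.18-fold range of
scales, so a 1.15 step guarantees at least one scale lands cleanly on
every plaque. Scales whose footprint would exceed 25 voxels are evaluated
on 2ⁿ mean-pooled copies of the volume and upsampled — the usual
scale-space economy, which also keeps the kernel-size practicality bound
honest at every level.

Voxels with score ≥ `min_score` are candidates; each dark 26-component
(`v ≤ t_dark`) touched by a candidate becomes one plaque whose extent is
the **dark core** (not the rim), keeping diameters commensurate with the
<30/30–40/>40 µm classes. Two gates follow: equivalent diameter within
`[min_diameter_um, max_diameter_um]`, and the **pale-rim test** — the
component's peak score must exceed `background − mean_core_gray`
(background = volume median) by `rim_elevation_frac` (default 0.12) of
that same contrast. A rimless dark body (a soma) peaks at ≈
background − core; only a genuinely paler surround lifts the peak above
it. Because the test is a ratio of measured contrasts it is invariant to
any affine intensity map, including the contrast stretch; the same
reasoning puts the pipeline's `min_score` default at 0.75 ×
(t_bright − t_dark).

**Somata and tracts.** Dark components (minus vessel/plaque exclusions,
which must be disjoint) are routed by size and shape: equivalent diameter
within `soma_diameter_range_um` (default 5–18 µm) → soma, with a
`size_class` split at 10 µm flagging the small plaque-associated cells;
equivalent diameter ≥ `tract_min_diameter_um` (30 µm) *and* PCA elongation
(√ of major/minor inertia-eigenvalue ratio) ≥ 2 → tract. Everything else
is discarded.

**Processes.** Voxels strictly inside `(t_dark, t_bright)` are kept where
the middle eigenvalue of the spacing-aware Gaussian Hessian (σ = 1 µm,
units gray/µm²) reaches `tubeness_min` (default 2.0, calibrated so a 2 µm
dark filament at 25 gray contrast scores ≈ 5 while the interior and
surface of dark blobs score ≈ 0–2). Components under 10 voxels are
removed. The eigenvalues are computed with the closed-form trigonometric
method for symmetric 3×3 matrices, vectorised over the volume.

**Fusion** paints channels in increasing precedence so that
vessel > plaque > soma > tract > process wins on overlaps; the result
partitions the union of the inputs and re-fusing the extracted masks is
idempotent. The precedence follows specificity: brighter/rarer channels
are more distinctive.

## Morphometry

* Equivalent diameter `(6V/π)^(1/3)` with `V` = voxel count × voxel
  volume. For digitized spheres of radius ≥ 5 voxels the error is below
  1 %, shrinking with radius.
* Sphericity `π^(1/3)(6V)^(2/3)/A` with `A` from a marching-cubes
  iso-surface of the (padded) component. Naïve face counting was rejected:
  on a digitized ball it converges to 1.5× the true area, which would cap
  sphericity at ≈ 0.67 and make the measure useless for the "plaques are
  rough" comparison; marching-cubes areas give digitized balls ≈ 0.9–1.0.
* Size classes are the half-open bins [0, 30), [30, 40), [40, ∞) µm —
  closed on the left so boundary diameters are assigned deterministically.
* Density grids use floor indexing (upper-boundary centroids clamp into
  the last bin) and conserve the total count exactly; kernel mode smooths
  and renormalises mass.
* Region statistics assign each object by its **centroid** to the first
  region (in argument order) that contains it, making counts additive over
  disjoint unions and border cases unambiguous. Zero-count regions report
  a null (not NaN) average.
* Normalized cortical depth is the two-sided ratio
  `d_pia / (d_pia + d_wm)` of straight-line distances to the pial-side and
  white-matter-side boundary voxels, so every sample's profile spans
  [0, 1] regardless of local cortical thickness. The white-matter side is
  derived as the mask boundary minus the dilated pia surface; mask faces
  cut by the volume edge are not treated as boundary. A mask without two
  distinct sides raises a topology error.
* The vessel graph is the 3D medial-axis skeleton with per-node radius
  from the Euclidean distance transform (µm) and edges along 26-adjacency;
  plaque–vessel proximity reports each plaque's nearest node and that
  node's radius plus summary quantiles, so a "plaques sit at distal,
  small-radius vessel ends" association can be tested downstream. An empty
  graph yields flagged rows, never an exception.

## Synthetic phantom

The generator emulates the contrast regime above — not the optics. Default
conditions: 256³ voxels at 1 µm, baseline gray 150/255, Gaussian noise
σ = 8, a 0.8→1.2 per-slice illumination gain ramp, horizontal stripes of
amplitude 10 gray levels at 8 cycles/image with random phase per slice;
40 plaques with diameters spanning 10–50 µm (core −80, rim +30 over a
shell of 0.4× core radius), 300 somata of 6–15 µm (−80, mildly
ellipsoidal, volume-preserving anisotropy), 3 branching vessel trees with
8 µm root radius tapering to 2 µm (+70), 2 dark tracts (25 µm radius,
140 µm long cylinders along the sectioning axis, −80), and 200 thin
process filaments (1 µm radius, ~80 µm persistent random walks, −25).
Plaque diameters are drawn stratified over the stated range (evenly spaced
strata with uniform jitter, shuffled) so a 40-object draw always populates
every size class.

Placement is rejection sampling against an occupancy grid: tracts first,
then vessel trees (unchecked — vessels may tunnel other tissue, as real
vasculature does), then plaques (clearance 8 µm beyond the rim), somata
(clearance 3 µm) and filaments (which simply terminate at obstacles). An
object that cannot be placed — either it cannot fit at all or the retry
budget is exhausted — raises a placement error naming the structure class.
Ground truth (label volume + object tables; the plaque label is the dark
core, matching the detector's definition of extent) is recorded *before*
gain/stripe/noise corruption. A single `numpy` Generator seeded by one
integer drives everything; identical specs give bit-identical output.

What the phantom does **not** model: a point-spread function or partial
volume at structure boundaries, knife chatter and stitching seams,
staining-intensity gradients, curved cortical geometry (depth-profile
tests use a flat slab), touching/overlapping structures (placement
enforces clearances), and tissue texture beyond white noise. Passing the
recovery tests therefore demonstrates correctness of the algorithms under
the stated contrast regime, not segmentation accuracy on real acquisitions
— on real data the band quantiles and score thresholds must be set per
dataset, and boundary effects will degrade diameter accuracy by roughly
the PSF width.

## Evaluation

Detection evaluation matches predicted to true centroids greedily in
ascending distance within a 10 µm radius, one-to-one; precision, recall,
F1 and the diameter MAE over matched pairs follow. The empty-vs-empty case
is defined as perfect and flagged degenerate.

On the default phantom the full pipeline (preprocess → all channels →
fusion → morphometry) takes ~1–2 min on one CPU; across seeds it recovers
plaques at F1 ≥ 0.98 with diameter MAE < 0.5 µm, somata within 1 %,
vessels at Dice ≥ 0.97, and both tracts — the acceptance suite asserts the
looser bounds F1 ≥ 0.90, MAE ≤ 3 µm, ±10 %, Dice ≥ 0.80. A degradation
property holds the design honest: median F1 over five seeds never rises as
phantom noise increases (σ = 6 → 25 → 70 drives it 1.0 → ≈ 0.9 → 0).

## Problem sizes used in the test suite

Unit fixtures are ≤ 96³; oracle-equivalence checks run 100 random
≤ 28³ volumes against a Python BFS flood fill and a 1000-node brute-force
nearest-neighbour; the end-to-end recovery test runs the full default 256³
phantom once; determinism is checked by hashing all artifacts of two
pipeline runs on a 96³ phantom. These sizes were chosen so the whole suite
exercises every code path, including the full-scale conditions, in a few
minutes.

## Known limitations

* Quantile-based band fitting assumes the operator knows the approximate
  dark and bright volume fractions; a histogram with no gap (heavy partial
  volume, dense pathology) will need manually set thresholds.
* The plaque detector keys on the described morphology (dark core, paler
  rim); cored plaques without a discernible rim are rejected by design,
  and diffuse plaques without a dark core are invisible to it.
* Tract/soma routing by size + elongation will misroute a genuinely
  spherical 30 µm+ dark body (rare in this modality).
* The vessel skeleton uses thinning; very noisy masks produce spurious
  short spurs that inflate low-radius node counts. Proximity medians are
  therefore reported alongside quartiles.
* Mesh export writes raw marching-cubes triangles (OBJ/PLY) without
  decimation or smoothing.
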
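# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `ciliaquant`, and what the synthetic-data tests do and do
not demonstrate about real microscopy data.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)`; `voxel_size` follows the same axis order.
All positions, distances, sigmas and areas are physical (µm, µm²), with the
origin at the stack corner and the centre of voxel *i* at `(i + 0.5)·d`.
Pixels appear only at I/O boundaries. Forces are SI (N); picoNewtons are a
formatting layer.

## Synthetic scenes

The generator emulates a stained whole-mount field of multiciliated cells:

* **Cell borders** are convex polygons tiling the field (axis-aligned squares
  of 8 µm, the typical apical footprint of a mature ependymal cell). Manual
  segmentation variability is out of scope; borders are exported as ground
  truth.
* **Centrioles**: 30 per cell by default (scalar or per-cell counts), sampled
  by dart throwing inside a patch disk of radius 1.8 µm with a minimum
  spacing of 0.4 µm. Feasibility is validated against a random-sequential-
  adsorption bound (`n·s² ≤ 1.6·R²`) so infeasible specs fail loudly rather
  than hang. The patch centre is displaced 1.2 µm toward +x, emulating the
  anterior positioning of the patch in mature cells; the magnitude is
  configurable.
* **Orientation field**: each cell has a mean beat direction (fixed or
  uniform-random per cell); individual centriole orientations are
  wrapped-normal about it with dispersion 0.35 rad by default. Each Cep164
  partner is rendered as a single punctum displaced 0.25 µm from its centrin
  along that orientation — the pairing stage needs one Cep164 centroid per
  basal body, not a resolved appendage ring.
* **Puncta** are 3D Gaussians of PSF width (σ = 0.1 µm xy, 0.25 µm z) at the
  ground-truth positions, amplitude 1000. The default grid is 0.1 µm xy /
  0.23 µm z over 20 z-planes, the standard sampling used to capture all
  centrioles of a cell.
* **Actin channel**: two z-bands of 6 slices each — apical anchored at the
  Cep164 plane, subapical 1.4 µm deeper. Within a band, pixels inside the
  patch disk carry `ratio × base` and the remaining (border-eroded) cell
  interior carries `base`, so the patch/rest mean ratio equals the requested
  value *exactly* before noise. Two idealisations follow from that exactness
  requirement: the actin bands are piecewise-constant (no PSF blur), and the
  band separation is 1.4 µm rather than the ~1 µm of the real subapical
  network, because at 0.23 µm z-sampling two 6-slice measurement windows less
  than 1.38 µm apart overlap and the two target ratios could not be recovered
  independently.
* **Noise** is Poisson (optional, scaled) followed by additive Gaussian, the
  usual shot + read-noise camera composition; both stages and all sampling
  derive from a single integer seed, and identical spec + seed gives
  bit-identical output.
* **Beating traces** are sinusoids (or asymmetric-stroke sawtooths) sampled
  at 250 Hz. `amplitude` means half the peak-to-peak excursion: the sampled
  waveform is affinely normalised so the noiseless range is exactly
   `2 × amplitude` (a raw sampled sinusoid misses its continuous extremes by
  up to ~10⁻⁴ relative at 250 Hz / 28 Hz). No numeric beating amplitude is
  established for ependymal cilia in the source measurements, so the 5 µm
  default is an assumption, stated as such.

What the synthetic data does **not** emulate: optical aberrations beyond a
Gaussian PSF, background gradients, autofluorescence, non-convex or irregular
cell borders, centriole clusters with merged appendages, axoneme staining, and
actin cables linking patch to membrane. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to every
real-world artefact; detector parameters remain config-exposed for real data.

## Detection

`filter_stack` applies Gaussian pre-smoothing (σ = 0.1 µm xy / 0.25 µm z, the
centriole scale) then a Laplacian-of-Gaussian (σ = 0.12 µm xy / 0.25 µm z,
tuned to the rendered punctum width), sign-flipped so bright blobs are
positive peaks. Sigmas are specified in µm and converted per axis, so
anisotropic voxels are handled; sub-half-voxel sigmas warn. Kernels are
truncated at 6σ: the default 4σ support leaves a ~3×10⁻⁴ relative bias on
constant regions because the discrete LoG weights no longer sum to zero.

`extract_maxima` keeps voxels that equal the maximum over an *ellipsoidal
physical neighbourhood* (our choice of neighbourhood shape, radius =
`maxima_min_distance` per axis in µm) and exceed the threshold, then greedily
prunes to pairwise minimum distance in descending-score order with a
lexicographic (z, y, x) tie-break — fully deterministic. The threshold
defaults to the 0.998 quantile of the LoG response, making detected positions
invariant to intensity rescaling; an absolute threshold is available for
reproducibility across stacks. The pair (quantile 0.998, min-distance
0.3 µm) is the centriole-scale operating point used for all conditions: at
the generator's 0.4 µm packing it separates adjacent puncta while keeping
noise maxima sub-threshold at SNR 5. Sub-voxel quadratic refinement is
deliberately **off** by default — maxima are reported at voxel centres, and
on noiseless renders the localisation error is below the voxel half-diagonal.
Manual corrections are replaced by machine-readable accept/reject lists
(scriptable and logged) rather than an interactive step.

## Patch geometry

The patch is the largest density-connected subset of a cell's detections
(DBSCAN-style: cores have ≥ 3 neighbours within 1.5 µm — about 3× the mean
rendered spacing — plus density-reachable border spots), a reproducible
formalisation of a manually corrected density boundary. Cluster selection is
by (size, summed score) descending with a lexicographic centroid tie-break;
if no spot is core the patch degenerates to the single highest-scoring spot,
flagged low-confidence. Patch **area** is the xy convex-hull area (z is
ignored throughout the geometry stage by design); collinear or < 3-point sets
have area 0, and single-centriole cells are excluded from patch-size
statistics — the area statistic is known to be sensitive to scattered
centrioles, and the density rule records exactly which spots it excluded
rather than hiding them. Nearest-neighbour distances are xy Euclidean, one
per centriole, in input order.

## Orientation statistics

Pairing minimises the summed xy Euclidean distance (orientations live in the
apical plane; z is ignored) via `scipy.optimize.linear_sum_assignment`;
rectangular instances produce `min(n, m)` pairs and unmatched detections are
reported, never dropped. Each pair yields a unit vector; the per-cell summary
is the circular mean direction, resultant length `R = |mean unit vector|`,
and deviations wrapped to (−π, π]. Zero-length displacements are excluded
with a warning; when R ≈ 0 (antipodal degenerate) the mean direction is NaN
and flagged. Histograms use 18 half-open 20° bins covering [0°, 360°); an
angle exactly on an edge falls in the upper bin. Both signed deviations and
their absolute values can be derived from the output since the convention in
circular plots is ambiguous in practice.

The primary two-sample test is Watson's *U*², computed from the difference of
the pooled empirical CDFs (tie steps averaged) — rotation-invariant, the
appropriate property for angles — with the asymptotic null series
`P(U² > u) = 2·Σ (−1)^{j−1} exp(−2j²π²u)` (51 terms; the odd count keeps the
partial sum on the correct side as u → 0). Simulated calibration at n = 50
per group: type-I error 0.034–0.062 across seeds at α = 0.05, power 1.0
against von Mises κ = 4 vs uniform. The KS alternative first centres each
sample on its own circular mean (the circle has no natural origin; the
original wrapping convention is unspecified, so ours is documented here) and
applies the linear two-sample test. Groups under 8 angles are flagged
unreliable.

## Intensity quantification and statistics

Band projections sum `n_slices` z-planes centred on the anchor plane; for the
default even count of 6 the window is the anchor plus 3 planes above and 2
below (documented rounding), truncated windows are flagged. The patch/rest
ratio uses caller-supplied masks — ground truth for synthetic data,
user-drawn polygons for real data; automatic segmentation is deliberately
excluded — with border pixels removed from both masks before the call.
Neighbour normalisation divides a cell's mean intensity by the mean of its
three closest non-transfected neighbours (centroid-to-centroid, ties broken
by cell id; fewer than three available → use what exists and flag).
Fold-change normalisation divides per-cell counts by the mean of a reference
population (contralateral hemisphere, surrounding non-transfected cells, or
littermate controls — same arithmetic, documented mode).

Outlier removal is the location-model form of ROUT: median centre,
normal-consistent MAD scale, two-sided t p-values on standardised residuals
(n−1 df), Benjamini–Hochberg step-up at rate Q (default 1%). The regression
form is unnecessary for univariate count distributions. Constant samples,
n < 10, or Q = 0 remove nothing; removals are logged, monotone in Q.

Group comparisons: two groups → two-sided Mann–Whitney; more → Kruskal–Wallis
omnibus then Dunn's pairwise z-comparisons on pooled tie-corrected ranks with
Bonferroni adjustment (the classic correction for Dunn's procedure; the
original software's adjustment family and sidedness are not specified, so the
conservative choice is made and recorded here). Binned distance distributions
use the Cochran–Armitage χ² test for trend (scores default to bin indices;
reduces exactly to the 1-df Pearson χ² in the 2×2 case).

## Kinetics

Kymographs sample intensity along a polyline at unit pixel spacing with
bilinear interpolation, one column per frame of a 200 ms default window.
Beat frequency is estimated twice: (1) *primary* — prominent peaks of the
linearly detrended trace divided by duration, with one peak = one full beat
cycle (the cycle convention is fixed here since "number of beats" could mean
half-strokes); (2) *spectral* — the dominant non-DC periodogram frequency.
The prominence threshold is 3× the robust noise SD, estimated as the residual
of a least-squares sinusoid fitted at the spectral frequency (with a
10⁻³·range floor so noiseless traces are counted exactly). Estimates
disagreeing by more than the resolution floor 1/duration — always reported —
are flagged, as are traces with no supra-threshold peaks (frequency 0).
Amplitude is max − min of the tip-position series; traces shorter than one
expected period are flagged. The "16 pixels²" ROI convention is read as a
16-px-square (averaged); the 4×4 alternative is selectable.

## Force model

`C = 4πμ/log₁₀(L/r)`; `F_flow = C·f·A·L`; `F_torque = F_flow·L/L_c`.
The **base-10 logarithm is a deliberate model decision**: with the default
geometry (μ = 10⁻³ N·s·m⁻², L = 11.1 µm, r = 99 nm) it yields
C = 6.13×10⁻³ ≈ 6×10⁻³ N·s·m⁻², consistent with published estimates for
ependymal cilia, whereas a natural log gives 2.7×10⁻³; the base is exposed
for sensitivity analysis. Defaults: r = 99 nm, L_c = 510 nm, L = 11.1 µm
(measured means), μ = 10⁻³ N·s·m⁻² (CSF). Beat frequency and amplitude have
**no defaults** — they are observables of each recording and must be given
explicitly; only their product is constrained by a target force
(f·A = F/(C·L)). Note ∂C/∂r > 0: a thicker cilium has a smaller L/r, a
smaller log and hence larger drag. `sensitivity_table` evaluates both forces
over one-at-a-time parameter grids (e.g. the ± sem bounds on r, L, L_c).

## Problem sizes and tolerances

Default test/acceptance scenes are 4–18 cells of 25–30 centrioles on
160×160×20 to 240×240×20 voxel grids — large enough that detection,
geometry and orientation statistics operate in their intended regime, small
enough to keep the full suite fast. Oracle comparisons (hull, nearest
neighbour, assignment) are exact to floating-point round-off; noiseless
recoveries are exact up to mask/voxel discretisation (ratio tolerance 0.05,
localisation within the voxel diagonal); stochastic recoveries (SNR-5
detection at 0.95, Watson calibration band [0.03, 0.08], fold-change within
2 SE of 0.60) use seeded Monte-Carlo at the replicate counts stated in the
tests.

## Known limitations

* Cell borders are rectangles; real ependymal cells are irregular polygons.
  All algorithms accept arbitrary convex polygons, but tests only exercise
  rectangles.
* The detector reports voxel-centre maxima; sub-voxel refinement exists but
  is off by default, so localisation error is bounded by the voxel geometry.
* The Watson U² p-value is asymptotic; below ~8 angles per group it is
  flagged rather than replaced by an exact permutation p.
* The force model is an order-of-magnitude slender-cylinder estimate: no
  waveform integration, no elastohydrodynamics, no wall effects.
* The ROUT implementation is the univariate location form, not the original
  nonlinear-regression form.
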
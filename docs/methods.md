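# Methods

## Forward model and demodulation

An off-axis interferogram is modelled as
`I = B[1 + m cos(2π(fx·x + fy·y) + φ)]` with background `B` (counts), fringe
visibility `m ∈ [0, 1]` and carrier `(fx, fy)` in cycles/pixel (default
(0.2, 0.1): well clear of DC, resolvable by a 12×12 window, below Nyquist).
Additive Gaussian read-out noise is applied to the intensity and clipped at
zero.

**Carrier estimation** applies a DFT-periodic Hann window (exact nulls at
integer bins, so a fringe-free frame has essentially no energy outside the
DC lobe), searches the half-plane `fx ≥ 0` outside an exclusion radius
(max of 0.03 cycles/px and 6 bins), and refines the peak by parabolic
interpolation of the log magnitude per axis.  A frame whose best peak does
not stand above both an absolute fraction of DC (10⁻⁴) and the spectral
median floor (6×) is reported as carrier-free.  Modulation depth is
estimated from the peak/DC magnitude ratio; with non-integer carrier bins it
is accurate only to leakage (tens of percent) and is informational.

**Windowed least-squares demodulation** fits, at every pixel, the
three-parameter local model `I ≈ a + c·cos(2πf·r) + s·sin(2πf·r)` over a
centred square window by linear least squares, with the carrier supplied
externally — 12×12 windows are too small for a stable joint
frequency-and-phase fit.  The wrapped phase is `φ = atan2(−s, c)`, the sign
chosen so that increasing optical thickness increases φ under the forward
model.  Windows are clipped at the image border (zero padding contributes
nothing to the normal-equation sums); no fringes are invented by mirroring.
An even window cannot be centred on a pixel, so the sums use a
(window+1)-tap kernel with half-weight ends — same 12-pixel support,
symmetric weighting — which removes a half-pixel phase attribution bias
(~0.02 rad on a typical cell dome).  Pixels with singular normal equations
(zero-variance windows) get phase 0 and quality 0; elsewhere quality is
1 − normalised fit residual.  The fit assumes φ approximately constant
across the window; the residual error grows with phase curvature and is
~0.006 rad RMSE for a 5 rad dome of 60 px width.

**Fourier demodulation** (sideband filtering with a raised-cosine filter of
radius half the carrier magnitude, then carrier ramp removal) serves as an
independent oracle; the two methods agree to <0.05 rad RMSE on noiseless
frames.  A purely linear object phase is indistinguishable from a carrier
shift, so tests that use ramps inform the demodulator of the true carrier.

**Background subtraction** removes an empty-field reference frame, then a
plane fitted over the lowest-phase quartile (the non-cell pixels), then the
background mode (histogram mode over 128 bins, refined to the median of the
modal bin so the offset is not quantised to the bin width).

## Phase unwrapping

Residues are 2×2 loops whose four wrapped gradient sums equal ±2π; the
implementation records charge = loop sum / 2π.  Branch cuts use
nearest-neighbour pairing: each unbalanced residue connects to the nearest
opposite unbalanced charge (Chebyshev metric) unless the border is closer;
segments are rasterized 8-connected, which a 4-connected integration cannot
cross.  Integration is a deterministic breadth-first flood fill from the
highest-quality non-cut pixel (image centre when no quality map exists),
adding wrapped neighbour differences; cut-isolated pixels are flagged in
`valid_mask` and excluded from feature extraction downstream.  By
construction the output differs from the wrapped input by exact multiples of
2π on the valid mask.  The Itoh row-then-column cumulative unwrapper is
provided purely as an oracle and enforces its own precondition (zero
residues).

## Segmentation

Default: Otsu threshold over the whole image (background mode vs cell mode),
floored at 0.3 rad, used as the seed of a hysteresis threshold whose low
level is the floor — this recovers the smooth low-phase shoulder of spread
cells that a plain Otsu cut removes — followed by 3×3 binary opening, hole
filling, optional watershed splitting on distance-transform maxima, and
removal of regions below 50 µm² or touching the border.  Border-touching
cells are excluded by default because their areas and volumes are
truncated.  Cells overlapping unwrapping-invalid pixels are flagged and
skipped by the time-series classifier.

## Features

Phase is converted to optical path difference `z = φλ/2π` (µm) before any
surface computation, so lateral and axial axes share units.  The top surface
is the graph area of `z` over the mask: per-pixel `√(1+|∇z|²)·pitch²` with
finite differences restricted to in-mask neighbours (one-sided at the
support boundary).  The rim skirt down to z = 0 belongs to neither surface —
a flat pancake of area A has top surface exactly A — and `s_top ≥ s_pr`
holds identically.  This quadrature converges for smooth profiles (<1%
change on doubling resolution) but underestimates near-vertical rims
(≈4% low for a hemisphere at 0.2 µm pitch); the sphericity test therefore
feeds the sphericity formula full-sphere volume and area obtained from the
phantom's generating geometry.

Sphericity is the standard `ψ = π^⅓(6V)^⅔ / S` (sphere → 1), computed from
the OPD volume (µm³) and OPD membrane area (µm², top + projected).  `σ_φ` is
reported as the variance of in-cell phase; kurtosis is Pearson (normal → 3),
not excess.  Dry mass is `DM = λ Σφ ΔA / (2πα)` with the specific refraction
increment α = 0.19 mL/g (literature-typical; with λ in µm and α in
µm³/pg the result is picograms directly).  Masks under 8 pixels are
rejected; zero-variance phase yields kurtosis/skewness 0 with a
degenerate-distribution flag.  The bright-field baseline features use the
binary mask only, via Crofton perimeters and equivalent-ellipse moments.

## Morphology and error analysis

Under constant intracellular refractive index,
`h = φλ / (2π(n_cell − n_medium))`; negative phase clips to zero with a
clip-fraction diagnostic.  Defaults n_cell = 1.380, n_medium = 1.337
(Δn = 0.043) are literature-typical values, surfaced in `OpticalConstants`.
Cohort error analysis computes signed per-cell relative errors (%) of
average height, volume and surface area against a matched reference cohort,
reporting the mean (systematic component), standard deviation (random
component) and 10-bin histograms over ±40%.  Reference morphology comes from
phantom ground truth; the Monte-Carlo error budget draws a per-cell true
n_cell uniformly within ±0.01 of nominal and adds 0.15 rad correlated
speckle, which yields a volume-error spread of ~13% and reproduces the
mechanism by which rippled height maps systematically overestimate membrane
surface area (the bias grows monotonically with speckle amplitude; a
constant phase offset alone does not change the graph area, so the
mechanism is the ripple, not the mean shift).

## Synthetic phantoms

Geometry: a rotated superellipse support (`|u|^p + |v|^p < 1`, p ∈ [2, 2.6])
with cap profile `h0(1−ρ_p)^q`, plus Gaussian blebs (apoptotic) and a
band-limited multiplicative roughness field (necrotic; 16 random cosines of
5–14 µm wavelength, factor clipped to [0.4, 1.6] so the profile nowhere
thins to zero).  The height function is analytic: pixel values are
area-averaged over a 3×3-supersampled grid (camera pixel integration), and
ground-truth volume/mean height/surface area are integrated on the fine grid
by an independent triangle tessellation, never via the feature module.
Support is cut at 10% of peak height (the measurable support of a phase
object); the discrete height-map integral matches the ground-truth volume
within 0.5% by construction, and the hemisphere phantom reproduces
(2/3)πr³ to <0.01%.

Archetype defaults (µm): live — spread dome, radius 14, height 3.2, q 0.45;
apoptotic — compact cap, radius 7.5, height 6.5, ≥2 blebs (σ 1.4 µm,
amplitude 1.6 µm) on the rim; necrotic — broad low irregular pancake,
radius 17, height 2.4, q 0.25, roughness 0.35.  Line modifiers: A549 scale
1.45 / height 1.20 (largest of the three); 3T3 scale 0.85 / height 0.8 /
aspect ×1.7 (elongated fibroblasts); HeLa nominal.  All dimensions are
literature-typical for adherent cells; the necrotic thickness and roughness
bound were chosen so the profile stays above the segmentation floor, and the
line-scale contrast so that the 9-class feature clouds are separated
(minimum inter-class centroid distance ≈ 1.2 z-units), which the spec-level
tests verify via classification accuracy.  Class draws use a 12–15%
coefficient of variation, truncated to ±50%.

The generator emulates: archetype-dependent morphology, pixel integration,
correlated coherent noise on phase (Gaussian field, 2 px correlation,
default σ 0.08 rad in datasets), and intensity noise on holograms.  It does
not emulate: diffraction/defocus, subcellular refractive-index structure,
cell-cell contact in datasets (cells are placed on disjoint slots in
time-series frames), uneven illumination, or camera nonlinearity.  Passing
tests therefore demonstrate the correctness of the algorithms under the
stated image formation model, not performance on real microscope data.

Default pixel pitch is 0.35 µm/px, typical of a ~6.5 µm camera pixel behind
a 20× objective; it is a configuration default, not a calibration.

## Classification

Feature tables are pandas DataFrames with named feature columns and
line/state labels.  Pipelines drop zero-variance features, z-score on
training statistics, then fit: SVC with an inhomogeneous polynomial kernel
(degree 2 or 3, coef0 = 1) for the "quadratic"/"cubic" kernels, RBF for
Gaussian, C = 1 (one-vs-one multi-class, the native SVC scheme); k-NN with
k = 7, cosine or Minkowski p = 3 metric, distance weighting; random forest
or AdaBoost with 200 trees.  Hyperparameters are package defaults, chosen
once, since only the kernel/metric families are prescribed by the problem.
Dry mass is proportional to phase volume, so after z-scoring they are the
same predictor; `v_phase` is used in the default predictor set.  Splits are
stratified on the joint (line, state) label at 20% test fraction.  The
feature-progression analysis trains on nested prefixes of a ranking
(greedy-forward when none is given) on a fixed split.  The treatment
time-series pipeline segments each frame, extracts features per cell, skips
cells overlapping invalid phase, predicts states and reports per-timepoint
counts and fractions; frames with zero cells get NaN fractions.

The simulated treatment series interpolates the (live, apoptotic, necrotic)
mixture linearly over 13 five-minute frames with deterministic
largest-remainder apportionment of 16 cells per frame, making the mixture an
exact ground truth for the recovered fractions.

## Numerical choices and limitations

* Wrapping convention: (−π, π], `wrap(x) = π − mod(π − x, 2π)`.
* Problem sizes in tests and the acceptance script (512² frames, 50-phantom
  oracle cohorts, 9×50-cell datasets, 13-frame series) were chosen as the
  smallest sizes at which the measured quantities are stable across seeds.
* The Goldstein cut placement uses classic greedy nearest-neighbour pairing
  with straight rasterized cuts, not the box-growing multi-residue variant;
  for the residue densities produced by speckled cell images this is
  equivalent in practice, but very dense residue fields may get longer cuts
  than optimal.
* Accuracy figures quoted anywhere in this repository are measured on the
  synthetic generator's conditions; they characterise the implementation,
  not any real cell database.
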
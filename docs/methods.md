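# Methods

This note records the models, conventions and design choices behind
`ramantag`, in the order the pipeline applies them.

## Measurement model and the synthetic phantom

The pipeline assumes hyperspectral cubes in which every pixel holds an
independent Raman spectrum on a shared, strictly increasing wavenumber
axis, with intensities in detector counts and a lateral sampling of
0.5 µm/px by default. The `phantom` module renders this model
explicitly so every downstream stage can be tested against ground
truth:

* **Geometry** — one elliptical cell on empty background, an elliptical
  nucleus strictly inside it, and circular lipid droplets placed by
  seeded rejection sampling inside the cell, outside the nucleus, and
  non-overlapping. An optional perinuclear ring (matrix pixels within a
  configurable distance of the nucleus boundary) carries extra drug,
  emulating drug accumulation adjacent to the nuclear envelope/ER.
* **Spectra** — sums of Lorentzian bands (amplitude = peak height in
  counts, not area). Compartment dictionaries give the nucleus the DNA
  backbone band at 789 cm⁻¹ and the droplets dominant lipid CH₂ bands
  (2850, 1447 cm⁻¹); the drug band set is 2223 (1.0), 1618 (0.35),
  1510 (0.3), 1255 (0.15) relative heights at a base of 80 counts, the
  alkyne tag a single 2115 cm⁻¹ band at 100 counts. A broad water
  combination band (centre 2150 cm⁻¹, FWHM 400 cm⁻¹, 50 counts)
  underlies the silent region; a low-order polynomial baseline
  underlies everything.
* **Default study conditions** — a treated M1-like cell with drug
  loadings droplet 1.0 / matrix 0.15 / nucleus 0.10 (constructed
  droplet:nucleus ratio 10, droplet enrichment roughly an order of
  magnitude, as a strongly lipophilic drug would show), additive
  i.i.d. Gaussian noise of 1.5 counts SD against an 80-count droplet
  nitrile peak, and a 64×64 px grid on a 550–3150 cm⁻¹ axis in 2 cm⁻¹
  steps. No in-droplet enhancement factor is established
  experimentally; these loadings are the package's chosen simulation
  conditions, fixed once.
* **What the phantom does not emulate** — optical blur (compartment
  boundaries are pixel-sharp, which makes segmentation easier than on
  real cells), Poisson photon statistics (noise is additive Gaussian of
  constant variance), spectral variation within a compartment, 3-D
  z-structure, and instrument response. Passing recovery tests
  therefore demonstrates correctness of the algorithms under the stated
  model, not performance on real instrument data.

Identical (spec, seed) pairs produce bit-identical cubes; spikes,
noise, droplet placement and annotations all draw from
`numpy.random.default_rng` seeded generators.

## Despiking

Cosmic-ray spikes are detected on the first differences
d_i = x_i − x_{i−1} via modified z-scores
z = 0.6745·(d − median d)/MAD(d), computed per spectrum, with channel i
(i ≥ 1) owning d_i and a default threshold of 37. Flagged channels are
replaced by the mean of unflagged channels within ±3 channels (the
window widens only in the degenerate all-flagged case). MAD = 0
(constant spectra) yields no flags, avoiding a 0/0 on synthetic
fixtures.

Channel 0 owns no difference, so a leading-edge spike cannot be flagged
through the generic rule and would poison the repair of channel 1. It
is therefore flagged on the one-sided signature that only a channel-0
spike produces: |z₁| above threshold without the sign-flipped partner
|z₂| (an interior spike always creates the ±pair d_i, d_{i+1}). This
keeps despiking idempotent — a second pass flags nothing new.

A property worth knowing when choosing thresholds: differencing
inflates the noise scale by √2, so for Gaussian noise of SD σ the
expected score of a spike of amplitude A is z ≈ A/(√2·σ). A threshold
T therefore detects spikes reliably only above ≈ √2·T·σ (≈52σ at
T = 37); genuine cosmic rays, at thousands of counts, sit far above
this edge, while the band-edge slopes of smooth spectra stay well below
it.

## Background correction

Plain SNIP (no log-log-sqrt compression): iterative clipping
b_i ← min(b_i, (b_{i−p} + b_{i+p})/2) with the half-window p increasing
1..N and edge clamping; the baseline never exceeds the input. The
correction is applied in three sections — 3150–2600 cm⁻¹ (100
iterations), 2800–1800 cm⁻¹ (7), 1900–550 cm⁻¹ (100) — because the
silent region needs a gentle clip that removes the broad water band yet
preserves narrow tag bands, while the crowded fingerprint and
CH-stretch regions need a deep one. Overlapping sections are merged
with a linear cross-fade (triangular weights that vanish at the section
edges), which is continuous by construction; channels outside every
section pass through unchanged. The SNIP variant is isolated behind
one function so an LLS-transformed or decreasing-window variant can be
swapped in.

Wavenumber calibration applies a single global shift, the mean of
(reference − measured) over the calibrant band pairs; a
4-acetaminophen reference table (ASTM E1840 values) ships as editable
package data. Spectra are then linearly resampled onto 600–3050 cm⁻¹
in 2 cm⁻¹ steps (1226 channels), with extrapolation refused. The
pipeline order is fixed: despike → background → calibrate → resample.

## Band quantitation

A band area is the trapezoidal integral of (spectrum − chord) over a
window of centre ± half-width (default 15 cm⁻¹), where the chord joins
the spectrum values at the window bounds snapped to the nearest on-grid
channels. This local linear background makes the area exactly linear
in the spectrum and exactly invariant to any added affine function of
wavenumber, and suppresses the residual water background; on pure noise
it is approximately zero-mean and can be negative.

Tag abundances are normalized by Ā_nuc, the mean 789 ± 15 cm⁻¹ (DNA)
area over the cell's nuclear pixels, which cancels system-performance
and global-intensity variation between cells; a non-positive Ā_nuc is
an error rather than a silent division. For display, values pass
through arsinh(x) = ln(x + √(x²+1)) — log-like at large |x| but defined
at and below zero. SNIP attenuates every band by a common
(scale-invariant) factor, so normalized ratios such as droplet/nucleus
are preserved even though absolute areas shrink.

## Segmentation

Each pixel is classified independently (no spatial features) by a
random forest — 100 trees, entropy criterion, unlimited depth, fixed
seed, no feature scaling (forests are insensitive to monotone feature
transforms) — on eight band-area features: 789, 1342, 1267, 1100,
1447, 1661, 2850, 2940 cm⁻¹, all ±15. The windows deliberately avoid
the drug bands (2223, 1618, 1510 cm⁻¹) so the segmentation is
insensitive to drug loading; a test verifies that varying loading
0→10× changes fewer than 2% of predicted pixels. Training uses
partially annotated images (0 = unlabeled) and requires at least two
classes.

The cell mask derives from a class map by thresholding at label ≥ 2,
one erosion and one dilation with a 3×3 square, keeping the largest
8-connected component (discarding partially imaged neighbours), and
border-flood hole filling. The operation is idempotent on its own
output. Manual repair is supported through an override image
(0 keep / 1 force outside / 2 force inside) rather than interactive
editing.

## Differential band detection

Spectra are max-1-normalized, then fitted with a degree-4 smoothing
spline. The smoothing factor (default 1000) is interpreted as the
spline's residual budget in units of the estimated noise variance: the
fit uses weights 1/σ̂ with σ̂ the robust noise estimate
MAD(Δy)/(0.6745·√2), making s ≈ m (the channel count, 1226 on the
default grid) the classic choice and keeping the parameter meaningful
across intensity scales. A noiseless spectrum (σ̂ = 0) falls back to
an interpolating spline.

Band maxima are negative local minima of the spline's second
derivative, evaluated on a 10×-refined grid. Two gates suppress noise:
the |second-derivative| extremum must reach 2% of the largest such
magnitude in the spectrum (the detection statistic, chosen over the raw
spectrum value so weak-but-sharp bands survive), and the normalized
spectrum must recede by Δ = 0.01 on both sides of the band's local
maximum before rising above it. Because a second-derivative extremum
of an overlapped band sits slightly off the intensity maximum, the
hysteresis walk first climbs to the nearest local max — without this,
shoulders of stronger neighbours are systematically lost. Detected
positions are invariant to positive rescaling of the input.

Treated-vs-control comparison reports treated peaks with no control
peak within a 10 cm⁻¹ match tolerance; a zero tolerance would report
every band as "new" under run-to-run jitter of a fraction of a channel.

## Colocalization

Cell-mask pixels become scatter points (x = normalized CN area,
y = normalized CC area); pixels with a negative coordinate are excluded
from the scatter but retained for display with their own code. The
density mode is located by a Gaussian KDE (Scott's bandwidth) evaluated
on a 256×256 grid over the retained points, computed after the
negative-value exclusion. The partition geometry is:

* central line through the origin with slope s = y*/x* (the CC/CN ratio
  at the mode) separating the CC-rich from the CN-rich half;
* intensity boundary at t₀ = 1.05 × the mode's projection
  t = (x + s·y)/√(1+s²) along the central direction — "just beyond"
  the densest cluster.

Boundary points go to the lower-ratio / lower-intensity segment. The
four segments partition the retained points exactly, and labels are
invariant to a common positive rescaling of both maps when the geometry
is recomputed. Back-projection paints codes 1–4 per segment, 5 for
excluded pixels, 0 outside the mask, and is bijective with the point
list.

## DFT activity-to-intensity conversion

Quantum-chemistry Raman activities Sⱼ (Å⁴ amu⁻¹) convert to Stokes
intensities via

Iⱼ ∝ (ν̃₀ − ν̃ⱼ)⁴ · Sⱼ / ( ν̃ⱼ · [1 − exp(−h c ν̃ⱼ / (k_B T))] )

with ν̃₀ = 19455.3 cm⁻¹ (514 nm excitation), T = 298.15 K, and
constants from `scipy.constants` (CODATA). Harmonic frequencies are
first multiplied by an empirical scale factor (0.9626). Conversion
convention is a hook: the fourth power can use the scattered-frequency
difference (default) or ν̃₀ alone. Broadened spectra use unit-peak-
height Lorentzians (FWHM 15 cm⁻¹; unit-area selectable) and are
max-normalized to 1, so doubling all activities changes nothing.
Modes at or above the excitation wavenumber are rejected.

## SRS corrections

Stimulated Raman loss is bilinear in pump and Stokes power, so frames
are rescaled by (P_pump,ref·P_Stokes,ref)/(P_pump·P_Stokes) with the
first frame as the (arbitrary but fixed) reference; a pump-only model
is selectable. Off-resonance subtraction is plain pixelwise
difference with negatives preserved. Spectral traces are normalized by
the affine map sending the 2050–2300 cm⁻¹ window to [0, 1]
(idempotent; constant windows are an error). Z-stacks collapse by
pixelwise maximum (or mean).

## Numerical choices and problem sizes

* Pixel coordinates are 0-based, row-major, origin top-left everywhere;
  compartment labels are 1 background, 2 matrix, 3 nucleus, 4 droplet.
* Window bounds and SNIP section bounds snap to on-grid channels; ±15
  windows align exactly with the 2 cm⁻¹ grid.
* Recovery experiments run on 64×64 px phantoms with 1226–1301 channel
  spectra — large enough for stable per-compartment statistics
  (hundreds of pixels per class) while a full train-and-recover cycle
  stays in the minutes range; unit tests use 40×40 phantoms of the same
  structure.
* Cubes are float64 throughout; the HDF5 container round-trips exactly.

## Known limitations

* Single-cell assumption: normalization uses one nuclear region per
  image; multi-cell fields require per-cell masks before quantitation.
* The despiking threshold semantics inherit the √2 differencing factor
  described above; spikes below ~√2·T·σ are by construction invisible.
* Spatially correlated artifacts (stripe noise, adjacent-pixel cosmic
  rays) are out of scope; despiking is purely per spectrum.
* The colocalization geometry assumes the density mode sits strictly
  inside the positive quadrant; tag-free images (mode on an axis) are
  rejected rather than force-fitted.
* Calibration is a single global shift; wavenumber-dependent warping is
  not modelled.
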
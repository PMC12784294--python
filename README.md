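# ramantag

Hyperspectral Raman analysis of bioorthogonal tags in the cellular
silent region.

Small molecules carrying a nitrile (C≡N, ~2223 cm⁻¹) or alkyne
(C≡C, ~2115 cm⁻¹) group can be located inside cells without external
labels: their stretching vibrations fall in the silent wavenumber
region (1800–2700 cm⁻¹) of the cellular Raman spectrum, where
endogenous biomolecules contribute essentially nothing. `ramantag`
implements the complete analysis pipeline for such experiments — from
raw hyperspectral cubes (H×W pixels, each holding a full spectrum) to
per-compartment tag abundances and two-tag colocalization maps — for
researchers doing Raman-based drug-localization studies in cells
(e.g., a nitrile-bearing FLAP antagonist in primary macrophages,
multiplexed with an alkyne-tagged fatty acid).

## What the pipeline computes

1. **Preprocessing** (per pixel): cosmic-ray despiking by modified
   z-scores of first differences, *z*ᵢ = 0.6745·(dᵢ − median d)/MAD(d),
   threshold 37; sectioned SNIP background correction
   (3150–2600 cm⁻¹: 100 iterations, 2800–1800 cm⁻¹: 7,
   1900–550 cm⁻¹: 100) with cross-faded merging; wavenumber calibration
   against 4-acetaminophen bands; linear resampling onto
   600–3050 cm⁻¹ in 2 cm⁻¹ steps (1226 channels).
2. **Band quantitation**: the area A between the spectrum and the chord
   joining the window bounds (trapezoidal rule, window centre ± 15 cm⁻¹),
   which cancels the broad water combination band underlying the silent
   region. Abundances are reported as
   A(CN) / Ā_nuc(789 ± 15 cm⁻¹) — normalized to the mean DNA backbone
   band area over the cell's nuclear pixels — and display-compressed
   with arsinh, which unlike log is defined for the negative ratios that
   pure noise produces.
3. **Segmentation**: a per-pixel random forest on eight band-area
   features (789, 1342, 1267, 1100, 1447, 1661, 2850, 2940 cm⁻¹, all
   ±15, deliberately avoiding the drug's own bands) labels background /
   cellular matrix / nucleus / lipid droplet; the binary cell mask
   follows by thresholding, 3×3 erosion+dilation, largest-component
   selection and hole filling.
4. **Differential band detection**: a degree-4 smoothing spline;
   band maxima are negative local minima of its second derivative,
   gated by a 2% height limit and a Δ = 0.01 vertical hysteresis;
   treated-vs-control reporting of newly appearing bands.
5. **Colocalization**: per-pixel scatter of normalized CN (x) vs CC (y)
   areas, negatives excluded; a four-segment partition built from the
   scatter's density mode (central line through the origin with the
   mode's CC/CN slope; intensity boundary just beyond the mode) and
   back-projection of segment labels onto the pixel grid.
6. **DFT spectra**: conversion of computed Raman activities Sⱼ to
   intensities Iⱼ ∝ (ν̃₀−ν̃ⱼ)⁴·Sⱼ / (ν̃ⱼ·[1−exp(−hcν̃ⱼ/k_BT)]), with
   frequency scaling (0.9626) and 15 cm⁻¹ Lorentzian broadening.
7. **SRS stacks**: bilinear pump×Stokes power correction, off-resonance
   (2500 cm⁻¹) subtraction, silent-window (2050–2300 cm⁻¹) 0–1
   normalization, z-projection.

Every stage is testable without instrument data through the `phantom`
module, which renders synthetic cells (elliptical cell body and nucleus,
circular lipid droplets, per-compartment Raman band dictionaries, tag
loadings, water band, baseline, noise, spikes) together with the ground
truth the pipeline must recover.

## Worked example

Recover the compartment distribution of a nitrile-tagged drug from a
synthetic treated cell (true loadings: droplet 1.0, matrix 0.15,
nucleus 0.10):

```python
import numpy as np
from ramantag import PhantomSpec, make_phantom, train_from_phantoms, run_localization

cube, truth = make_phantom(PhantomSpec(seed=31))

rng = np.random.default_rng(7)
cubes, annotations = [], []
for seed in (101, 102):
    c, t = make_phantom(PhantomSpec(seed=seed))
    ann = np.where(rng.random(t.class_map.shape) < 0.3, t.class_map, 0)
    cubes.append(c); annotations.append(ann)
model = train_from_phantoms(cubes, annotations, seed=0)

result = run_localization(cube, model)
print(result.summary.round(4).to_string(index=False))
```

prints

```
 class       name    n   mean     sd     se
     1 background    0    NaN    NaN    NaN
     2     matrix 1707 0.0904 0.0243 0.0006
     3    nucleus  339 0.0577 0.0246 0.0013
     4    droplet  227 0.6266 0.0289 0.0019
```

The `mean` column is the nuclear-DNA-normalized nitrile band area per
compartment: the droplet mean exceeds matrix and nucleus by an order of
magnitude, and the recovered droplet/nucleus ratio (0.6266/0.0577 ≈ 10.9)
matches the constructed loading ratio of 10 to within a few percent.
The SNIP correction attenuates all bands by a common factor, so
normalized ratios are preserved even though absolute areas are not.

A command-line interface mirrors the stages
(`ramantag simulate | preprocess | quantify | segment | peaks |
dft-broaden | run-localization | run-coloc`); see `ramantag --help`.

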
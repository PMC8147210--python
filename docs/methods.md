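# Methods

## Moisture bookkeeping and the study design

All moisture values are wet-basis fractions internally and percent in every
report: `M_wb = W_m / (W_m + W_d)` for water mass `W_m` and dry-matter mass
`W_d`; dry matter of a sample of initial mass `W_o` is `DM = W_o (1 − M_wb)`.

The design emulator reproduces a drying/rewetting experiment on five feed
groups (a TMR and four by-product materials).  Per group: one sample stays
in its original condition; one sample is withdrawn from a 40 °C oven every
30 min over 9 h 30 min (19 dried samples); and a fresh 200 g aliquot
receives 20 incremental 5 mL water doses (1 mL ≡ 1 g).  That is 40 samples
per group, 200 in total.  Rewetting is exact bookkeeping:
`M_wb(k) = (W_m0 + 5k)/(W_o + 5k)`.  Drying kinetics are not implied by the
design itself, so the emulator uses exponential water loss,
`W_m(k) = W_m0 (1 − r)^k` with default `r = 0.085` — monotone, positive, and
spanning roughly the 10–80 % wet-basis ranges reported for such materials
over 19 steps.  Dry matter is conserved along both arms; only water moves.
Initial per-group moistures (45, 30, 35, 32, 28 %) sit inside each
material's typical range; the emulator matches ranges, not any particular
sample trajectory, because per-step trajectories are material-dependent.

## Synthetic spectra and scenes

The reflectance model is a two-component absorption mixture on a gently
tilted baseline (0.90 → 0.82 across the grid):

    R(λ) = offset + slope · (baseline(λ) − m·A_water(λ) − (1−m)·A_dry(λ)) + ε(λ)

`A_water` has Gaussian lobes at 1000 nm (depth 0.18, σ 40 nm) and 1450 nm
(0.35, σ 55) — the O-H stretching second and first overtones.  `A_dry` has
lobes at 1225 nm (0.12, σ 45), 1530 nm (0.10, σ 50) and 1660 nm (0.12, σ 50)
— C-H, N-H and aromatic C-H overtones of carbohydrate and protein.  Because
dry-matter fraction is `1 − m`, the dry lobes anticorrelate with moisture,
exactly as in real feed, where nutrient percentages rise as water leaves.
`(offset, slope)` is an additive/multiplicative scatter pair drawn per
sample (tables) or per pixel (scenes) from ±0.02 and 0.95–1.05.  Noise is
zero-mean Gaussian with s.d. 0.002 below 1917 nm and 5× that above, where
SWIR detectors lose signal-to-noise; values are clipped to (0, 1.2].

A scene is a rasterised disk (default radius 22 px in a 64×64 frame) on a
flat 0.12-reflectance background.  Disk pixels get the sample moisture plus
a Gaussian-smoothed zero-mean random field (s.d. 3 points, smoothness 8 px),
re-centred so the disk mean equals the sample moisture to 1e-6 — this is
the "unevenly spread" moisture that the maps visualise.  Raw counts are
`R·(white − dark) + dark`, with a smooth radial illumination profile and a
λ-dependent lamp roll-off in the white frame and a small positive dark
frame; calibration is therefore the exact inverse of scene construction, and
a noise-free scene round-trips to 1e-10.

What the generator does **not** emulate: wavelength-correlated instrument
drift, specular highlights, petri-dish rims, sample-height variation,
nonlinear detector response, and the chemical diversity of real feeds (the
dry component is one fixed profile per scene, not a mixture of ingredients).
Model metrics on synthetic tables are consequently optimistic — prediction
R² near 0.99+ versus ~0.93–0.98 on real scans — so passing tests demonstrate
correctness of the pipeline's algebra and plumbing, not field performance.

## Calibration and masking

Reflectance is `(raw − dark)/(white − dark)` elementwise; white/dark frames
may be full-frame or per-scan-line (broadcast).  Denominators below 1e-6 are
flagged invalid and output 0.

The mask thresholds the band nearest 1140 nm, where the sample is brightest
relative to the background.  The default threshold 0.46 reproduces the
instrument configuration this pipeline models; `"auto"` uses the midpoint of
the band image's max and min.  Cleanup is erosion (disk structuring element,
radius 1) followed by **morphological reconstruction** (binary propagation
of the eroded seed inside the thresholded image) and hole filling.
Reconstruction rather than bare erosion is deliberate: erosion alone would
shave a one-pixel ring off every object, biasing mean spectra at the sample
boundary, whereas reconstruction removes isolated specks smaller than the
structuring element while restoring surviving objects exactly — a clean disk
is recovered pixel-for-pixel.

## Preprocessing

Mean (`x/mean`), max (`x/max`) and range (min-max to [0, 1]) normalisation,
SNV with the sample (n−1) standard deviation, MSC by per-row OLS on a
reference spectrum and inversion `(x − b0)/b1`, and Savitzky-Golay
derivatives (first: window 11, order 2; second: window 11, order 3; both per
nm of the actual grid spacing, edges by polynomial extrapolation).  The MSC
reference is the calibration-set mean spectrum, frozen at fit time and
reused verbatim for validation rows and pixel spectra — every transform is
row-local once fitted, which is the precondition for pixel-wise mapping.
Spectra are restricted to 894–1917 nm (175 of 275 bands) *before* any
window-based transform, so the noisy detector region never leaks into
derivative windows.

## PLSR

NIPALS PLS1 with mean-centring, one component at a time, iteration cap 500
and tolerance 1e-10 on the score vector (for a univariate response the inner
loop converges immediately).  Extraction stops early if the residual
response is numerically exhausted.  The model collapses to
`β = W (PᵀW)⁻¹ q` with `intercept = ȳ − x̄·β`; score-path and β-path
predictions agree to 1e-8 and β equals the ordinary least-squares solution
at full latent rank (both tested, the latter also against scikit-learn's
PLS implementation as an independent reference).

Latent-variable count: leave-one-out CV over 1..10 candidates on the
calibration set, argmin of RMSE with ties to the smaller count.  Each fold
runs one NIPALS pass at the cap and evaluates all truncations, so LOO over
140 samples costs 140 fits, not 1400.  Metrics: R² = 1 − SSres/SStot (a
perfect fit scores exactly 1) and SEC/SEV/SEP as plain RMSE in percentage
points, without degrees-of-freedom or bias correction.  The 70/30 split is
simple random, shared across all methods, seeded and recorded.

## Mapping and decisions

Foreground pixel spectra are subset to the model's band window, transformed
by the frozen preprocessing (required for the nonlinear transforms — β was
learned in preprocessed space), multiplied by β, and folded back to an
image.  Background is NaN, never 0, so 0 % moisture stays representable.
The 3×3 median filter computes each foreground pixel's median over in-mask
neighbours only.  Decision rule: moisture above the high cut (default 40 %)
→ retreat for water control; below the low cut (default 20 %) → retreat
(too dry for immediate feeding, acceptable for storage contexts); otherwise
accept.  Cuts are exclusive: exactly 20 % or 40 % is accepted.  For a map
the decision statistic is the masked mean, matching the tabular protocol.

## Coefficient localisation

A moisture model should draw its signal from water absorption.  On synthetic
tables the |β| profile (smoothed over 5 bands) of the single-component model
— the X-y covariance direction — peaks within ±30 nm of a water lobe, and
the same holds for the majority of the eight methods at their cross-validated
complexity.  SNV is the documented exception: variance scaling redistributes
weight toward the dry-matter lobes, which carry the mirror-image (1 − m)
signal, and range normalisation can pin the deep 1450 nm trough near its
per-spectrum minimum with the same effect.  Both alternatives are legitimate
regression strategies — the dry lobes are genuinely informative — so the
localisation check is stated for the covariance direction and the method
majority, not for every transform.

## Problem sizes and numerical choices

Default experiment: 200 samples, 64×64×275 scenes, 175-band models, LOO over
140 calibration samples, 8 methods — the full acceptance run completes in
well under a minute on one CPU, and the test suite in a few seconds.  Guard
values: ε = 1e-6 for calibration denominators, |b1| ≥ 1e-12 for MSC slopes,
NIPALS weight-norm floor 1e-13.  Ties in `nearest_band` break toward the
lower index; the wavelength grid is the exact uniform partition of
[894, 2504] nm into 275 centres (spacing 1610/274 ≈ 5.876 nm), which
reproduces both the 275-band full grid and the 175-band low-noise window.

## Known limitations

- The generator's absorption lobes are Gaussian cartoons; real NIR bands are
  asymmetric and temperature-dependent.
- SEP/R²P on synthetic data overstate real-world accuracy (see above).
- MSC on pixel spectra uses the tabular mean-spectrum reference; real pixel
  populations have wider scatter than sample means, which can stress the
  |b1| guard on very dark pixels.
- The pipeline writes full-frame white/dark references; per-line references
  are accepted on input but not produced by the generator.
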
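# Methods

## Problem setting

After exposure to ionizing radiation, phosphorylated histone H2AX (γ-H2AX)
accumulates at DNA double-strand breaks within minutes, forming discrete
nuclear foci. Imaging flow cytometry (IFC) captures a brightfield and a
fluorescence raster for every cell in flow, so a single acquisition yields
three per-sample dose-response endpoints over a gated lymphocyte population:

* **MFI** — mean γ-H2AX fluorescence intensity per cell, averaged over the
  population (a.u.);
* **spot count** — mean number of detected γ-H2AX foci per cell;
* **spot area** — mean total focus-mask area per cell (pixels²).

`ifcdose` implements the full analysis chain for estimating an unknown
absorbed dose from these endpoints: a synthetic-data generator, image-level
feature extraction, calibration-curve fitting and inversion, a
K-nearest-neighbors (K-NN) non-parametric dose estimator, and an
evaluation/triage layer.

## Dose-response model

MFI is modeled as affine in dose D (Gy):

    MFI = α·D + β

with α the fluorescence gain per Gy and β the background at 0 Gy. Spot
count and spot area saturate:

    Y = v·(1 − exp(−ξ·D))

with plateau v and steepness ξ (1/Gy). The saturation is a projection
artifact, not a biological ceiling: at high dose, foci crowd the 2-D
nuclear image and co-located foci are segmented as a single spot, so
detected-spot endpoints plateau while total fluorescence keeps rising.
In the image-level generator this behaviour is emergent — foci are rendered
individually and merging happens in the detector — rather than imposed
parametrically.

## Synthetic-data generator

The generator emulates a calibration study of 10 donors × 9 samples each
(two unirradiated controls plus 0.5, 1, 2, 4, 6, 8, 10 Gy), with ~3,000
gated lymphocytes per sample, and a blinded validation set of 75 samples
from 9 fresh donors irradiated at the same dose levels.

Per-cell model (image level): the true focus count is Poisson with mean
`focus_rate · D`; foci are placed uniformly inside the nucleus interior as
2-D Gaussian bumps of width `focus_sigma`, each carrying integrated
intensity `alpha_true / focus_rate`, on a diffuse nuclear background that
integrates to `beta_true` — so expected integrated fluorescence is exactly
affine in dose. Contaminant events (apoptotic cells: bright condensed
fragments; debris: dim amorphous blobs) are injected at
`contaminant_fraction` and are separable from lymphocytes by circularity
and internal texture.

Noise structure (feature level): three multiplicative, mean-one log-normal
terms —

| term | default SD | acts on |
|---|---|---|
| donor effect (MFI) | `donor_sd = 0.10` | all samples of a donor |
| donor effect (spot endpoints) | `donor_sd / 2` | ditto |
| sample technical noise | `sample_noise_sd = 0.05` | each endpoint of each sample |
| per-cell noise | `cell_noise_sd = 0.15`, averaged to `0.15/√3000` | per-sample residual |

Spot endpoints get half the donor SD because between-donor variability in
staining efficiency and antibody uptake perturbs total fluorescence more
than focus yield per Gy, which is closer to a physical constant.
Multiplicative noise makes the absolute MFI scatter grow with dose — the
high-dose heteroscedasticity that degrades calibration-curve inversion.

Defaults `alpha_true = 30` a.u./Gy, `beta_true = 100` a.u. set a convenient
intensity scale; `focus_rate = 2.5` foci/Gy makes the noiseless detected-spot
curve rise roughly linearly below 4 Gy and plateau between 4 and 10 Gy;
feature-level plateaus `v = 25` spots / `120` px² with ξ = 0.25 / 0.22 per Gy
match the image-level shapes. `donor_sd` and `sample_noise_sd` were
calibrated once against the published scale of the method comparison
(calibration-curve RMSE peaking near 1.3 Gy, ±1 Gy coverage near 80% for CC
and 90% for K-NN) and are not adjusted thereafter.

What the generator does **not** emulate: optics, flow speed, spectral
compensation, camera noise, focus-intensity variation between breaks,
repair kinetics (everything is a single 1-hour-equivalent snapshot), and
any donor covariates (age, sex, smoking). Passing tests therefore
demonstrate correctness of the analysis chain under the assumed statistical
structure, not instrument-level fidelity.

## Image analysis

* **Whole-cell mask**: Otsu threshold on brightfield + hole fill, all
  components kept (a fragmented apoptotic event's mask covers every
  fragment, which is what makes its circularity low).
* **Nucleus mask**: largest connected component of the thresholded
  brightfield, holes filled, then a 4-pixel disc erosion — pulls the
  analysis region off the nuclear rim.
* **Spot mask**: inside the eroded nucleus, pixels exceeding the local
  background (median fluorescence within the mask) by `bright_ratio`
  percent of the cell's peak-above-background contrast; connected regions
  smaller than `min_spot_pixels = 2` are dropped. Each retained region
  necessarily contains a local intensity peak. Referencing the threshold to
  the peak contrast (rather than to the raw background level) keeps the
  knob meaningful when the diffuse background is near zero; `bright_ratio`
  defaults to 10 and is exposed in `GateConfig`.
* **Spot count**: connected components of the spot mask, 8-connectivity by
  default (4-connectivity available).
* **Spot area**: total spot-mask pixels per cell; the per-sample value is
  the population mean (a per-spot mean is available as a secondary
  statistic).
* **Gates**, in order: in-focus (gradient-RMS sharpness proxy; the default
  threshold passes all synthetic images because literal instrument cutoffs
  are hardware-specific), singlet (brightfield area and aspect-ratio
  windows), marker-positive (absolute MFI cutoff, derived from a high
  quantile of the 0 Gy control distribution via
  `gh2ax_positive_threshold`; disabled by default).
* **Healthy-lymphocyte classifier**: linear discriminant on
  (circularity, texture contrast) — round, internally smooth events are
  healthy lymphocytes; fragmented, textured events are apoptotic cells or
  debris. The simplest classifier realising that separation; serialises to
  one file.

Coordinates are row-major with the origin at the top-left pixel; masks are
boolean index sets; all areas are in pixel units. Mask nesting
(spot ⊆ eroded nucleus ⊆ nucleus ⊆ image) holds for every processed cell.

## Calibration fits and CC inversion

Both response forms are fitted by unweighted least squares —
`numpy.linalg.lstsq` for the linear form, bounded
`scipy.optimize.curve_fit` (v, ξ > 0, initialised at v₀ = max y,
ξ₀ = 1/mean dose) for the saturating form — with parameter covariance and
95% bands. The saturating initialisation is robust for plateauing data;
non-convergence raises with the solver message.

Calibration-curve (CC) dose estimation inverts the linear MFI fit:
D̂ = (MFI_obs − β)/α, truncated below at 0 Gy (flagged in diagnostics).
The 95% interval inverts the fit's *prediction* band — solving the Fieller
quadratic for the doses where the band straddles the observed value. The
prediction band (which includes the single-observation variance term) is
used rather than the mean-response band because the query is one new
sample, not an estimate of the calibration mean; when the quadratic's
leading coefficient or discriminant is non-positive (slope indistinguishable
from band growth) the interval is reported as unbounded rather than
invented. Confidence level is fixed at 95% throughout.

## K-NN dose estimator

The query's endpoint vector is placed among the n = 90 calibration rows and
the estimate is the mean delivered dose of its k nearest rows under
Euclidean distance (default k = 7). Columns are standardized by the
calibration set's own mean/SD before distances are taken — raw MFI
(hundreds of a.u.) would otherwise dominate spot count (tens) and make two
of the three endpoints irrelevant. Queries are always transformed with the
frozen calibration statistics, never their own. Ties at the k-th distance
break deterministically by calibration-row index; duplicate rows are
allowed and legitimately weight the neighborhood.

*Tuning*: a seeded 70:30 split of the calibration rows; every test-row dose
is estimated from the training rows for each k in 1..15; the RMSE-minimising
k is selected (ties to the smaller k). Under the default noise the selected
k concentrates in a small interior range — large enough to vote down a
mislabelled nearest neighbour, small enough not to drag in adjacent dose
levels.

*Confidence intervals*: percentile bootstrap over calibration rows
(B = 2000 by default). Distances are invariant under row resampling, so
each replicate reuses the precomputed distance vector; standardization
statistics stay frozen; replicates with fewer than k distinct rows are
redrawn. The bootstrap unit is the calibration sample row (not the donor,
not the cell) — the simplest standard scheme.

Every estimate is a mean of calibration doses, hence bounded by
[min D, max D]; the estimator cannot extrapolate beyond the calibrated
range, which is the price paid for its robustness to the high-dose MFI
heteroscedasticity.

## Evaluation and triage

RMSE = √(mean (D̂ᵢ − Dᵢ)²), overall and within true-dose bins (default
edges 0, 2, 4, 6, 8, 10 Gy; empty bins reported as absent). Tolerance
coverage counts |D̂ − D| ≤ t for t = 0.5 and 1 Gy, boundary inclusive.
Triage dichotomizes at 2 Gy, boundary inclusive (an estimate of exactly
2 Gy is positive, i.e. referred for cytogenetic follow-up); the truth label
applies the same rule to the delivered dose. The confusion report exposes
per-class precision and recall; a metric whose denominator is empty is
reported as NaN, never coerced to 0.

## Pipeline and reproducibility

`run_pipeline` executes simulate → calibrate → estimate (CC and K-NN) →
evaluate, writing tab-delimited tables, JSON fit files, and a manifest with
the canonical-config hash and a sha256 checksum per artifact. Every
stochastic stage draws from a named substream derived from the single
global seed, so a (config, seed) pair reproduces byte-identical artifacts
and manifests; the manifest deliberately carries no timestamps, since they
would break that contract.

## Problem sizes

Tests and the acceptance script use the feature-level generator for
population-scale statements (50 replicate studies of 90 calibration + 75
validation samples run in seconds) and the image-level generator at reduced
raster/population sizes (48–64 px frames, tens to hundreds of cells) where
the assertion is about masks, merging, or classification geometry. These
sizes are the package's own defaults for its test fixtures; the generator's
scientific defaults (3,000 cells/sample, 64 px frames) remain those of the
emulated study design.

## Known limitations

* The exact semantics of the commercial instrument's "tight" object mask
  and peak mask are unpublished; the implementations here are reasonable
  morphological readings, and absolute endpoint values are not expected to
  match any particular instrument.
* MFI is computed over the whole-cell mask for all gated cells; computing
  it over nucleus pixels only is a defensible alternative.
* The linear MFI fit pools all donors (per-donor fitting is available as an
  option but not the default).
* Generator variances are design choices, not estimates from cell-level
  data; all downstream statistical claims are conditional on them.
* K-NN estimates cannot exceed the calibrated dose range; doses above
  10 Gy would be reported as ≈10 Gy.
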
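# Methods

This note records the models, algorithms and design choices behind
`nirmc`, in the spirit of a software methods section: what is computed,
under which assumptions, and which decisions were genuinely open.

## Spectral data model

Spectra are apparent absorbance, log(1/R), from diffuse reflectance on a
shared strictly-increasing wavelength grid in nm. The default instrument
emulation has **1557 points spanning 1000–2500 nm sampled uniformly in
wavenumber** (10000 → 4000 cm⁻¹) and converted to nm. This reconciles a
Fourier-transform instrument's constant-wavenumber sampling with a
stated nm range: 751 points would result from a literal 2 nm spacing,
and 1557 points cannot be uniform in nm over that range. The grid length
and span are configurable; nothing downstream assumes uniform spacing.
Nearest-wavelength lookup breaks ties toward the lower wavelength, a
deterministic documented convention.

Replicate spectra (3 per sample by default) are arithmetically averaged
before modelling; species, origin and role must be constant within a
sample. Calibration/validation splitting is by origin, with disjoint,
jointly covering label lists.

The canonical file format is a wide CSV
(`sample_id,species,origin,replicate,role,mc` + one column per
wavelength) written with shortest round-tripping float reprs, so
write→read is value-identical. A minimal JCAMP-DX-like reader
(`##XUNITS=NANOMETERS`, XY pairs) covers single-spectrum imports.

## Reference moisture

Wet-basis MC is `(W_w − W_d)/W_w`, reported in % (the library returns the
fraction; reporting multiplies by 100). Duplicate determinations are
averaged per sample; the duplicate spread is the SD with n−1 denominator,
defined only for samples with ≥ 2 duplicates. The 8.0–12.5 % trade
safety range is a closed interval: both boundaries classify as
`in_range`. Oven drying also removes ~0.4 % non-water mass in real
beans; the generator exposes this as `nonwater_loss` (default off).

## Pre-treatments

All windowed filters use reflection padding so output length equals
input length. Gaussian smoothing uses sigma = window/4 with the kernel
truncated to the window. Savitzky–Golay derivatives are taken **with
respect to grid index** (unit spacing), because the default grid is not
uniform in nm; this keeps coefficient magnitudes comparable across the
grid and is documented rather than hidden. The window must exceed the
polynomial order (the least-squares fit requirement); the study grid's
window 3 with polynomial order 2 is therefore admissible, while window 3
with order 3 is not.

MSC/EMSC fit each spectrum against the calibration mean m by least
squares, `x ≈ a·1 + b·m + Σ cᵢ tⁱ` with t the wavelength affinely mapped
to [−1, 1] (polynomial order 0 = MSC, default EMSC order 2), and return
`(x − a − Σ cᵢ tⁱ)/b`. A slope |b| < 1e−8 is a degenerate fit. The
correction inverts the generator's scatter model *exactly* when the
chemistry content of the scattered spectrum lies in the fitted basis
(e.g. scatter applied to the reference itself); for general spectra the
least-squares fit absorbs part of the per-sample chemistry deviation
into (a, b, c), so recovery is approximate — this is inherent to EMSC,
not an implementation artifact, and the test suite asserts the exact
case at 1e−8 and the general case loosely.

OSC removes one or more spectral components orthogonal to the response:
each component iterates (orthogonalise score against y → weights →
score) to a fixed point (tolerance 1e−10 on the score change, max 500
iterations), orthogonalises the final training score against y, and
deflates `X − t pᵀ`. New samples are deflated with the stored weight and
loading vectors; since y is unavailable at prediction time, their scores
are not re-orthogonalised — the standard OSC asymmetry.

The comparison harness sweeps the full catalogue (15 smoothers, 14 SG
derivative variants, 2 normalisations, 2 baselines, SNV, MSC, EMSC, OSC,
plus raw) and ranks by leave-one-out RMSECV with the pre-treatment
refitted inside every fold, so stateful treatments never see the held-out
sample. This reproduces the *procedure* of finding the best
pre-treatment, not any data-specific outcome.

## Outlier screening

Mean-centered PCA (SVD); screening uses 2 components by default.
Hotelling's T² per sample is `Σ score²/eigenvalue` over retained
components, compared against the F-based critical value
`p(n−1)/(n−p)·F₁₋α(p, n−p)` at α = 0.05. Flagged samples are then
*arbitrated*, not dropped: the calibration PLSR is refitted with and
without them and removal is recommended only if LOO RMSECV improves by
more than 10 % relative (a documented default for an inherently
qualitative "not significantly affected" judgement). High-T² samples in
a calibrated range are often legitimate extremes.

## Calibration models

PLS1 via classical NIPALS on mean-centered, **unscaled** data: weights
`w ∝ Xcᵀyc`, scores `t = Xc w`, loadings `p = Xcᵀt/tᵀt`,
`q = ycᵀt/tᵀt`, deflation `Xc ← Xc − t pᵀ`; regression vector
`b = W(PᵀW)⁻¹q`. Because no variable scaling is applied anywhere,
"weighted" and raw regression coefficients coincide (asserted by test).
With as many components as the rank, PLS1 reproduces OLS, which the
suite checks against the normal equations and against scikit-learn's
PLSRegression as an independent implementation.

"Full cross validation" is leave-one-out with re-centering per fold; the
NIPALS components are nested, so one max-LV fit per fold yields the
held-out prediction at every truncated component count. The
parsimonious-LV rule picks the smallest count whose RMSECV is within 5 %
(configurable) of the minimum; the workflow also accepts explicit counts,
and its defaults (3 raw / 4 EMSC / 3 subset) mirror the study's choices.

MLR is OLS with intercept; rank deficiency is an error naming the
dependent columns. Its calibration error uses leverage correction
`sqrt(mean((e_i/(1−h_i))²))` with hat diagonals from the QR of the
design — the mean (not n−1) normalisation is used and, for OLS, the
corrected residuals are exactly the leave-one-out residuals (asserted
against a brute-force refit loop).

## Validation statistics

For residuals e = ŷ − y: bias = mean(e), RMSEP = √mean(e²),
SEP = √(Σ(e−bias)²/(n−1)), R² = 1 − SSE/SST (not squared Pearson, for
consistency with the RMSE-based reporting), RPD = SD(y, n−1)/SEP. These
satisfy RMSEP² = bias² + SEP²(n−1)/n identically. A zero SEP yields an
infinite RPD, rendered as the string "inf" in tables rather than being
dropped. The model-comparison table rounds R² to 4 decimals and errors
to 2.

Two models' prediction errors on the same validation samples are
compared with a two-sided paired t-test on dᵢ = e²ₐᵢ − e²ᵦᵢ (the test
behind such p-values is rarely named in applied reports; the paired-t
interpretation is the documented default), with a seeded sign-flip
randomization test (10⁴ resamples) as a distribution-free alternative.

## Synthetic-data generator

The generator defines the study conditions, not a tunable benchmark:

* 108 samples — 64 calibration from 7 origins (10,9,9,9,9,9,9; an equal
  split is impossible since 64 is not divisible by 7) and 44 validation
  from 5 origins (9,9,9,9,8). Three origin names recur across purposes
  in the study design; the validation copies get a " (val)" suffix so
  origin-based splitting stays well-defined.
* True MC ~ U(6, 22) % wet basis; species fixed per origin.
* Chemistry spectra are sums of Gaussian bands: water bands at 1450 and
  1940 nm carry the moisture signal (0.013 and 0.020 AU per % MC around
  the 14 % midpoint), constituent bands near 1155, 1212, 1340, 1409,
  1724 and 2249 nm carry small moisture sensitivities of both signs and
  species offsets, and a broad background band carries a 0.25 AU
  species-level offset so that the species contrast dominates total
  spectral variance — matching real Arabica/Robusta reflectance data,
  where the first principal component separates the species while
  moisture loads on later components.
* Each replicate (3 per sample) receives an independent scatter draw of
  exactly the EMSC form — offset a ~ N(0, 0.02), multiplier
  b ~ N(1, 0.05), order-2 polynomial coefficients ~ N(0, 0.01) — plus
  iid spectral noise of SD 0.002 AU.
* Gravimetric duplicates (2 per sample) are realised as (W_w, W_d) pairs
  with W_w ~ N(10 g, 0.1 g). The configured duplicate SD (0.21 % MC) is
  the *expected observed* within-sample SD: the Gaussian scale is divided
  by the c4(n) small-sample factor (c4(2) ≈ 0.798), since the n−1 SD of
  two duplicates is biased low and the quantity a study reports is the
  average measured SD.
* One global seed drives four named sub-streams (moisture, scatter,
  noise, gravimetry) via `default_rng([seed, stream])`; identical
  (config, seed) pairs are bit-identical.

What the generator does **not** emulate: radiative transfer or
Kubelka–Munk physics, humidity-equilibration kinetics, wavelength-
dependent noise, instrument drift, and the exact variance decomposition
of the real data. Passing tests therefore demonstrate that the
*pipeline* recovers known structure under realistic magnitudes, not that
it would achieve any particular accuracy on real beans.

A second configuration (`make_band_recovery_config`) places all
moisture-informative bands exactly at the seven published wavelengths,
giving wavelength selection a known ground truth: coefficient-based
peak picking recovers ≥ 6 of the 7 band centres within ±15 nm in the
majority of seeds.

## Wavelength selection

The published model was built from seven wavelengths chosen by visual
inspection of the PLSR coefficient plot. The reproducible surrogate
here: local maxima of |b| (plateaus resolve to their lower-wavelength
edge), keep the k = 7 largest greedily subject to a pairwise separation
of ≥ 20 nm, ties toward the lower wavelength, result sorted ascending.
The published predictor itself ships as an immutable constant table and
is evaluated exactly as printed.

## Problem sizes and determinism

Default runs use the full study geometry (108 samples × 1557
wavelengths, 3 replicates); the complete pre-treatment sweep with
fold-wise refitting takes ~10 s, a single workflow run well under a
second, and the 10-seed stability study a few seconds. All simulations,
randomization tests and seed sweeps derive from explicit integer seeds;
reports regenerate byte-identically.

## Known limitations

* EMSC fidelity to any specific commercial implementation ("full MSC
  model" variants) is not claimed; the basis is {1, m, t, t²}.
* OSC removes variation orthogonal to y on the training set only;
  new-sample deflation reuses fixed weights (see above).
* SEP has no published numeric anchor in the study this emulates, so it
  is validated only through the RMSEP/bias/SEP identity.
* The paired-t interpretation of the published p-value is an assumption;
  the randomization test is provided for robustness.
* Which four real samples were T²-flagged in the original data is
  unknowable without the spectra; only the screening procedure is
  reproduced.
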
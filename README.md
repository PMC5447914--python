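# nirmc — NIR moisture-content chemometrics for green coffee beans

Moisture content (MC, % wet basis) is the quality parameter that decides
whether green coffee can be traded at all: the accepted safety range is
8.0–12.5 % (drier beans shrink; wetter beans grow fungi and mycotoxins).
The reference method is slow gravimetry — oven-drying ~10 g of whole
beans for 16 h and computing the relative mass loss

    MC = (W_w − W_d) / W_w

from wet weight `W_w` and dried weight `W_d`. `nirmc` implements the
chemometric alternative: predicting MC directly from near-infrared
diffuse-reflectance spectra, log(1/R) on 1000–2500 nm, of intact beans
of both *Coffea arabica* and *C. canephora* (Robusta).

The package is organised as an analysis project: the library under
`src/nirmc/` holds every computational step, and the numbered scripts
under `analysis/` narrate the workflow over a synthetic, study-structured
dataset (the original spectra were never deposited, so a first-class
generator stands in for them).

## What the library implements

* **Spectra handling** (`spectra`) — a `SpectraSet` container on a shared
  wavelength grid (default: 1557 points spanning 1000–2500 nm, uniform in
  wavenumber), wide-CSV and minimal JCAMP-DX-like I/O, replicate
  averaging, origin-based calibration/validation splitting, wavelength
  subsetting.
* **Reference moisture** (`gravimetric`) — wet-basis MC from duplicate
  weighings, duplicate-spread summaries, safety-range classification.
* **Pre-treatments** (`preprocess`) — smoothing (moving average,
  Gaussian, median), Savitzky–Golay derivatives, area/mean normalisation,
  offset/linear baselines, SNV, MSC and polynomial EMSC, NIPALS-style
  orthogonal signal correction; all with strict fit-on-calibration /
  apply-to-validation discipline, plus a harness that ranks the whole
  catalogue by leave-one-out RMSECV.
* **Outlier screening** (`outliers`) — mean-centered PCA, Hotelling's T²
  with the F-based 5 % ellipse, and a keep/drop decision that refits the
  calibration with and without flagged samples.
* **Calibration** (`models`) — NIPALS PLS1 (mean-centered, unscaled;
  `b = W(PᵀW)⁻¹q`), full-rank MLR, leave-one-out cross-validation,
  parsimonious latent-variable choice, leverage-corrected error
  (`e_i/(1−h_i)`, exact LOO for OLS).
* **Wavelength selection** (`wavelengths`) — peak picking on |b| of the
  full-spectrum PLSR with a minimum-separation rule, subset refits, and
  the published seven-wavelength predictor
  `MC(%) = −4.20 + 115.02·V1 + 0.40·V2 − 116.18·V3 + 76.16·V4 − 97.72·V5
  + 63.76·V6 − 17.59·V7` at 1155, 1212, 1340, 1409, 1724, 1908, 2249 nm.
* **Validation metrics** (`metrics`) — R², RMSEC/RMSECV/RMSEP, SEP, bias,
  RPD, the table-shaped model report, and paired squared-error tests
  (paired t and sign-flip randomization).
* **Synthetic data** (`simulate`) — Gaussian-band chemistry spectra with
  water bands at 1450/1940 nm, species offsets, EMSC-form multiplicative
  and polynomial scatter, replicate noise, and duplicate gravimetric
  records; 64 calibration + 44 validation samples, MC ~ U(6, 22) %.
* **Workflow/CLI** (`workflow`, `cli`) — the orchestrated end-to-end run
  and a small `nirmc simulate|run|predict` command-line front end.

## Worked example

```bash
python analysis/04_calibrate_and_validate.py
```

simulates the default dataset (seed 1), screens outliers, fits the four
model configurations, and prints:

```
                    raw_plsr emsc_plsr subset_mlr subset_pls
LVs                        3         4        n/a          3
R2 calibration        0.9925    0.9999     0.9942     0.9803
R2 cross validation   0.9889    0.9872     0.9921     0.9775
RMSEC (% MC)            0.39      0.04       0.35       0.64
RMSECV (% MC)           0.48      0.51       0.40       0.68
R2 prediction         0.9883    0.9874     0.9909     0.9567
RMSEP (% MC)            0.48      0.50       0.43       0.93
Bias (% MC)             0.12      0.07      -0.02      -0.00
RPD                     9.55      8.98      10.51       4.81
```

Columns are the four study configurations: full-spectrum PLSR on raw and
on EMSC-corrected spectra, and MLR / 3-LV PLS on seven selected
wavelengths. RMSEP is the root-mean-square validation error in % MC
(here ~0.4–0.9 % MC against a reference method whose own duplicate error
is ~0.2 % MC); RPD is the ratio of the validation-set reference SD to the
bias-corrected prediction error — values above 3 are conventionally
considered good for screening use. The other drivers
(`01_simulate_dataset.py`, `02_screen_outliers.py`,
`03_compare_preprocessing.py`, `05_seed_stability.py`) generate the data
files, run the T² screening, rank all 38 pre-treatments by RMSECV, and
replicate the comparison over 10 seeds.

Predicting from the published constants directly:

```python
>>> from nirmc.wavelengths import published_predict
>>> published_predict([0, 0, 0, 0, 0, 0, 0])
-4.2
```

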
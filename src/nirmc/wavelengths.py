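"""Wavelength selection from PLSR regression coefficients.

The full-spectrum PLSR coefficient vector b is scanned for local maxima
of |b|; the k largest peaks are kept greedily subject to a minimum
pairwise separation (default 20 nm), a deterministic surrogate for
picking informative bands off a coefficient plot by eye.  The selected
columns are then refitted as small MLR or PLS models.

The module also ships the published seven-wavelength moisture predictor
for intact green coffee beans,

    MC (%) = -4.20 + 115.02 V1 + 0.40 V2 - 116.18 V3 + 76.16 V4
             - 97.72 V5 + 63.76 V6 - 17.59 V7,

where V1..V7 are the log(1/R) intensities at 1155, 1212, 1340, 1409,
1724, 1908 and 2249 nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, SelectionError
from .models import MlrModel, PlsModel, fit_mlr, fit_plsr
from .spectra import SpectraSet, WavelengthGrid, subset_wavelengths

#: The published predictor's wavelengths (nm) and coefficients (% MC per
#: absorbance unit); immutable constants exactly as printed.
PUBLISHED_WAVELENGTHS = (1155.0, 1212.0, 1340.0, 1409.0, 1724.0, 1908.0, 2249.0)
PUBLISHED_COEFFICIENTS = (115.02, 0.40, -116.18, 76.16, -97.72, 63.76, -17.59)
PUBLISHED_INTERCEPT = -4.20


@dataclass(frozen=True)
class PublishedMoistureModel:
    """The printed seven-wavelength MLR moisture predictor."""

    intercept: float = PUBLISHED_INTERCEPT
    coefficients: tuple = PUBLISHED_COEFFICIENTS
    wavelengths: tuple = PUBLISHED_WAVELENGTHS

    def predict(self, v: Sequence[float]) -> float:
        return published_predict(v)

    def to_frame(self) -> pd.DataFrame:
        """Constant table (wavelength, coefficient) for CSV export."""
        return pd.DataFrame({
            "wavelength_nm": ("intercept",) + self.wavelengths,
            "coefficient": (self.intercept,) + self.coefficients,
        })


def published_predict(v: Sequence[float]) -> float:
    """Evaluate the published predictor at seven log(1/R) intensities,
    given in the documented wavelength order."""
    v = np.asarray(v, dtype=float).ravel()
    if v.shape != (7,):
        raise ArgumentError(f"expected exactly 7 intensities, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ArgumentError("intensities must be finite")
    return float(PUBLISHED_INTERCEPT + np.dot(PUBLISHED_COEFFICIENTS, v))


def select_wavelengths(b: np.ndarray, grid: WavelengthGrid, k: int = 7,
                       min_separation: float = 20.0) -> np.ndarray:
    """Pick the k strongest |b| local maxima with pairwise separation.

    Peaks are interior points where |b| is >= both neighbours (ties on a
    plateau resolve to its lower-wavelength edge); the k largest are kept
    greedily, skipping any within ``min_separation`` nm of an accepted
    peak; equal-magnitude ties prefer the lower wavelength.  Returns the
    selected wavelengths sorted ascending.
    """
    b = np.asarray(b, dtype=float).ravel()
    if b.size != len(grid):
        raise ArgumentError("coefficient vector length must equal grid length")
    if k < 1:
        raise ArgumentError("k must be >= 1")
    mag = np.abs(b)
    lam = grid.values
    interior = np.arange(1, b.size - 1)
    is_peak = (mag[interior] > mag[interior - 1]) & (mag[interior] >= mag[interior + 1])
    peaks = interior[is_peak]
    if peaks.size == 0:  # fall back to the global argmax (flat/monotone b)
        peaks = np.array([int(np.argmax(mag))])
    order = sorted(peaks, key=lambda i: (-mag[i], lam[i]))
    chosen: list[int] = []
    for i in order:
        if all(abs(lam[i] - lam[j]) >= min_separation for j in chosen):
            chosen.append(i)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise SelectionError(
            f"only {len(chosen)} admissible peaks found, needed {k}",
            n_found=len(chosen))
    return np.sort(lam[chosen])


def refit_subset(cal: SpectraSet, y: np.ndarray, wavelengths: Sequence[float],
                 method: str = "pls", n_lv: int = 3,
                 tolerance: float = 2.0) -> MlrModel | PlsModel:
    """Refit an MLR or PLS model on the selected wavelength columns."""
    if len(wavelengths) == 0:
        raise ArgumentError("empty wavelength list")
    sub = subset_wavelengths(cal, wavelengths, tolerance)
    if method == "mlr":
        return fit_mlr(sub.X, y, wavelengths=sub.grid.values)
    if method == "pls":
        if n_lv > len(wavelengths):
            raise ArgumentError(
                f"n_lv {n_lv} exceeds the {len(wavelengths)} selected wavelengths")
        return fit_plsr(sub.X, y, n_lv, wavelengths=sub.grid.values)
    raise ArgumentError(f"unknown method {method!r}")
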
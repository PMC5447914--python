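"""Spectral pre-treatments.

Every transformer follows the fit-on-calibration / apply-anywhere
discipline: methods with fitted state (MSC/EMSC reference spectrum, OSC
weights) must be fitted on calibration data and are then applied unchanged
to validation data, so no information leaks from the validation set.

Stateless row-wise treatments (smoothing, Savitzky-Golay derivatives,
normalisation, baseline correction, SNV) are plain functions over 1-D or
2-D arrays, wrapped by small transformer classes so the whole catalogue
can be swept uniformly by :func:`compare_preprocessing`.

Windowed filters use reflection padding at the edges so the output length
equals the input length.  Savitzky-Golay derivatives are taken with
respect to grid *index* (unit spacing): the default instrument grid is
non-uniform in nm, and index-based derivatives keep coefficient magnitudes
comparable across the grid.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, signal

from .exceptions import (
    ArgumentError,
    ConvergenceError,
    DegenerateFitError,
    DegenerateSpectrumError,
    RankError,
)
from .spectra import SpectraSet, WavelengthGrid

DEFAULT_WINDOWS = (3, 7, 11, 15, 19)
SG_CONFIGS = ((1, 2), (2, 2), (3, 3))  # (derivative order, polynomial order)


def _check_window(window: int, n: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ArgumentError(f"window must be odd and >= 3, got {window}")
    if window > n:
        raise ArgumentError(f"window {window} exceeds spectrum length {n}")


# -- stateless row-wise treatments ---------------------------------------

def smooth(x: np.ndarray, method: str = "moving_average", window: int = 11) -> np.ndarray:
    """Smooth along the last axis with reflection padding.

    ``gaussian`` uses sigma = window/4 with the kernel truncated to the
    window; ``median`` is a running median.
    """
    x = np.asarray(x, dtype=float)
    _check_window(window, x.shape[-1])
    if method == "moving_average":
        return ndimage.uniform_filter1d(x, size=window, axis=-1, mode="reflect")
    if method == "gaussian":
        sigma = window / 4.0
        radius = (window - 1) // 2
        return ndimage.gaussian_filter1d(x, sigma=sigma, axis=-1,
                                         mode="reflect", truncate=radius / sigma)
    if method == "median":
        if x.ndim == 1:
            return ndimage.median_filter(x, size=window, mode="reflect")
        return np.stack([ndimage.median_filter(row, size=window, mode="reflect")
                         for row in x])
    raise ArgumentError(f"unknown smoothing method {method!r}")


def sg_derivative(x: np.ndarray, deriv: int, poly: int, window: int) -> np.ndarray:
    """Savitzky-Golay derivative w.r.t. grid index, reflection edges."""
    x = np.asarray(x, dtype=float)
    if deriv > poly:
        raise ArgumentError(
            f"derivative order {deriv} exceeds polynomial order {poly}")
    if deriv < 0 or poly < 1:
        raise ArgumentError("need deriv >= 0 and poly >= 1")
    _check_window(window, x.shape[-1])
    if window <= poly:
        raise ArgumentError(
            f"window {window} too small for polynomial order {poly}")
    return signal.savgol_filter(x, window, poly, deriv=deriv, delta=1.0,
                                axis=-1, mode="mirror")


def normalize(x: np.ndarray, mode: str = "mean", spacing: float = 1.0) -> np.ndarray:
    """Mean normalisation (output mean 1) or area normalisation (unit
    absolute area, using the given grid spacing)."""
    x = np.asarray(x, dtype=float)
    if mode == "mean":
        denom = x.mean(axis=-1, keepdims=True)
    elif mode == "area":
        denom = np.abs(x).sum(axis=-1, keepdims=True) * spacing
    else:
        raise ArgumentError(f"unknown normalization mode {mode!r}")
    if np.any(np.abs(denom) < 1e-300):
        raise DegenerateSpectrumError(f"zero {mode} denominator")
    return x / denom


def baseline_correct(x: np.ndarray, mode: str = "offset") -> np.ndarray:
    """Subtract the minimum (offset) or the least-squares line (linear)."""
    x = np.asarray(x, dtype=float)
    if mode == "offset":
        return x - x.min(axis=-1, keepdims=True)
    if mode == "linear":
        n = x.shape[-1]
        if n < 2:
            raise ArgumentError("linear baseline needs at least 2 points")
        t = np.arange(n, dtype=float)
        t = (t - t.mean()) / t.std()
        xm = x.mean(axis=-1, keepdims=True)
        slope = (x - xm) @ t / (t @ t)
        return x - xm - np.outer(np.atleast_1d(slope), t).reshape(x.shape)
    raise ArgumentError(f"unknown baseline mode {mode!r}")


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centre and scale to unit SD
    (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd < 1e-300):
        raise DegenerateSpectrumError("constant spectrum has no SNV transform")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


# -- transformer protocol -------------------------------------------------

class Preprocessor:
    """Fit/transform protocol over 2-D spectra matrices; the base class
    is the identity (raw spectra)."""

    name = "raw"
    needs_y = False

    def fit(self, X: np.ndarray, y: np.ndarray | None = None,
            grid: WavelengthGrid | None = None) -> "Preprocessor":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)

    def fit_transform(self, X, y=None, grid=None):
        return self.fit(X, y, grid).transform(X)

    def spec(self) -> dict:
        """Serialisable description (method + parameters)."""
        return {"method": self.name}


class RowwisePreprocessor(Preprocessor):
    """Stateless treatment applied row by row."""

    def __init__(self, name: str, fn: Callable[[np.ndarray], np.ndarray],
                 params: dict | None = None):
        self.name = name
        self.fn = fn
        self.params = params or {}

    def transform(self, X):
        return self.fn(np.asarray(X, dtype=float))

    def spec(self):
        return {"method": self.name, **self.params}


class ScatterCorrection(Preprocessor):
    """MSC / EMSC against the calibration mean spectrum.

    Each spectrum x is modelled as

        x = a·1 + b·m + c1·t + ... + cp·t^p + residual,

    with m the calibration mean and t the wavelength affinely mapped to
    [-1, 1]; the correction returns (x - a - sum_i ci t^i)/b.  poly_order 0
    is plain MSC; the EMSC default is order 2.
    """

    def __init__(self, poly_order: int = 2):
        if poly_order not in (0, 1, 2):
            raise ArgumentError("poly_order must be 0 (MSC), 1 or 2")
        self.poly_order = poly_order
        self.name = "msc" if poly_order == 0 else f"emsc{poly_order}"
        self.reference_: np.ndarray | None = None
        self._basis: np.ndarray | None = None

    def fit(self, X, y=None, grid=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise ArgumentError("scatter correction needs >= 2 calibration rows")
        if grid is None:
            raise ArgumentError("scatter correction needs the wavelength grid")
        self.reference_ = X.mean(axis=0)
        t = grid.scaled()
        cols = [np.ones_like(t), self.reference_]
        cols += [t ** k for k in range(1, self.poly_order + 1)]
        self._basis = np.column_stack(cols)
        return self

    def transform(self, X):
        if self.reference_ is None:
            raise ArgumentError("scatter correction not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        coef, *_ = np.linalg.lstsq(self._basis, X.T, rcond=None)
        a, b = coef[0], coef[1]
        if np.any(np.abs(b) < 1e-8):
            raise DegenerateFitError("scatter slope estimate too close to zero")
        nuisance = np.zeros_like(X)
        t = self._basis[:, 2:]  # polynomial columns
        if t.size:
            nuisance = (t @ coef[2:]).T
        return (X - a[:, None] - nuisance) / b[:, None]

    def spec(self):
        return {"method": "msc" if self.poly_order == 0 else "emsc",
                "poly_order": self.poly_order}


class OrthogonalSignalCorrection(Preprocessor):
    """NIPALS-style OSC: remove spectral variation orthogonal to y.

    Each component iterates (score orthogonalisation against y, weight
    estimation, score update) to a fixed point; the removed training score
    is orthogonalised against y before deflation.  New samples are deflated
    with the stored weight/loading pairs.  n_components = 0 is the identity.
    """

    def __init__(self, n_components: int = 1, tol: float = 1e-10,
                 max_iter: int = 500):
        if n_components < 0:
            raise ArgumentError("n_components must be >= 0")
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.name = f"osc{n_components}"
        self.x_mean_: np.ndarray | None = None
        self.weights_: list[np.ndarray] = []
        self.loadings_: list[np.ndarray] = []
        self.train_scores_: list[np.ndarray] = []

    def fit(self, X, y=None, grid=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if y is None:
            raise ArgumentError("OSC requires the response vector at fit time")
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        if n != y.size or n < 3:
            raise ArgumentError("OSC needs matching X rows and y, n >= 3")
        if self.n_components >= min(n - 1, X.shape[1]):
            raise RankError("n_components must be below the data rank")
        self.x_mean_ = X.mean(axis=0)
        Xc = X - self.x_mean_
        yc = y - y.mean()
        self.weights_, self.loadings_, self.train_scores_ = [], [], []
        for _ in range(self.n_components):
            w, t_orth = _osc_component(Xc, yc, self.tol, self.max_iter)
            p = Xc.T @ t_orth / (t_orth @ t_orth)
            Xc = Xc - np.outer(t_orth, p)
            self.weights_.append(w)
            self.loadings_.append(p)
            self.train_scores_.append(t_orth)
        return self

    def transform(self, X):
        if self.x_mean_ is None:
            raise ArgumentError("OSC not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.x_mean_
        for w, p in zip(self.weights_, self.loadings_):
            t = Xc @ w
            Xc = Xc - np.outer(t, p)
        return Xc + self.x_mean_

    def spec(self):
        return {"method": "osc", "n_components": self.n_components}


def _osc_component(Xc: np.ndarray, yc: np.ndarray, tol: float,
                   max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """One OSC component: converged weight vector and its y-orthogonal
    training score."""
    yy = yc @ yc
    # start from the first principal score
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    t = u[:, 0] * s[0]
    for _ in range(max_iter):
        t_orth = t - yc * (yc @ t) / yy
        w = Xc.T @ t_orth
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            raise ConvergenceError("OSC weight vector vanished")
        w = w / nw
        t_new = Xc @ w
        if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
            t = t_new
            break
        t = t_new
    else:
        raise ConvergenceError(f"OSC did not converge in {max_iter} iterations")
    t_orth = t - yc * (yc @ t) / yy
    return w, t_orth


# -- module-level constructors matching the workflow surface ---------------

def fit_scatter(cal: SpectraSet, method: str = "emsc",
                poly_order: int | None = None) -> ScatterCorrection:
    """Fit MSC (poly_order 0) or EMSC (default order 2) on calibration data."""
    if method == "msc":
        order = 0
    elif method == "emsc":
        order = 2 if poly_order is None else poly_order
        if order < 1:
            raise ArgumentError("EMSC needs poly_order >= 1; use msc for 0")
    else:
        raise ArgumentError(f"unknown scatter method {method!r}")
    return ScatterCorrection(poly_order=order).fit(cal.X, grid=cal.grid)


def fit_osc(cal: SpectraSet, y: np.ndarray,
            n_components: int = 1) -> OrthogonalSignalCorrection:
    return OrthogonalSignalCorrection(n_components).fit(cal.X, y, cal.grid)


# -- the comparison catalogue ---------------------------------------------

def preprocessing_catalogue(windows: Sequence[int] = DEFAULT_WINDOWS,
                            sg_configs: Sequence[tuple[int, int]] = SG_CONFIGS,
                            ) -> list[Callable[[], Preprocessor]]:
    """Factories for the full pre-treatment grid swept by the study design:
    3 smoothers x windows, 3 SG derivative configs x windows, 2
    normalisations, 2 baselines, SNV, MSC, EMSC and 1-component OSC."""
    factories: list[Callable[[], Preprocessor]] = []

    def rowwise(name, fn, **params):
        factories.append(lambda name=name, fn=fn, params=params:
                         RowwisePreprocessor(name, fn, params))

    for m in ("moving_average", "gaussian", "median"):
        for w in windows:
            rowwise(f"smooth_{m}_w{w}", lambda X, m=m, w=w: smooth(X, m, w),
                    method=m, window=w)
    for d, p in sg_configs:
        for w in windows:
            if w > p:
                rowwise(f"sg_d{d}p{p}_w{w}",
                        lambda X, d=d, p=p, w=w: sg_derivative(X, d, p, w),
                        deriv=d, poly=p, window=w)
    for mode in ("area", "mean"):
        rowwise(f"normalize_{mode}", lambda X, mode=mode: normalize(X, mode),
                mode=mode)
    for mode in ("offset", "linear"):
        rowwise(f"baseline_{mode}",
                lambda X, mode=mode: baseline_correct(X, mode), mode=mode)
    rowwise("snv", snv)
    factories.append(lambda: ScatterCorrection(poly_order=0))
    factories.append(lambda: ScatterCorrection(poly_order=2))
    factories.append(lambda: OrthogonalSignalCorrection(1))
    return factories


def compare_preprocessing(cal: SpectraSet, y: np.ndarray, max_lv: int = 10,
                          factories: Sequence[Callable[[], Preprocessor]] | None = None,
                          include_raw: bool = True):
    """Leave-one-out RMSECV of a PLSR model under each pre-treatment.

    Stateful treatments are refitted inside every cross-validation fold so
    held-out samples never inform the fitted state.  Returns a DataFrame
    (name, best_n_lv, rmsecv, r2_cv) sorted by RMSECV.
    """
    import pandas as pd

    from .models import full_cross_validation_pipeline

    if factories is None:
        factories = preprocessing_catalogue()
    rows = []
    if include_raw:
        factories = [lambda: Preprocessor()] + list(factories)
    for factory in factories:
        proto = factory()
        curve = full_cross_validation_pipeline(factory, cal, y, max_lv)
        k = int(np.argmin(curve.rmsecv)) + 1
        rows.append({"name": proto.name, "best_n_lv": k,
                     "rmsecv": curve.rmsecv[k - 1], "r2_cv": curve.r2_cv[k - 1]})
    return pd.DataFrame(rows).sort_values("rmsecv").reset_index(drop=True)
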
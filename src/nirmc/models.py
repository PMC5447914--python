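"""Calibration models: NIPALS PLSR and full-rank MLR.

PLS1 (univariate y) via the classical NIPALS deflation: weights are the
covariance direction Xc'yc, scores t = Xc w, loadings p = Xc't/t't, and X
is deflated by t p' after every latent variable.  The regression vector on
the centered scale is b = W (P'W)^-1 q, so prediction is an affine map
(X - x_mean) b + y_mean.  Only mean centering is applied — no variable
scaling — so raw and "weighted" regression coefficients coincide.

"Full cross validation" means leave-one-out: each held-out sample is
predicted by a model refitted (including re-centering) on the remaining
rows.  For MLR, calibration error is estimated by leverage correction,
sqrt(mean((e_i/(1-h_i))^2)), which for OLS equals exact leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import (
    ArgumentError,
    CollinearityError,
    InsufficientDataError,
    LeverageError,
    RankError,
)

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 1000


@dataclass
class PlsModel:
    """Fitted PLS1 model (mean-centered, unscaled)."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # W, p x k
    x_loadings: np.ndarray  # P, p x k
    y_loadings: np.ndarray  # q, k
    scores: np.ndarray     # T, n x k (training scores)
    b: np.ndarray          # regression vector on the centered scale
    n_lv: int
    fitted: np.ndarray     # training-set predictions
    wavelengths: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ArgumentError(
                f"model expects {self.x_mean.size} columns, got {X.shape[1]}")
        return (X - self.x_mean) @ self.b + self.y_mean


@dataclass
class MlrModel:
    """Ordinary least squares with intercept on a small predictor set."""

    intercept: float
    coefficients: np.ndarray
    wavelengths: np.ndarray | None
    fitted: np.ndarray
    leverages: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coefficients.size:
            raise ArgumentError(
                f"model expects {self.coefficients.size} columns, "
                f"got {X.shape[1]}")
        return self.intercept + X @ self.coefficients


@dataclass
class CvCurve:
    """Leave-one-out error per latent-variable count (1..max_lv)."""

    rmsecv: np.ndarray
    r2_cv: np.ndarray
    n: int

    def __post_init__(self):
        self.rmsecv = np.asarray(self.rmsecv, dtype=float)
        self.r2_cv = np.asarray(self.r2_cv, dtype=float)
        if self.rmsecv.size == 0:
            raise ArgumentError("empty cross-validation curve")


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int,
             wavelengths: np.ndarray | None = None) -> PlsModel:
    """NIPALS PLS1 on mean-centered X and y with ``n_lv`` latent variables."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ArgumentError("X rows and y length differ")
    if n_lv < 1:
        raise ArgumentError("n_lv must be >= 1")
    if n < n_lv + 2:
        raise InsufficientDataError(
            f"{n} samples cannot support {n_lv} latent variables")
    if np.std(y) < 1e-300:
        raise ArgumentError("y has zero variance (degenerate target)")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    T = np.empty((n, n_lv))
    nw0 = None
    for k in range(n_lv):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw0 is None:
            nw0 = max(nw, 1e-300)
        if nw <= 1e-12 * nw0:
            raise RankError(
                f"X rank exhausted after {k} latent variables (asked {n_lv})")
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            raise RankError(
                f"X rank exhausted after {k} latent variables (asked {n_lv})")
        pk = Xc.T @ t / tt
        q[k] = float(yc @ t) / tt
        Xc -= np.outer(t, pk)
        W[:, k], P[:, k], T[:, k] = w, pk, t
    b = W @ np.linalg.solve(P.T @ W, q)
    fitted = (X - x_mean) @ b + y_mean
    return PlsModel(x_mean, y_mean, W, P, q, T, b, n_lv, fitted,
                    None if wavelengths is None else np.asarray(wavelengths, float))


def predict(model: PlsModel | MlrModel, X: np.ndarray) -> np.ndarray:
    """Predict % MC from spectra with a fitted PLS or MLR model."""
    return model.predict(X)


def full_cross_validation(X: np.ndarray, y: np.ndarray, max_lv: int) -> CvCurve:
    """Leave-one-out RMSECV and R2cv for 1..max_lv latent variables."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n - 1 < max_lv + 2:
        raise RankError(f"max_lv {max_lv} too large for {n} samples")
    preds = np.empty((n, max_lv))
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_plsr(X[keep], y[keep], max_lv)
        # NIPALS components are nested, so one max_lv fit yields the
        # held-out prediction at every truncated LV count

        xc = X[i] - model.x_mean
        t = np.empty(max_lv)
        for k in range(max_lv):
            t[k] = xc @ model.weights[:, k]
            xc = xc - t[k] * model.x_loadings[:, k]
        cum = np.cumsum(t * model.y_loadings)
        preds[i] = model.y_mean + cum
    err = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(err ** 2, axis=0))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - np.sum(err ** 2, axis=0) / sst
    return CvCurve(rmsecv, r2, n)


def full_cross_validation_pipeline(preproc_factory: Callable, cal, y,
                                   max_lv: int) -> CvCurve:
    """Leave-one-out curve with the preprocessor refitted inside each fold.

    ``preproc_factory`` builds a fresh (unfitted) transformer; ``cal`` is a
    SpectraSet.  Stateful treatments therefore never see the held-out row.
    """
    X = cal.X
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n - 1 < max_lv + 2:
        raise RankError(f"max_lv {max_lv} too large for {n} samples")
    preds = np.empty((n, max_lv))
    for i in range(n):
        keep = np.arange(n) != i
        proc = preproc_factory()
        Zt = proc.fit_transform(X[keep], y[keep], cal.grid)
        Zi = proc.transform(X[i:i + 1])
        model = fit_plsr(Zt, y[keep], max_lv)
        xc = Zi[0] - model.x_mean
        t = np.empty(max_lv)
        for k in range(max_lv):
            t[k] = xc @ model.weights[:, k]
            xc = xc - t[k] * model.x_loadings[:, k]
        preds[i] = model.y_mean + np.cumsum(t * model.y_loadings)
    err = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(err ** 2, axis=0))
    sst = float(np.sum((y - y.mean()) ** 2))
    return CvCurve(rmsecv, 1.0 - np.sum(err ** 2, axis=0) / sst, n)


def choose_n_lv(curve: CvCurve, tolerance: float = 0.05) -> int:
    """Most parsimonious LV count: smallest L with
    RMSECV(L) <= (1 + tolerance) * min RMSECV."""
    if tolerance < 0:
        raise ArgumentError("tolerance must be >= 0")
    best = curve.rmsecv.min()
    ok = np.flatnonzero(curve.rmsecv <= (1.0 + tolerance) * best)
    return int(ok[0]) + 1


def fit_mlr(X: np.ndarray, y: np.ndarray,
            wavelengths: np.ndarray | None = None) -> MlrModel:
    """OLS with intercept; refuses rank-deficient designs, naming the
    dependent columns."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ArgumentError("X rows and y length differ")
    if n < p + 1:
        raise InsufficientDataError(
            f"need more than {p} samples for {p} predictors plus intercept")
    A = np.column_stack([np.ones(n), X])
    # column-scaled rank check so units do not mask collinearity
    scale = np.linalg.norm(A, axis=0)
    scale[scale == 0] = 1.0
    Q, R = np.linalg.qr(A / scale)
    diag = np.abs(np.diag(R))
    bad = np.flatnonzero(diag < 1e-10 * diag.max())
    if bad.size:
        cols = [int(j) - 1 for j in bad]  # -1: report predictor index
        raise CollinearityError(
            f"rank-deficient design; dependent predictor columns {cols}", cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    # hat diagonal via the thin QR of the unscaled design
    Qu, _ = np.linalg.qr(A)
    leverages = np.sum(Qu * Qu, axis=1)
    return MlrModel(float(coef[0]), coef[1:],
                    None if wavelengths is None else np.asarray(wavelengths, float),
                    fitted, leverages)


def leverage_corrected_rmse(model: MlrModel, X: np.ndarray,
                            y: np.ndarray) -> float:
    """sqrt(mean((e_i/(1-h_i))^2)) over the calibration set — exact
    leave-one-out error for OLS."""
    y = np.asarray(y, dtype=float).ravel()
    e = y - model.predict(X)
    h = model.leverages
    if np.any(h >= 1.0 - 1e-12):
        raise LeverageError("a leverage is numerically 1; correction undefined")
    return float(np.sqrt(np.mean((e / (1.0 - h)) ** 2)))


def rmse(y_ref: np.ndarray, y_hat: np.ndarray) -> float:
    y_ref = np.asarray(y_ref, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    return float(np.sqrt(np.mean((y_hat - y_ref) ** 2)))


def r_squared(y_ref: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - SSE/SST (not squared Pearson)."""
    y_ref = np.asarray(y_ref, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    sst = float(np.sum((y_ref - y_ref.mean()) ** 2))
    return 1.0 - float(np.sum((y_hat - y_ref) ** 2)) / sst
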
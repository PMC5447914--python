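"""PCA-based spectral outlier screening with Hotelling's T².

Screening follows standard chemometric practice: a mean-centered PCA on
the raw spectra (2 components by default), the T² statistic of each
sample's scores scaled by the component variances, and the F-based 5%
critical contour

    T2_crit = p (n - 1) / (n - p) * F_{1-alpha}(p, n - p).

Flagged samples are not dropped automatically: :func:`keep_or_drop`
refits the calibration model with and without them and recommends keeping
unless cross-validation error improves by more than a configured relative
threshold — high-leverage spectra are often legitimate extremes of the
calibrated range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ArgumentError, DegenerateFitError, InsufficientDataError
from .models import full_cross_validation
from .spectra import SpectraSet


@dataclass
class PcaModel:
    """Mean-centered PCA of a spectra matrix."""

    mean: np.ndarray
    loadings: np.ndarray          # p x k, orthonormal columns
    eigenvalues: np.ndarray       # score variances (n-1 denominator)
    explained_fraction: np.ndarray
    scores: np.ndarray            # n x k
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(data: SpectraSet | np.ndarray, n_pc: int) -> PcaModel:
    """Mean-centered PCA via SVD, keeping ``n_pc`` components."""
    if isinstance(data, SpectraSet):
        X = data.X
        ids = data.meta["sample_id"].tolist()
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        ids = [str(i) for i in range(X.shape[0])]
    n, p = X.shape
    if n < 2:
        raise ArgumentError("PCA needs at least 2 rows")
    if not (1 <= n_pc <= min(n - 1, p)):
        raise ArgumentError(
            f"n_pc must be in [1, {min(n - 1, p)}], got {n_pc}")
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    eig_all = s ** 2 / (n - 1)
    total = eig_all.sum()
    frac = eig_all[:n_pc] / total if total > 0 else np.zeros(n_pc)
    scores = U[:, :n_pc] * s[:n_pc]
    return PcaModel(mean, Vt[:n_pc].T, eig_all[:n_pc], frac, scores, ids)


def hotelling_limit(n: int, n_pc: int, alpha: float = 0.05) -> float:
    """F-based critical T² value for the (1 - alpha) ellipse."""
    if not 0 < alpha < 1:
        raise ArgumentError(f"alpha must be in (0, 1), got {alpha}")
    if n <= n_pc or n_pc < 1:
        raise ArgumentError(f"need n > n_pc >= 1, got n={n}, n_pc={n_pc}")
    p = n_pc
    return p * (n - 1) / (n - p) * stats.f.ppf(1 - alpha, p, n - p)


def hotelling_t2(scores: np.ndarray, eigenvalues: np.ndarray | None = None,
                 cov: np.ndarray | None = None) -> np.ndarray:
    """T² per row: scores' Sigma^-1 scores (diagonal Sigma by default)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if cov is not None:
        sol = np.linalg.solve(cov, scores.T)
        return np.einsum("ij,ji->i", scores, sol)
    if eigenvalues is None:
        raise ArgumentError("need eigenvalues or a covariance matrix")
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if np.any(eigenvalues <= 1e-300):
        raise DegenerateFitError("zero eigenvalue among retained components")
    return np.sum(scores ** 2 / eigenvalues, axis=1)


def flag_outliers(model: PcaModel, alpha: float = 0.05) -> pd.DataFrame:
    """T² per sample against the critical limit, sorted by descending T².

    Returns a DataFrame (sample_id, t2, threshold, flagged).
    """
    n = model.scores.shape[0]
    t2 = hotelling_t2(model.scores, model.eigenvalues)
    limit = hotelling_limit(n, model.n_components, alpha)
    out = pd.DataFrame({"sample_id": model.sample_ids, "t2": t2,
                        "threshold": limit, "flagged": t2 > limit})
    return out.sort_values("t2", ascending=False).reset_index(drop=True)


@dataclass
class KeepDropDecision:
    """Outcome of refitting with and without suspected outliers."""

    flagged: list[str]
    rmsecv_with: float
    rmsecv_without: float
    r2_cv_with: float
    r2_cv_without: float
    delta_rmsecv_rel: float  # (with - without)/with; > 0 means dropping helps
    recommendation: str      # "keep" or "drop"
    threshold: float


def keep_or_drop(cal: SpectraSet, y: np.ndarray, flagged: list[str],
                 n_lv: int = 3, rel_threshold: float = 0.10) -> KeepDropDecision:
    """Fit the PLSR calibration with and without flagged samples and
    recommend keeping them unless leave-one-out RMSECV improves by more
    than ``rel_threshold`` (relative) on removal."""
    y = np.asarray(y, dtype=float).ravel()
    ids = cal.meta["sample_id"]
    unknown = set(flagged) - set(ids)
    if unknown:
        raise ArgumentError(f"flagged ids not in set: {sorted(unknown)}")
    curve_with = full_cross_validation(cal.X, y, n_lv)
    keep_mask = ~ids.isin(flagged).to_numpy()
    n_left = int(keep_mask.sum())
    if n_left < n_lv + 3:
        raise InsufficientDataError(
            f"dropping {len(flagged)} samples leaves {n_left} rows, "
            f"too few for {n_lv} latent variables")
    curve_wo = full_cross_validation(cal.X[keep_mask], y[keep_mask], n_lv)
    rw, rwo = curve_with.rmsecv[-1], curve_wo.rmsecv[-1]
    delta = (rw - rwo) / rw if rw > 0 else 0.0
    rec = "drop" if delta > rel_threshold else "keep"
    if not flagged:
        rec = "keep"
    return KeepDropDecision(list(flagged), rw, rwo, curve_with.r2_cv[-1],
                            curve_wo.r2_cv[-1], delta, rec, rel_threshold)


def outlier_report(flags: pd.DataFrame, decision: KeepDropDecision | None = None
                   ) -> pd.DataFrame:
    """Outlier report CSV shape: sample_id, T², threshold, flagged,
    recommendation."""
    out = flags.copy()
    out["recommendation"] = decision.recommendation if decision else ""
    return out
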
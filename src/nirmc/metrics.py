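"""Validation statistics and model comparison.

For validation residuals e = y_hat - y_ref:

    bias  = mean(e)
    RMSEP = sqrt(mean(e^2))
    SEP   = sqrt(sum((e - bias)^2) / (n - 1))   (bias-corrected spread)
    R2    = 1 - SSE/SST                          (not squared Pearson)
    RPD   = SD(y_ref, n-1) / SEP

These satisfy the algebraic identity RMSEP^2 = bias^2 + SEP^2 (n-1)/n.
A perfect prediction has SEP 0 and RPD reported as +inf (rendered as the
string "inf" in tables, never silently dropped).

Prediction errors of two models on the same validation samples are
compared with a two-sided paired t-test on the squared residual
differences d_i = e_a,i^2 - e_b,i^2 (a sign-flip randomization test is
available as a distribution-free alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ArgumentError


@dataclass
class ValidationReport:
    """Table-shaped statistics for one model configuration."""

    n: int
    r2_pred: float
    rmsep: float
    sep: float
    bias: float
    rpd: float
    n_lv: int | None = None
    r2_cal: float | None = None
    r2_cv: float | None = None
    rmsec: float | None = None
    rmsecv: float | None = None
    extras: dict = field(default_factory=dict)


def evaluate_predictions(y_ref: np.ndarray, y_hat: np.ndarray,
                         n_lv: int | None = None) -> ValidationReport:
    """Prediction statistics for one model on a validation set."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_ref.shape != y_hat.shape:
        raise ArgumentError(
            f"length mismatch: {y_ref.size} reference vs {y_hat.size} predicted")
    n = y_ref.size
    if n < 3:
        raise ArgumentError("need at least 3 validation samples")
    sd_ref = float(np.std(y_ref, ddof=1))
    if sd_ref <= 0:
        raise ArgumentError("reference values have zero variance")
    e = y_hat - y_ref
    bias = float(np.mean(e))
    rmsep = float(np.sqrt(np.mean(e ** 2)))
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    sst = float(np.sum((y_ref - y_ref.mean()) ** 2))
    r2 = 1.0 - float(np.sum(e ** 2)) / sst
    rpd = sd_ref / sep if sep > 0 else math.inf
    return ValidationReport(n, r2, rmsep, sep, bias, rpd, n_lv=n_lv)


def compare_prediction_errors(e_a: np.ndarray, e_b: np.ndarray,
                              method: str = "paired_t_squared",
                              n_resamples: int = 10_000,
                              seed: int | None = 0) -> float:
    """Two-sided p-value for a difference in squared prediction errors.

    ``paired_t_squared`` is a paired t-test on d_i = e_a,i^2 - e_b,i^2;
    ``randomization`` is a seeded sign-flip permutation of the d_i using
    |mean(d)| as the statistic.  Symmetric in its arguments.
    """
    e_a = np.asarray(e_a, dtype=float).ravel()
    e_b = np.asarray(e_b, dtype=float).ravel()
    if e_a.shape != e_b.shape:
        raise ArgumentError("residual vectors must pair the same samples")
    if e_a.size < 3:
        raise ArgumentError("need at least 3 paired residuals")
    d = e_a ** 2 - e_b ** 2
    if method == "paired_t_squared":
        if np.allclose(d, 0.0):
            return 1.0
        if np.std(d, ddof=1) == 0.0:
            return 0.0  # constant nonzero difference: t is infinite
        return float(stats.ttest_1samp(d, 0.0).pvalue)
    if method == "randomization":
        if n_resamples < 1:
            raise ArgumentError("n_resamples must be >= 1")
        rng = np.random.default_rng(seed)
        obs = abs(d.mean())
        signs = rng.choice((-1.0, 1.0), size=(n_resamples, d.size))
        perm = np.abs((signs * d).mean(axis=1))
        # +1 correction keeps the p-value valid and never exactly zero
        return float((1 + np.sum(perm >= obs - 1e-15)) / (1 + n_resamples))
    raise ArgumentError(f"unknown method {method!r}")


_ROW_ORDER = ["LVs", "R2 calibration", "R2 cross validation", "RMSEC (% MC)",
              "RMSECV (% MC)", "R2 prediction", "RMSEP (% MC)", "Bias (% MC)",
              "RPD"]


def report_table(entries: list[tuple[str, ValidationReport]]) -> pd.DataFrame:
    """Model-comparison table: statistics as rows, configurations as
    columns; R2 rounded to 4 decimals, errors to 2, infinite RPD as the
    string "inf"."""
    if not entries:
        raise ArgumentError("no entries to report")

    def fmt_r2(v):
        return "n/a" if v is None else f"{v:.4f}"

    def fmt_err(v):
        return "n/a" if v is None else f"{v:.2f}"

    def fmt_rpd(v):
        return "inf" if math.isinf(v) else f"{v:.2f}"

    cols = {}
    for name, r in entries:
        cols[name] = ["n/a" if r.n_lv is None else str(r.n_lv),
                      fmt_r2(r.r2_cal), fmt_r2(r.r2_cv), fmt_err(r.rmsec),
                      fmt_err(r.rmsecv), fmt_r2(r.r2_pred), fmt_err(r.rmsep),
                      fmt_err(r.bias), fmt_rpd(r.rpd)]
    return pd.DataFrame(cols, index=_ROW_ORDER)


def report_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`report_table` output."""
    return table.to_string()
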
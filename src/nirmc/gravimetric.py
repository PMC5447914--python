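"""Gravimetric reference moisture (ISO 6673 style).

Moisture content on a wet basis is the relative mass loss on oven drying,

    MC = (Ww - Wd) / Ww,

with Ww the wet and Wd the dried sample weight.  The reference method runs
duplicate determinations per sample; models are calibrated against the
duplicate mean.  The duplicate spread (SD with n-1 denominator) quantifies
the reference method's own error and is the floor any spectroscopic model
can sensibly reach.

The 8.0-12.5 % MC trade "safety range" is exposed as a classifier; both
boundaries count as in range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, NirmcError

SAFETY_RANGE = (8.0, 12.5)  # % MC, closed interval


@dataclass(frozen=True)
class MoistureRecord:
    """One duplicate weighing: wet and dried weight in grams."""

    sample_id: str
    ww: float
    wd: float
    duplicate: int = 1

    def __post_init__(self):
        if self.ww <= 0:
            raise ArgumentError(f"wet weight must be positive, got {self.ww}")
        if self.wd < 0:
            raise ArgumentError(f"dry weight must be non-negative, got {self.wd}")
        if self.wd > self.ww:
            raise NirmcError(
                f"negative moisture: dry weight {self.wd} g exceeds "
                f"wet weight {self.ww} g for sample {self.sample_id!r}")
        if self.duplicate < 1:
            raise ArgumentError("duplicate index must be a positive integer")

    @property
    def mc_percent(self) -> float:
        return 100.0 * mc_wet_basis(self.ww, self.wd)


def mc_wet_basis(ww: float, wd: float) -> float:
    """Wet-basis moisture fraction (Ww - Wd)/Ww, in [0, 1)."""
    if ww <= 0:
        raise ArgumentError(f"wet weight must be positive, got {ww}")
    if wd > ww:
        raise NirmcError(
            f"negative moisture: dry weight {wd} exceeds wet weight {ww}")
    if wd < 0:
        raise ArgumentError(f"dry weight must be non-negative, got {wd}")
    return (ww - wd) / ww


@dataclass(frozen=True)
class DuplicateSummary:
    """Per-sample duplicate means plus spread summaries across samples."""

    per_sample: pd.DataFrame  # sample_id, n_duplicates, mc_percent, sd_percent
    mean_sd: float  # average of per-sample SDs (samples with >=2 duplicates)
    median_sd: float


def summarize_duplicates(records: list[MoistureRecord]) -> DuplicateSummary:
    """Collapse duplicate MC determinations to per-sample means.

    SDs use the n-1 denominator and are defined only for samples with at
    least two duplicates; ``mean_sd``/``median_sd`` summarise those SDs
    across samples (NaN if no sample has duplicates).
    """
    if not records:
        raise ArgumentError("no moisture records given")
    df = pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "mc": [r.mc_percent for r in records],
    })
    g = df.groupby("sample_id", sort=False)["mc"]
    per = pd.DataFrame({
        "sample_id": list(g.groups),
        "n_duplicates": g.count().to_numpy(),
        "mc_percent": g.mean().to_numpy(),
        "sd_percent": g.std(ddof=1).to_numpy(),
    })
    sds = per.loc[per["n_duplicates"] >= 2, "sd_percent"]
    mean_sd = float(sds.mean()) if len(sds) else float("nan")
    median_sd = float(sds.median()) if len(sds) else float("nan")
    return DuplicateSummary(per, mean_sd, median_sd)


def classify_safety(mc_percent: float) -> str:
    """Classify % MC against the 8.0-12.5 % trade safety range."""
    if mc_percent < 0:
        raise ArgumentError(f"moisture cannot be negative, got {mc_percent}")
    lo, hi = SAFETY_RANGE
    if mc_percent < lo:
        return "below"
    if mc_percent > hi:
        return "above"
    return "in_range"


# -- I/O ------------------------------------------------------------------

def read_weighing_records(path: str | Path) -> list[MoistureRecord]:
    """Read ``sample_id,duplicate,ww_g,wd_g`` CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    needed = {"sample_id", "duplicate", "ww_g", "wd_g"}
    if not needed.issubset(df.columns):
        raise ArgumentError(f"weighing CSV must have columns {sorted(needed)}")
    return [MoistureRecord(r.sample_id, float(r.ww_g), float(r.wd_g),
                           int(r.duplicate)) for r in df.itertuples()]


def write_weighing_records(records: list[MoistureRecord], path: str | Path) -> None:
    pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "duplicate": [r.duplicate for r in records],
        "ww_g": [repr(r.ww) for r in records],
        "wd_g": [repr(r.wd) for r in records],
    }).to_csv(path, index=False)


def moisture_report(summary: DuplicateSummary) -> pd.DataFrame:
    """Per-sample MC with safety-range flags, ready to write as CSV."""
    out = summary.per_sample.copy()
    out["safety"] = [classify_safety(v) for v in out["mc_percent"]]
    return out
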
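"""Spectra data model and I/O.

A :class:`SpectraSet` is the package's central container: a matrix of
log(1/R) apparent-absorbance spectra on a shared :class:`WavelengthGrid`,
with per-row sample metadata (sample id, species, origin, replicate index
and calibration/validation role) and an optional vector of gravimetric
reference moisture values (% wet basis).

The canonical on-disk form is a wide CSV whose header is
``sample_id,species,origin,replicate,role,mc`` followed by one column per
wavelength (nm, '.' decimal separator, UTF-8).  Floats are written with
Python's shortest round-tripping repr so write→read is value-identical.
A minimal JCAMP-DX-like reader for single spectra is also provided.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ArgumentError,
    ConsistencyError,
    CoverageError,
    FormatError,
    GridError,
    LookupError_,
)

SPECIES = ("Arabica", "Robusta")
ROLES = ("calibration", "validation", "unassigned")
META_COLUMNS = ["sample_id", "species", "origin", "replicate", "role"]

#: Default instrument emulation: 1557 points covering 1000-2500 nm, sampled
#: uniformly in wavenumber (10000 -> 4000 cm^-1) as an FT instrument does.
DEFAULT_N_POINTS = 1557
DEFAULT_WN_RANGE = (10_000.0, 4_000.0)  # cm^-1, high -> low so nm increases


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm shared by a set of spectra."""

    values: np.ndarray
    _allow_unsorted: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        min_len = 1 if self._allow_unsorted else 2  # subsets may be single
        if vals.ndim != 1 or vals.size < min_len:
            raise GridError("wavelength grid needs at least 2 points")
        if not np.all(np.isfinite(vals)):
            raise GridError("wavelength grid contains non-finite values")
        if not self._allow_unsorted and np.any(np.diff(vals) <= 0):
            raise GridError("wavelengths must be strictly increasing")

    def __len__(self):
        return self.values.size

    @classmethod
    def default(cls, n_points: int = DEFAULT_N_POINTS,
                wn_range: tuple[float, float] = DEFAULT_WN_RANGE) -> "WavelengthGrid":
        """Grid uniform in wavenumber, converted to nm (1000-2500 nm default)."""
        wn = np.linspace(wn_range[0], wn_range[1], n_points)
        return cls(1e7 / wn)

    def scaled(self) -> np.ndarray:
        """Wavelengths affinely mapped to [-1, 1] (EMSC/polynomial basis)."""
        lo, hi = self.values.min(), self.values.max()
        return 2.0 * (self.values - lo) / (hi - lo) - 1.0

    def nearest(self, target: float, tolerance: float) -> int:
        """Index of the grid point nearest ``target`` within ``tolerance``.

        Ties are broken toward the lower wavelength.
        """
        dist = np.abs(self.values - target)
        i = int(np.argmin(dist))  # argmin returns the first (lower-nm) minimum
        if dist[i] > tolerance:
            raise LookupError_(
                f"no grid point within {tolerance} nm of target {target} nm")
        return i


@dataclass(frozen=True)
class Spectrum:
    """A single log(1/R) spectrum with its metadata."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_id: str = ""
    species: str = "Arabica"
    origin: str = ""
    replicate: int = 1

    def __post_init__(self):
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", ab)
        if ab.shape != (len(self.grid),):
            raise ArgumentError("absorbance length must equal grid length")
        if not np.all(np.isfinite(ab)):
            raise ArgumentError("absorbance contains non-finite values")
        if self.species not in SPECIES:
            raise ArgumentError(f"unknown species {self.species!r}")
        if self.replicate < 1:
            raise ArgumentError("replicate index must be a positive integer")


class SpectraSet:
    """Matrix of spectra plus row metadata and optional reference MC.

    Parameters
    ----------
    grid:
        Shared wavelength grid.
    X:
        2-D array, one row per sample-replicate, columns matching ``grid``.
    meta:
        DataFrame with columns ``sample_id, species, origin, replicate, role``.
    reference_mc:
        Optional per-row gravimetric moisture, % wet basis (NaN allowed).
    """

    def __init__(self, grid: WavelengthGrid, X: np.ndarray,
                 meta: pd.DataFrame, reference_mc: np.ndarray | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(grid):
            raise ArgumentError(
                f"matrix has {X.shape[1]} columns but grid has {len(grid)} points")
        meta = meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ArgumentError(f"metadata missing columns {missing}")
        if len(meta) != X.shape[0]:
            raise ArgumentError("metadata row count does not match matrix")
        bad_roles = set(meta["role"]) - set(ROLES)
        if bad_roles:
            raise ArgumentError(f"unknown roles {sorted(bad_roles)}")
        bad_species = set(meta["species"]) - set(SPECIES)
        if bad_species:
            raise ArgumentError(f"unknown species {sorted(bad_species)}")
        if reference_mc is not None:
            reference_mc = np.asarray(reference_mc, dtype=float)
            if reference_mc.shape != (X.shape[0],):
                raise ArgumentError("reference_mc length does not match matrix")
        self.grid = grid
        self.X = X
        self.meta = meta[META_COLUMNS].copy()
        self.meta["replicate"] = self.meta["replicate"].astype(int)
        self.reference_mc = reference_mc

    # -- basic protocol ----------------------------------------------------
    def __len__(self):
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "SpectraSet":
        mc = None if self.reference_mc is None else self.reference_mc.copy()
        return SpectraSet(self.grid, self.X.copy(), self.meta.copy(), mc)

    def with_matrix(self, X: np.ndarray, grid: WavelengthGrid | None = None) -> "SpectraSet":
        """Same metadata, different absorbance matrix (and optionally grid)."""
        mc = None if self.reference_mc is None else self.reference_mc.copy()
        return SpectraSet(grid or self.grid, X, self.meta.copy(), mc)

    def take(self, rows: Sequence[int] | np.ndarray) -> "SpectraSet":
        rows = np.asarray(rows, dtype=int)
        mc = None if self.reference_mc is None else self.reference_mc[rows]
        return SpectraSet(self.grid, self.X[rows], self.meta.iloc[rows], mc)

    def row(self, i: int) -> Spectrum:
        m = self.meta.iloc[i]
        return Spectrum(self.grid, self.X[i], m.sample_id, m.species,
                        m.origin, int(m.replicate))

    def values_equal(self, other: "SpectraSet") -> bool:
        same_mc = (self.reference_mc is None) == (other.reference_mc is None)
        if same_mc and self.reference_mc is not None:
            same_mc = np.array_equal(self.reference_mc, other.reference_mc,
                                     equal_nan=True)
        return (np.array_equal(self.grid.values, other.grid.values)
                and np.array_equal(self.X, other.X)
                and self.meta.equals(other.meta)
                and same_mc)


# -- operations -----------------------------------------------------------

def average_replicates(s: SpectraSet) -> SpectraSet:
    """Average replicate spectra to one row per sample_id.

    Species, origin and role must be constant within a sample; the
    reference MC is averaged (it is normally constant across replicates).
    Sample order follows first appearance.
    """
    ids = s.meta["sample_id"]
    order = ids.drop_duplicates().tolist()
    rows, meta_rows, mcs = [], [], []
    for sid in order:
        mask = (ids == sid).to_numpy()
        sub = s.meta[mask]
        for col in ("species", "origin", "role"):
            if sub[col].nunique() > 1:
                raise ConsistencyError(
                    f"sample {sid!r} has conflicting {col} values "
                    f"{sorted(sub[col].unique())}")
        rows.append(s.X[mask].mean(axis=0))
        meta_rows.append({"sample_id": sid, "species": sub["species"].iat[0],
                          "origin": sub["origin"].iat[0], "replicate": 1,
                          "role": sub["role"].iat[0]})
        if s.reference_mc is not None:
            mcs.append(float(np.mean(s.reference_mc[mask])))
    mc = np.array(mcs) if s.reference_mc is not None else None
    return SpectraSet(s.grid, np.array(rows), pd.DataFrame(meta_rows), mc)


def split_by_origin(s: SpectraSet, cal_origins: Iterable[str],
                    val_origins: Iterable[str]) -> tuple[SpectraSet, SpectraSet]:
    """Assign calibration/validation roles by origin and split.

    The two lists must be disjoint and jointly cover every origin present.
    """
    cal, val = list(cal_origins), list(val_origins)
    overlap = set(cal) & set(val)
    if overlap:
        raise ArgumentError(
            f"origin lists overlap: {sorted(overlap)}")
    present = set(s.meta["origin"])
    uncovered = present - set(cal) - set(val)
    if uncovered:
        raise CoverageError(
            f"origins in set but in neither list: {sorted(uncovered)}")
    role = np.where(s.meta["origin"].isin(cal), "calibration", "validation")
    out = s.copy()
    out.meta["role"] = role
    cal_set = out.take(np.flatnonzero(role == "calibration"))
    val_set = out.take(np.flatnonzero(role == "validation"))
    return cal_set, val_set


def subset_wavelengths(s: SpectraSet, targets: Sequence[float],
                       tolerance: float = 2.0) -> SpectraSet:
    """Extract the nearest grid column for each target wavelength (no
    interpolation); the output grid holds the matched points in target order.
    """
    if len(targets) == 0:
        raise ArgumentError("empty wavelength target list")
    idx = [s.grid.nearest(t, tolerance) for t in targets]
    new_grid = WavelengthGrid(s.grid.values[idx], _allow_unsorted=True)
    return s.with_matrix(s.X[:, idx], grid=new_grid)


# -- I/O ------------------------------------------------------------------

def _format_float(x: float) -> str:
    return repr(float(x))


def write_spectra(s: SpectraSet, path: str | Path) -> None:
    """Write the canonical wide CSV dialect (value-exact round trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        header = META_COLUMNS + ["mc"] + [_format_float(v) for v in s.grid.values]
        w.writerow(header)
        for i in range(len(s)):
            m = s.meta.iloc[i]
            mc = ""
            if s.reference_mc is not None and np.isfinite(s.reference_mc[i]):
                mc = _format_float(s.reference_mc[i])
            w.writerow([m.sample_id, m.species, m.origin, int(m.replicate),
                        m.role, mc] + [_format_float(v) for v in s.X[i]])


def read_spectra(path: str | Path, dialect: str = "wide_csv") -> SpectraSet:
    """Read spectra from disk.

    ``wide_csv`` is the canonical dialect (see module docstring);
    ``jcampdx_like`` reads a single spectrum from a minimal JCAMP-DX-style
    file (``##XUNITS=NANOMETERS`` and an XYDATA block of x,y pairs).
    """
    path = Path(path)
    if dialect == "wide_csv":
        return _read_wide_csv(path)
    if dialect == "jcampdx_like":
        return _read_jcamp(path)
    raise ArgumentError(f"unknown dialect {dialect!r}")


def _read_wide_csv(path: Path) -> SpectraSet:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        n_meta = len(META_COLUMNS) + 1  # + mc column
        if len(header) < n_meta + 2 or header[:len(META_COLUMNS)] != META_COLUMNS \
                or header[len(META_COLUMNS)] != "mc":
            raise FormatError(
                f"{path}: header must start with {','.join(META_COLUMNS)},mc")
        try:
            grid_vals = np.array([float(v) for v in header[n_meta:]])
        except ValueError as e:
            raise FormatError(f"{path}: non-numeric wavelength in header: {e}") from None
        try:
            grid = WavelengthGrid(grid_vals)
        except GridError as e:
            raise GridError(f"{path}: {e}") from None
        rows, meta_rows, mcs = [], [], []
        any_mc = False
        for rownum, rec in enumerate(reader, start=2):
            if len(rec) != len(header):
                raise FormatError(
                    f"{path}: row {rownum} has {len(rec)} fields, "
                    f"expected {len(header)}")
            sid, species, origin, rep, role, mc_s = rec[:n_meta]
            try:
                vals = np.array([float(v) for v in rec[n_meta:]])
            except ValueError:
                raise FormatError(
                    f"{path}: row {rownum} has non-numeric absorbance") from None
            rows.append(vals)
            meta_rows.append({"sample_id": sid, "species": species,
                              "origin": origin, "replicate": int(rep),
                              "role": role})
            if mc_s == "":
                mcs.append(np.nan)
            else:
                mcs.append(float(mc_s))
                any_mc = True
        if not rows:
            raise FormatError(f"{path}: no data rows")
    mc = np.array(mcs) if any_mc else None
    return SpectraSet(grid, np.array(rows), pd.DataFrame(meta_rows), mc)


def _read_jcamp(path: Path) -> SpectraSet:
    """Minimal JCAMP-DX-like single-spectrum reader (XY pairs only)."""
    title, xunits = path.stem, None
    xs, ys = [], []
    in_data = False
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            val = val.strip()
            if key == "TITLE":
                title = val or title
            elif key == "XUNITS":
                xunits = val.upper()
            elif key == "XYDATA":
                in_data = True
            elif key == "END":
                in_data = False
            continue
        if in_data:
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) != 2:
                raise FormatError(f"{path}: expected 'x y' pairs, got {line!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError:
                raise FormatError(f"{path}: non-numeric XYDATA {line!r}") from None
    if xunits != "NANOMETERS":
        raise FormatError(f"{path}: ##XUNITS must be NANOMETERS, got {xunits}")
    if len(xs) < 2:
        raise FormatError(f"{path}: fewer than 2 data points")
    grid = WavelengthGrid(np.array(xs))
    meta = pd.DataFrame([{"sample_id": title, "species": "Arabica",
                          "origin": "", "replicate": 1, "role": "unassigned"}])
    return SpectraSet(grid, np.array([ys]), meta)
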
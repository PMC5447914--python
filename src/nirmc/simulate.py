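"""Synthetic NIR coffee-bean datasets.

The generator emulates the structure of the study data the pipeline is
designed for: 108 samples (64 calibration from 7 origins, 44 validation
from 5), two species forming distinct spectral clusters, wet-basis
moisture uniform on 6-22 %, three replicate spectra per sample, and
duplicate gravimetric reference determinations with a 0.21 % MC
within-sample SD.

Each sample's *chemistry spectrum* is a sum of Gaussian absorption bands
whose amplitudes are affine in moisture (water bands at 1450 and 1940 nm
carry most of the moisture signal) plus species offsets on constituent
bands near 1155, 1212, 1340, 1409, 1724 and 2249 nm.  Every replicate
then receives an independent multiplicative/additive scatter draw of
exactly the form EMSC models,

    x = a + b * chem + p1 * t + p2 * t^2,   t = wavelength scaled to [-1, 1],

plus iid spectral noise.  Gravimetric duplicates are realised as
consistent (wet weight, dry weight) pairs around 10 g.

A single global seed governs all draws through named sub-streams
(``default_rng([seed, stream])``), so any stage is independently
reproducible and identical (config, seed) pairs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, ConfigError
from .gravimetric import MoistureRecord
from .spectra import (
    DEFAULT_N_POINTS,
    DEFAULT_WN_RANGE,
    SpectraSet,
    WavelengthGrid,
)

# Stream ids for the documented seed-splitting scheme.
_STREAM_MC = 0
_STREAM_SCATTER = 1
_STREAM_NOISE = 2
_STREAM_GRAVIMETRIC = 3


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``amplitude`` is the base log(1/R) height at mid-range moisture
    (14 % MC); ``moisture_sensitivity`` is absorbance per % MC;
    ``species_offset`` is added for Arabica (Arabica minus Robusta).
    """

    center: float
    width: float
    amplitude: float
    moisture_sensitivity: float = 0.0
    species_offset: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ConfigError(f"band width must be positive, got {self.width}")


def default_bands() -> tuple[BandSpec, ...]:
    """Default band library: water bands (1450/1940 nm) carrying the
    moisture signal, constituent bands near the informative wavelengths
    with species contrasts, and one broad background hump."""
    return (
        # water
        BandSpec(1450.0, 45.0, 0.55, moisture_sensitivity=0.013),
        BandSpec(1940.0, 55.0, 0.85, moisture_sensitivity=0.020),
        # constituents (caffeine/chlorogenic acid/lipids/carbohydrates...)
        BandSpec(1155.0, 22.0, 0.12, 0.0015, species_offset=0.030),
        BandSpec(1212.0, 24.0, 0.18, -0.0012, species_offset=-0.040),
        BandSpec(1340.0, 28.0, 0.22, 0.0018, species_offset=0.035),
        BandSpec(1409.0, 22.0, 0.28, 0.0030, species_offset=0.020),
        BandSpec(1724.0, 26.0, 0.30, -0.0020, species_offset=0.060),
        BandSpec(2249.0, 30.0, 0.38, 0.0025, species_offset=-0.045),
        # broad diffuse background; the large species offset makes the
        # species contrast the dominant spectral variance component, as in
        # real Arabica/Robusta reflectance data
        BandSpec(1650.0, 420.0, 0.25, 0.0, species_offset=0.25),
    )


#: Study-structured origin lists: (label, species, n_samples).  Origin
#: names appearing in both purposes get a " (val)" suffix on the
#: validation side so the two label lists stay disjoint.
DEFAULT_CAL_ORIGINS = (
    ("West Nusa Tenggara", "Arabica", 10),
    ("South Sulawesi", "Arabica", 9),
    ("Aceh", "Arabica", 9),
    ("South Sumatera", "Robusta", 9),
    ("Bali", "Robusta", 9),
    ("East Java", "Robusta", 9),
    ("North Sumatera", "Robusta", 9),
)
DEFAULT_VAL_ORIGINS = (
    ("West Java", "Arabica", 9),
    ("North Sumatera (val)", "Arabica", 9),
    ("South Sumatera (val)", "Robusta", 9),
    ("East Java (val)", "Robusta", 9),
    ("Bengkulu", "Robusta", 8),
)


@dataclass
class SimConfig:
    """Every generator parameter; defaults reproduce the study structure."""

    n_grid: int = DEFAULT_N_POINTS
    wn_range: tuple[float, float] = DEFAULT_WN_RANGE
    cal_origins: tuple = DEFAULT_CAL_ORIGINS
    val_origins: tuple = DEFAULT_VAL_ORIGINS
    mc_range: tuple[float, float] = (6.0, 22.0)     # % wet basis
    bands: tuple[BandSpec, ...] = field(default_factory=default_bands)
    scatter_b_sd: float = 0.05     # multiplicative, mean 1
    scatter_a_sd: float = 0.02     # additive offset, absorbance
    scatter_poly_sd: float = 0.01  # per polynomial coefficient
    scatter_poly_order: int = 2
    noise_sd: float = 0.002        # iid spectral noise, absorbance
    n_replicates: int = 3
    #: expected within-sample SD of duplicate MC determinations, % MC.
    #: This is what a study reports; the generator divides the Gaussian
    #: noise scale by the c4(n) small-sample factor so the *observed*
    #: average duplicate SD reproduces this value (E[s] = c4 sigma).
    duplicate_sd: float = 0.21
    n_duplicates: int = 2
    ww_mean: float = 10.0          # g
    ww_sd: float = 0.1             # g
    nonwater_loss: float = 0.0     # extra % mass loss on drying (off)

    def validate(self) -> None:
        for name in ("scatter_b_sd", "scatter_a_sd", "scatter_poly_sd",
                     "noise_sd", "duplicate_sd", "ww_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mc_range[0] >= self.mc_range[1] or self.mc_range[0] < 0:
            raise ConfigError(f"invalid MC range {self.mc_range}")
        if self.n_replicates < 1 or self.n_duplicates < 1:
            raise ConfigError("need at least one replicate and duplicate")
        if self.scatter_poly_order < 0:
            raise ConfigError("scatter polynomial order must be >= 0")
        if not self.bands:
            raise ConfigError("band library is empty")
        species = {s for _, s, _ in self.cal_origins + self.val_origins}
        if not species <= {"Arabica", "Robusta"}:
            raise ConfigError(f"unknown species in origin map: {species}")
        labels = [o for o, _, _ in self.cal_origins + self.val_origins]
        if len(labels) != len(set(labels)):
            raise ConfigError("origin labels must be unique across purposes")

    @property
    def n_cal(self) -> int:
        return sum(n for _, _, n in self.cal_origins)

    @property
    def n_val(self) -> int:
        return sum(n for _, _, n in self.val_origins)

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.default(self.n_grid, self.wn_range)


def make_default_config() -> SimConfig:
    """The study-structured defaults: 64 + 44 = 108 samples, MC 6-22 %,
    3 replicates, duplicate SD 0.21 % MC."""
    return SimConfig()


def make_band_recovery_config() -> SimConfig:
    """Variant for wavelength-recovery studies: the moisture-informative
    bands sit exactly at the seven published wavelengths (water bands
    removed), so coefficient-based selection has a known ground truth."""
    bands = (
        BandSpec(1155.0, 22.0, 0.15, 0.0060, species_offset=0.010),
        BandSpec(1212.0, 24.0, 0.18, -0.0050, species_offset=-0.012),
        BandSpec(1340.0, 28.0, 0.22, 0.0055, species_offset=0.010),
        BandSpec(1409.0, 22.0, 0.28, 0.0070, species_offset=0.008),
        BandSpec(1724.0, 26.0, 0.30, -0.0045, species_offset=0.015),
        BandSpec(1908.0, 25.0, 0.45, 0.0080, species_offset=0.0),
        BandSpec(2249.0, 30.0, 0.38, 0.0050, species_offset=-0.012),
        BandSpec(1650.0, 420.0, 0.25, 0.0, species_offset=0.005),
    )
    return SimConfig(bands=bands)


def chemistry_spectrum(grid: WavelengthGrid, bands: Sequence[BandSpec],
                       mc: float, species: str,
                       mc_center: float = 14.0) -> np.ndarray:
    """Noise- and scatter-free log(1/R) spectrum for one sample."""
    lam = grid.values
    out = np.zeros_like(lam)
    arabica = 1.0 if species == "Arabica" else 0.0
    for band in bands:
        amp = (band.amplitude
               + band.moisture_sensitivity * (mc - mc_center)
               + band.species_offset * arabica)
        out += amp * np.exp(-0.5 * ((lam - band.center) / band.width) ** 2)
    return out


def apply_scatter(x: np.ndarray, a: float, b: float,
                  poly: Sequence[float], lam_scaled: np.ndarray) -> np.ndarray:
    """Generator-side scatter: a + b*x + sum_i poly_i * t^(i+1) with t the
    wavelength scaled to [-1, 1] (powers start at 1; the constant term is
    ``a``)."""
    if b == 0:
        raise ArgumentError("multiplicative scatter term b must be nonzero")
    x = np.asarray(x, dtype=float)
    out = a + b * x
    for i, c in enumerate(poly, start=1):
        out = out + c * lam_scaled ** i
    return out


def c4_factor(n: int) -> float:
    """E[s]/sigma for the n-1-denominator SD of n iid normal draws."""
    from scipy.special import gammaln

    if n < 2:
        return 1.0
    return float(np.sqrt(2.0 / (n - 1))
                 * np.exp(gammaln(n / 2) - gammaln((n - 1) / 2)))


def simulate_dataset(config: SimConfig, seed: int
                     ) -> tuple[SpectraSet, list[MoistureRecord], dict]:
    """Generate one full study-structured dataset.

    Returns the replicate-level spectra (roles pre-assigned by origin),
    the duplicate weighing records, and a truth record with the per-sample
    true MC, species, origins and per-replicate scatter parameters.
    Identical (config, seed) pairs give bit-identical output.
    """
    config.validate()
    grid = config.grid()
    lam_scaled = grid.scaled()

    rng_mc = np.random.default_rng([seed, _STREAM_MC])
    rng_scatter = np.random.default_rng([seed, _STREAM_SCATTER])
    rng_noise = np.random.default_rng([seed, _STREAM_NOISE])
    rng_grav = np.random.default_rng([seed, _STREAM_GRAVIMETRIC])

    samples = []  # (sample_id, species, origin, role)
    c = v = 0
    for origin, species, n in config.cal_origins:
        for _ in range(n):
            c += 1
            samples.append((f"C{c:03d}", species, origin, "calibration"))
    for origin, species, n in config.val_origins:
        for _ in range(n):
            v += 1
            samples.append((f"V{v:03d}", species, origin, "validation"))

    n_samples = len(samples)
    true_mc = rng_mc.uniform(*config.mc_range, size=n_samples)

    rows, meta_rows, row_mc = [], [], []
    records: list[MoistureRecord] = []
    truth_scatter = []
    truth_samples = {}
    for i, (sid, species, origin, role) in enumerate(samples):
        chem = chemistry_spectrum(grid, config.bands, true_mc[i], species)

        # gravimetric duplicates -> the reference MC the models train on
        dup_sigma = config.duplicate_sd / c4_factor(config.n_duplicates)
        dup_mcs = []
        for d in range(1, config.n_duplicates + 1):
            mc_noisy = true_mc[i] + rng_grav.normal(0.0, dup_sigma)
            mc_noisy = max(mc_noisy, 0.0)
            ww = rng_grav.normal(config.ww_mean, config.ww_sd)
            loss_fraction = (mc_noisy + config.nonwater_loss) / 100.0
            wd = ww * (1.0 - loss_fraction)
            records.append(MoistureRecord(sid, ww, wd, duplicate=d))
            dup_mcs.append(100.0 * (ww - wd) / ww)
        ref_mc = float(np.mean(dup_mcs))

        for rep in range(1, config.n_replicates + 1):
            a = rng_scatter.normal(0.0, config.scatter_a_sd)
            b = rng_scatter.normal(1.0, config.scatter_b_sd)
            poly = rng_scatter.normal(0.0, config.scatter_poly_sd,
                                      size=config.scatter_poly_order)
            x = apply_scatter(chem, a, b, poly, lam_scaled)
            if config.noise_sd > 0:
                x = x + rng_noise.normal(0.0, config.noise_sd, size=len(grid))
            rows.append(x)
            meta_rows.append({"sample_id": sid, "species": species,
                              "origin": origin, "replicate": rep,
                              "role": role})
            row_mc.append(ref_mc)
            truth_scatter.append({"sample_id": sid, "replicate": rep,
                                  "a": a, "b": b, "poly": poly.tolist()})
        truth_samples[sid] = {"true_mc": float(true_mc[i]), "species": species,
                              "origin": origin, "role": role,
                              "reference_mc": ref_mc}

    spectra = SpectraSet(grid, np.array(rows), pd.DataFrame(meta_rows),
                         np.array(row_mc))
    truth = {"seed": seed,
             "samples": truth_samples,
             "scatter": truth_scatter,
             "bands": [asdict(b) for b in config.bands],
             "n_cal": config.n_cal, "n_val": config.n_val}
    return spectra, records, truth
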
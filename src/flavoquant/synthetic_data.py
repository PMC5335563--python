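"""Seeded forward simulators for every analysis in the package.

Each generator is the exact forward model of the corresponding fitter
plus seeded Gaussian noise, so generator/fitter pairs round-trip
exactly at zero noise and parameter-recovery studies are reproducible
from a single integer seed.

Noise is Gaussian, either additive (fixed sigma in signal units) or
proportional (sigma as a relative fraction, photon-flux-like) — the
latter is the natural choice for fluorescence intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding_titration import (
    TightBindingParams,
    TitrationPoint,
    TitrationProtocol,
    TitrationSeries,
    concentrations_at_point,
    predicted_fluorescence,
)
from .cofactor_composition import CalibrationCurve, EmissionSpectrum
from .enzyme_kinetics import RatePoint, michaelis_menten
from .photometry import FAD, FMN
from .thermal_unfolding import MeltCurve, TwoTransitionFit, two_transition_model

__all__ = [
    "NoiseSpec",
    "generate_titration",
    "generate_emission_spectrum",
    "generate_melt",
    "generate_rates",
    "generate_mrm",
    "reference_spectra",
]

#: Emission peak shape used for synthetic flavin spectra: a single
#: Gaussian centred at 525 nm with 30 nm width. Only relative areas
#: matter downstream, so a simple unimodal shape suffices.
EMISSION_PEAK_CENTER = 525.0
EMISSION_PEAK_WIDTH = 30.0

DEFAULT_WAVELENGTH_GRID = np.arange(470.0, 650.5, 1.0)
DEFAULT_MELT_GRID = np.arange(20.0, 95.5, 0.5)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for a simulation: additive or proportional Gaussian.

    ``sigma`` is in signal units (additive) or a relative fraction
    (proportional). Identical seeds give identical output.
    """

    model: str = "proportional"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("additive", "proportional"):
            raise ValueError("noise model must be 'additive' or 'proportional'")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Add one noise realization to a clean signal."""
        if self.sigma == 0:
            return np.array(signal, dtype=float)
        z = rng.standard_normal(np.shape(signal))
        if self.model == "additive":
            return signal + self.sigma * z
        return signal * (1.0 + self.sigma * z)


def generate_titration(
    params: TightBindingParams,
    protocol: TitrationProtocol | None = None,
    noise: NoiseSpec = NoiseSpec(),
    n_readings: int = 1,
) -> TitrationSeries:
    """Simulate a full titration (points 0..n_additions, inclusive).

    Totals are dilution-corrected per aliquot; the fluorescence at each
    point is the tight-binding model value plus noise. ``n_readings``
    emulates repeated emission readings per point (e.g. a 30 s
    recording) that are averaged into the single stored value.
    """
    if n_readings < 1:
        raise ValueError("n_readings must be at least 1")
    protocol = protocol or TitrationProtocol()
    rng = noise.rng()
    points = []
    for i in range(protocol.n_additions + 1):
        ft, at = concentrations_at_point(protocol, i)
        clean = predicted_fluorescence(params, ft, at)
        reads = noise.apply(np.full(n_readings, clean), rng)
        points.append(TitrationPoint(ft, at, float(np.mean(reads))))
    return TitrationSeries(points)


def _emission_shape(grid: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * ((grid - EMISSION_PEAK_CENTER) / EMISSION_PEAK_WIDTH) ** 2)


def generate_emission_spectrum(
    species_fractions: tuple[float, float],
    total_conc: float,
    grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> EmissionSpectrum:
    """Synthetic emission spectrum of an FMN/FAD mixture.

    ``species_fractions`` is (f_FMN, f_FAD), summing to 1. Intensity is
    the brightness-weighted sum of the species contributions (FMN
    brightness 1, FAD 1/9) times the shared Gaussian peak shape, scaled
    by the total flavin concentration (uM).
    """
    f_fmn, f_fad = species_fractions
    if abs(f_fmn + f_fad - 1.0) > 1e-9:
        raise ValueError("species fractions must sum to 1")
    if total_conc < 0:
        raise ValueError("total concentration must be non-negative")
    grid = DEFAULT_WAVELENGTH_GRID if grid is None else np.asarray(grid, dtype=float)
    amplitude = total_conc * (
        f_fmn * FMN.relative_brightness + f_fad * FAD.relative_brightness
    )
    clean = amplitude * _emission_shape(grid)
    return EmissionSpectrum(grid, noise.apply(clean, noise.rng()))


def reference_spectra(
    total_conc: float = 0.9, grid: np.ndarray | None = None
) -> tuple[EmissionSpectrum, EmissionSpectrum]:
    """Noiseless equimolar pure-FMN and pure-FAD reference spectra."""
    return (
        generate_emission_spectrum((1.0, 0.0), total_conc, grid),
        generate_emission_spectrum((0.0, 1.0), total_conc, grid),
    )


def generate_melt(
    fit: TwoTransitionFit,
    grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> MeltCurve:
    """Synthetic CD melt on a 20-95 deg C grid (0.5 deg steps by default)."""
    grid = DEFAULT_MELT_GRID if grid is None else np.asarray(grid, dtype=float)
    clean = two_transition_model(grid, fit)
    return MeltCurve(grid, noise.apply(clean, noise.rng()))


def generate_rates(
    kcat: float,
    km: float,
    enzyme_conc: float,
    substrate_levels,
    noise: NoiseSpec = NoiseSpec(),
) -> list[RatePoint]:
    """Initial-rate points v = kcat [E] S / (K_M + S) plus noise."""
    if kcat <= 0 or km <= 0 or enzyme_conc <= 0:
        raise ValueError("kcat, km and enzyme concentration must be positive")
    s = np.asarray(substrate_levels, dtype=float)
    clean = michaelis_menten(s, kcat * enzyme_conc, km)
    noisy = noise.apply(clean, noise.rng())
    return [RatePoint(float(si), float(vi)) for si, vi in zip(s, noisy)]


def generate_mrm(
    true_concs: tuple[float, float],
    curves: tuple[CalibrationCurve, CalibrationCurve],
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[float, float]:
    """Quantifier peak areas (FMN, FAD) from true concentrations and
    linear calibration curves, plus noise."""
    c_fmn, c_fad = true_concs
    if c_fmn < 0 or c_fad < 0:
        raise ValueError("true concentrations must be non-negative")
    cal_fmn, cal_fad = curves
    clean = np.array([
        cal_fmn.slope * c_fmn + cal_fmn.intercept,
        cal_fad.slope * c_fad + cal_fad.intercept,
    ])
    noisy = noise.apply(clean, noise.rng())
    return float(noisy[0]), float(noisy[1])
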
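"""FMN/FAD composition of a released flavin cofactor pool.

Two independent routes:

1. Fluorescence. After SDS denaturation the enzyme releases its flavin,
   and because free FMN is ~9-fold brighter than free FAD the emission
   of the released pool locates the sample on the line between the two
   equimolar pure references:

       F_fin = f_FMN * F_FMN + (1 - f_FMN) * F_FAD

   inverted as f_FMN = (F_fin - F_FAD) / (F_FMN - F_FAD). A
   full-spectrum generalization fits the mixture spectrum as a convex
   combination of the two reference spectra.

2. MRM (multiple reaction monitoring) mass spectrometry. Each species is
   quantified by a precursor->product transition against a linear
   calibration curve; the mole fraction follows from the two back-
   calculated concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "MixtureInputs",
    "MixtureEstimate",
    "MRMTransition",
    "DEFAULT_TRANSITIONS",
    "CalibrationCurve",
    "solve_flavin_fractions",
    "decompose_spectrum",
    "fit_calibration",
    "fraction_from_mrm",
    "qualifier_ratio_ok",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission spectrum on a fixed wavelength grid."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or wl.shape != it.shape:
            raise ValueError("wavelength and intensity must be matching 1-D arrays")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)

    def integrated(self) -> float:
        """Trapezoidal integral of the intensity over wavelength."""
        if len(self.wavelength_nm) == 1:
            return float(self.intensity[0])
        return float(np.trapezoid(self.intensity, self.wavelength_nm))


@dataclass(frozen=True)
class MixtureInputs:
    """Fluorescence readings for the two-point composition solve.

    ``f_fin`` is the emission of the SDS-released sample; the references
    are equimolar pure FMN and pure FAD readings at the same instrument
    settings. FMN must be the brighter reference.
    """

    f_fin: float
    f_fmn_ref: float
    f_fad_ref: float

    def __post_init__(self) -> None:
        if self.f_fad_ref < 0:
            raise ValueError("reference fluorescence must be non-negative")
        if self.f_fmn_ref <= self.f_fad_ref:
            raise ValueError("FMN reference must be brighter than FAD reference")


@dataclass(frozen=True)
class MixtureEstimate:
    """FMN/FAD mole-fraction estimate.

    ``f_fmn + f_fad == 1`` exactly. Values outside [0, 1] are reported
    unclamped with ``within_bounds=False`` (a warning is emitted at
    construction time by the estimators): an out-of-range fraction is a
    diagnostic for bad references, not a number to hide.
    """

    f_fmn: float
    f_fad: float
    uncertainty: float
    method: str

    @property
    def within_bounds(self) -> bool:
        return 0.0 <= self.f_fmn <= 1.0

    def __post_init__(self) -> None:
        if abs(self.f_fmn + self.f_fad - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")
        if self.method not in ("fluorescence", "spectrum", "mrm"):
            raise ValueError(f"unknown method {self.method!r}")


def _warn_if_out_of_range(f_fmn: float, context: str) -> None:
    if not 0.0 <= f_fmn <= 1.0:
        warnings.warn(
            f"{context}: FMN fraction {f_fmn:.3f} outside [0, 1]; check the "
            "reference measurements",
            stacklevel=3,
        )


def solve_flavin_fractions(
    inputs: MixtureInputs,
    sigma_fin: float = 0.0,
    sigma_fmn_ref: float = 0.0,
    sigma_fad_ref: float = 0.0,
) -> MixtureEstimate:
    """Two-point linear solve for the FMN fraction of a flavin mixture.

    ``f_FMN = (F_fin - F_FAD) / (F_FMN - F_FAD)`` and
    ``f_FAD = 1 - f_FMN``. Optional standard deviations of the three
    readings propagate to a first-order standard error on the fraction;
    the error shrinks as the brightness contrast between the references
    grows.
    """
    span = inputs.f_fmn_ref - inputs.f_fad_ref
    f_fmn = (inputs.f_fin - inputs.f_fad_ref) / span
    var = (
        sigma_fin**2
        + f_fmn**2 * sigma_fmn_ref**2
        + (1.0 - f_fmn) ** 2 * sigma_fad_ref**2
    ) / span**2
    _warn_if_out_of_range(f_fmn, "fluorescence composition")
    return MixtureEstimate(
        f_fmn=f_fmn, f_fad=1.0 - f_fmn, uncertainty=float(np.sqrt(var)), method="fluorescence"
    )


def decompose_spectrum(
    mix: EmissionSpectrum, ref_fmn: EmissionSpectrum, ref_fad: EmissionSpectrum
) -> MixtureEstimate:
    """Full-spectrum two-component unmixing.

    Fits the mixture spectrum as the convex combination
    ``f * ref_fmn + (1 - f) * ref_fad`` by least squares over the shared
    wavelength grid (closed form for the single free fraction). On a
    one-wavelength grid this is identical to
    :func:`solve_flavin_fractions`. Out-of-range fractions are reported
    unclamped with a warning.
    """
    for ref in (ref_fmn, ref_fad):
        if not np.array_equal(mix.wavelength_nm, ref.wavelength_nm):
            raise ValueError("spectra are not on a shared wavelength grid")
    direction = ref_fmn.intensity - ref_fad.intensity
    norm2 = float(direction @ direction)
    if norm2 == 0.0:
        raise ValueError("reference spectra are identical: species indistinguishable")
    if not (np.any(mix.intensity) or np.any(ref_fad.intensity)):
        raise ValueError("no signal in mixture spectrum")
    f_fmn = float((mix.intensity - ref_fad.intensity) @ direction) / norm2
    resid = mix.intensity - (f_fmn * ref_fmn.intensity + (1 - f_fmn) * ref_fad.intensity)
    n = len(mix.intensity)
    # standard error of the single fitted fraction from residual scatter
    sigma2 = float(resid @ resid) / max(n - 1, 1)
    se = float(np.sqrt(sigma2 / norm2))
    _warn_if_out_of_range(f_fmn, "spectral unmixing")
    return MixtureEstimate(f_fmn=f_fmn, f_fad=1.0 - f_fmn, uncertainty=se, method="spectrum")


@dataclass(frozen=True)
class MRMTransition:
    """A precursor -> product MRM transition for one flavin species."""

    species: str
    precursor_mz: float
    product_mz: float
    polarity: str
    retention_time: float
    role: str = "quantifier"

    def __post_init__(self) -> None:
        if self.species not in ("FMN", "FAD"):
            raise ValueError("species must be FMN or FAD")
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        if self.role not in ("quantifier", "qualifier"):
            raise ValueError("role must be 'quantifier' or 'qualifier'")


#: Default transitions: FAD fragments to AMP (348.1 m/z, quantifier) and
#: adenine (136.1 m/z) in positive mode; FMN to phosphate (97.0 m/z,
#: quantifier) and PO3- (78.9 m/z) in negative mode.
DEFAULT_TRANSITIONS = (
    MRMTransition("FAD", 786.15, 348.10, "positive", 8.85, "quantifier"),
    MRMTransition("FAD", 786.15, 136.10, "positive", 8.85, "qualifier"),
    MRMTransition("FMN", 455.00, 97.00, "negative", 8.73, "quantifier"),
    MRMTransition("FMN", 455.00, 78.90, "negative", 8.73, "qualifier"),
)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear MRM response: peak area = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    def concentration(self, area: float) -> float:
        """Back-calculate concentration from a peak area, floored at zero."""
        c = (area - self.intercept) / self.slope
        if c < 0:
            warnings.warn(
                "peak area below calibration intercept; concentration floored at 0",
                stacklevel=2,
            )
            c = 0.0
        return c


def fit_calibration(
    concentrations, areas, through_origin: bool = False
) -> CalibrationCurve:
    """Ordinary least-squares calibration line through >= 3 standards."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("concentrations and areas must be matching 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 calibration standards")
    if np.ptp(x) == 0:
        raise ValueError("calibration standards have no concentration variance")
    if through_origin:
        slope = float((x @ y) / (x @ x))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return CalibrationCurve(slope=slope, intercept=intercept, r_squared=min(r2, 1.0))


def fraction_from_mrm(
    area_fmn: float,
    area_fad: float,
    cal_fmn: CalibrationCurve,
    cal_fad: CalibrationCurve,
    sigma_area_fmn: float = 0.0,
    sigma_area_fad: float = 0.0,
) -> MixtureEstimate:
    """FMN mole fraction from quantifier peak areas and calibration curves.

    Concentrations are back-calculated per species (negative values
    floored at zero with a warning) and the fraction is
    ``c_FMN / (c_FMN + c_FAD)``. Optional area standard deviations give
    a first-order standard error.
    """
    if area_fmn < 0 or area_fad < 0:
        raise ValueError("peak areas must be non-negative")
    c_fmn = cal_fmn.concentration(area_fmn)
    c_fad = cal_fad.concentration(area_fad)
    total = c_fmn + c_fad
    if total == 0:
        raise ValueError("no analyte detected: both back-calculated concentrations are 0")
    f_fmn = c_fmn / total
    s_cf = sigma_area_fmn / cal_fmn.slope
    s_cd = sigma_area_fad / cal_fad.slope
    var = (c_fad * s_cf) ** 2 + (c_fmn * s_cd) ** 2
    se = float(np.sqrt(var)) / total**2
    return MixtureEstimate(f_fmn=f_fmn, f_fad=1.0 - f_fmn, uncertainty=se, method="mrm")


def qualifier_ratio_ok(
    quantifier_area: float,
    qualifier_area: float,
    expected_ratio: float,
    tolerance: float = 0.30,
) -> bool:
    """Identity gate on the qualifier/quantifier area ratio.

    Returns True when the observed ratio lies within ``tolerance``
    (relative, default +/-30%) of the expected ratio established from
    standards. A failing gate flags an interfering peak.
    """
    if quantifier_area <= 0 or expected_ratio <= 0:
        raise ValueError("quantifier area and expected ratio must be positive")
    observed = qualifier_area / quantifier_area
    return abs(observed - expected_ratio) <= tolerance * expected_ratio
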
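"""Flavin spectral constants and absorbance arithmetic.

Beer-Lambert concentration conversions, A280/A450 purity ratios and a
simple holo-fraction estimator for flavoprotein preparations.

Flavoproteins carry FAD or FMN as a redox cofactor. The protein absorbs
at 280 nm while the oxidized isoalloxazine ring absorbs around 450 nm,
so the A280/A450 ratio reports how completely a preparation is loaded
with cofactor: a fully flavinylated enzyme shows a low ratio (~12-13 for
an MBP-tagged proline dehydrogenase subunit), while apoprotein shows a
much higher one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "FlavinSpectralConstants",
    "AbsorbancePair",
    "FAD",
    "FMN",
    "RIBOFLAVIN",
    "SPECTRAL_CONSTANTS",
    "to_molar",
    "concentration_from_absorbance",
    "purity_ratio",
    "estimate_holo_fraction",
]

#: Multipliers converting tagged concentration units to molar.
_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


def to_molar(value: float, unit: str) -> float:
    """Convert a unit-tagged concentration to molar.

    Accepted tags: ``M``, ``mM``, ``uM`` (or ``µM``), ``nM``.
    """
    try:
        scale = _UNIT_SCALE[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(set(_UNIT_SCALE))}"
        ) from None
    return value * scale


@dataclass(frozen=True)
class FlavinSpectralConstants:
    """Molar absorption coefficient and relative fluorescence of a flavin.

    Parameters
    ----------
    species : str
        One of ``"FAD"``, ``"FMN"``, ``"riboflavin"``.
    epsilon : float
        Molar absorption coefficient in M^-1 cm^-1.
    lambda_abs : float
        Wavelength (nm) at which ``epsilon`` applies.
    relative_brightness : float
        Fluorescence emission per mole relative to FMN (= 1). Free FAD is
        roughly 9-fold less fluorescent than FMN because the adenine
        stacks onto the isoalloxazine ring and quenches it.
    """

    species: str
    epsilon: float
    lambda_abs: float
    relative_brightness: float

    def __post_init__(self) -> None:
        if self.species not in ("FAD", "FMN", "riboflavin"):
            raise ValueError(f"unknown flavin species {self.species!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 300.0 <= self.lambda_abs <= 600.0:
            raise ValueError("lambda_abs must lie in [300, 600] nm")
        if self.relative_brightness <= 0:
            raise ValueError("relative_brightness must be positive")


FAD = FlavinSpectralConstants("FAD", 11300.0, 450.0, 1.0 / 9.0)
FMN = FlavinSpectralConstants("FMN", 12200.0, 445.0, 1.0)
RIBOFLAVIN = FlavinSpectralConstants("riboflavin", 12500.0, 445.0, 1.0)

SPECTRAL_CONSTANTS = {c.species: c for c in (FAD, FMN, RIBOFLAVIN)}


@dataclass(frozen=True)
class AbsorbancePair:
    """A (A280, A450) absorbance reading pair for one sample.

    ``a_flavin`` is the absorbance at the flavin visible band (450 nm by
    convention here); ``pathlength`` is in cm.
    """

    a280: float
    a_flavin: float
    pathlength: float = 1.0

    def __post_init__(self) -> None:
        if self.a280 < 0:
            raise ValueError("a280 must be non-negative")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive")


def concentration_from_absorbance(
    a: float, constants: FlavinSpectralConstants, pathlength: float = 1.0
) -> float:
    """Beer-Lambert concentration (molar) from an absorbance reading.

    Returns ``a / (epsilon * pathlength)`` in M.
    """
    if a < 0:
        raise ValueError("absorbance must be non-negative")
    if pathlength <= 0:
        raise ValueError("pathlength must be positive")
    return a / (constants.epsilon * pathlength)


def purity_ratio(pair: AbsorbancePair) -> float:
    """A280/A450 ratio of a flavoprotein sample.

    Raises
    ------
    ValueError
        If the flavin absorbance is zero (apoprotein with no detectable
        flavin; the ratio is undefined).
    """
    if pair.a_flavin <= 0:
        raise ValueError(
            "flavin absorbance is zero or negative: purity ratio undefined "
            "(sample may be pure apoprotein)"
        )
    return pair.a280 / pair.a_flavin


def estimate_holo_fraction(ratio_obs: float, ratio_full: float) -> float:
    """Estimate the holoprotein fraction from an observed A280/A450 ratio.

    Model: A280 per subunit is flavin-independent while A450 scales with
    the holo fraction, so ``fraction = ratio_full / ratio_obs`` where
    ``ratio_full`` is the ratio of a fully flavinylated reference. The
    flavin contribution to A280 is neglected (protein absorbance
    dominates at these ratios). This is a model-based estimator, not a
    measured quantity.

    Values above 1 (observed ratio below the full-loading reference,
    i.e. measurement noise) are clipped to 1 with a warning.
    """
    if ratio_full <= 0:
        raise ValueError("ratio_full must be positive")
    if ratio_obs <= 0:
        raise ValueError("ratio_obs must be positive")
    fraction = ratio_full / ratio_obs
    if fraction > 1.0:
        warnings.warn(
            "observed ratio below full-loading reference; holo fraction clipped to 1",
            stacklevel=2,
        )
        fraction = 1.0
    return fraction
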
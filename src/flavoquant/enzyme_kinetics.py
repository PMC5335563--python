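"""Michaelis-Menten kinetics for the proline:DCPIP oxidoreductase assay.

Proline dehydrogenase activity is followed as the bleaching of the
artificial electron acceptor DCPIP at 600 nm. Initial rates versus
L-proline concentration are fitted to

    v = Vmax * S / (K_M + S)

and converted between the reporting conventions: turnover number
kcat = Vmax / [E], catalytic efficiency kcat / K_M, and specific
activity (U mg^-1, with 1 U = 1 umol min^-1) via the subunit molar
mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RatePoint",
    "KineticsFit",
    "EPSILON_DCPIP",
    "MBP_PRODH_SUBUNIT_MASS",
    "rate_from_absorbance",
    "michaelis_menten",
    "michaelis_menten_fit",
    "catalytic_efficiency",
    "specific_activity_to_kcat",
    "residual_activity_percent",
]

#: Molar absorption coefficient of oxidized DCPIP at 600 nm, pH ~7.4
#: (M^-1 cm^-1). Standard literature value; configurable per call.
EPSILON_DCPIP = 21000.0

#: Predicted denatured subunit mass of the MBP-tagged proline
#: dehydrogenase fusion (Da); default for specific-activity conversion.
MBP_PRODH_SUBUNIT_MASS = 74401.0


@dataclass(frozen=True)
class RatePoint:
    """One initial-rate measurement: substrate in mM, rate in uM min^-1
    (or any consistent concentration-per-time unit)."""

    substrate_conc: float
    rate: float

    def __post_init__(self) -> None:
        if self.substrate_conc < 0:
            raise ValueError("substrate concentration must be non-negative")


@dataclass(frozen=True)
class KineticsFit:
    """Fitted Michaelis-Menten parameters.

    ``kcat`` in s^-1, ``km`` in mM, ``efficiency = kcat / (km * 1e-3)``
    in s^-1 M^-1. ``vmax`` keeps the raw fitted maximum rate in the rate
    unit of the input data.
    """

    kcat: float
    km: float
    kcat_se: float
    km_se: float
    efficiency: float
    vmax: float
    vmax_se: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.km <= 0:
            raise ValueError("kcat and km must be positive")


def rate_from_absorbance(
    delta_a_per_min: float,
    epsilon_dcpip: float = EPSILON_DCPIP,
    pathlength: float = 1.0,
) -> float:
    """Convert a DCPIP absorbance slope (AU min^-1) to uM min^-1."""
    if delta_a_per_min < 0:
        raise ValueError("absorbance change rate must be non-negative")
    if epsilon_dcpip <= 0 or pathlength <= 0:
        raise ValueError("epsilon and pathlength must be positive")
    return delta_a_per_min / (epsilon_dcpip * pathlength) * 1e6


def michaelis_menten(s, vmax: float, km: float):
    """Hyperbolic rate law v = Vmax * S / (K_M + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def michaelis_menten_fit(
    points,
    enzyme_conc: float = 1.0,
    rate_per_minute: bool = False,
) -> KineticsFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Parameters
    ----------
    points : sequence of RatePoint
        At least 5 substrate levels; they should bracket K_M for the
        parameters to be identifiable.
    enzyme_conc : float
        Enzyme concentration in the same concentration unit as the
        rates, so that ``kcat = Vmax / enzyme_conc``.
    rate_per_minute : bool
        Set True when the rates are per minute; kcat is then divided by
        60 to report s^-1.

    Notes
    -----
    The fit is nonlinear only — linearizations (Lineweaver-Burk, direct
    linear plot) distort the error structure and are deliberately not
    provided. Standard errors come from the curvature of the
    least-squares surface. A warning is issued when the fitted K_M falls
    outside the substrate range (no curvature: the data constrain only
    Vmax/K_M or only Vmax).
    """
    pts = list(points)
    if len(pts) < 5:
        raise ValueError("need at least 5 substrate levels")
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    s = np.array([p.substrate_conc for p in pts])
    v = np.array([p.rate for p in pts])
    if np.ptp(s) == 0:
        raise ValueError("substrate concentrations are all identical")

    vmax0 = float(v.max()) * 1.2 if v.max() > 0 else 1.0
    half = vmax0 / 2.0
    km0 = float(np.interp(half, np.sort(v), s[np.argsort(v)])) if np.any(v > half) else float(np.median(s))
    km0 = max(km0, 1e-6)
    popt, pcov = curve_fit(
        michaelis_menten, s, v, p0=[vmax0, km0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    vmax, km = (float(x) for x in popt)
    vmax_se, km_se = (float(x) for x in np.sqrt(np.clip(np.diag(pcov), 0, None)))
    if not s.min() < km < s.max():
        warnings.warn(
            f"fitted K_M = {km:.3g} mM lies outside the substrate range "
            f"[{s.min():.3g}, {s.max():.3g}] mM; the parameters are poorly "
            "identified",
            stacklevel=2,
        )
    time_scale = 60.0 if rate_per_minute else 1.0
    kcat = vmax / enzyme_conc / time_scale
    kcat_se = vmax_se / enzyme_conc / time_scale
    return KineticsFit(
        kcat=kcat,
        km=km,
        kcat_se=kcat_se,
        km_se=km_se,
        efficiency=catalytic_efficiency(kcat, km),
        vmax=vmax,
        vmax_se=vmax_se,
        converged=np.all(np.isfinite(popt)),
    )


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat / K_M in s^-1 M^-1 from kcat in s^-1 and K_M in mM."""
    if km <= 0:
        raise ZeroDivisionError("K_M must be positive")
    return kcat / (km * 1e-3)


def specific_activity_to_kcat(sa: float, subunit_mass: float = MBP_PRODH_SUBUNIT_MASS) -> float:
    """Apparent turnover (s^-1) from specific activity (U mg^-1).

    1 U = 1 umol min^-1, so ``kcat_app = sa * subunit_mass / 60000``.
    This is the turnover at the assay substrate concentration, not the
    extrapolated Vmax turnover; at sub-saturating substrate the two
    differ by the Michaelis factor S/(K_M + S).
    """
    if sa <= 0 or subunit_mass <= 0:
        raise ValueError("specific activity and subunit mass must be positive")
    return sa * subunit_mass / 60000.0


def residual_activity_percent(sa_apo: float, sa_holo: float) -> float:
    """Residual activity of an apoprotein preparation, percent of holo."""
    if sa_holo <= 0:
        raise ValueError("holo specific activity must be positive")
    if sa_apo < 0:
        raise ValueError("apo specific activity must be non-negative")
    return 100.0 * sa_apo / sa_holo
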
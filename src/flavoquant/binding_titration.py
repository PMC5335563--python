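"""Tight-binding fluorescence titration model and fitter.

A fixed volume of dilute flavin (~200 nM) is titrated with small
aliquots of apoenzyme. Binding quenches the flavin fluorescence, so the
total emission F at each point is a linear combination of the three
species present:

    F = f_flavin * (flavin_total - c) + f_complex * c + f_apo * (apo_total - c)

where c is the equilibrium concentration of the apoprotein-flavin
complex and f_flavin, f_complex, f_apo are per-species fluorescence
conversion factors (f_apo absorbs the signal of residual holoenzyme
carried in with the titrant). Because the dissociation constant K_D is
comparable to or below the flavin concentration, free and total ligand
cannot be equated; c is the physical root of the mass-action quadratic
(the Morrison tight-binding solution):

    c^2 - (flavin_total + apo_total + K_D) c + flavin_total * apo_total = 0

Totals at each point are dilution-corrected exactly: adding fifty 5 uL
aliquots to 1.3 mL changes the volume by ~19%, which is not negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationProtocol",
    "TitrationPoint",
    "TitrationSeries",
    "TightBindingParams",
    "TitrationFitResult",
    "concentrations_at_point",
    "complex_concentration",
    "predicted_fluorescence",
    "fit_titration",
    "subtract_control",
]


@dataclass(frozen=True)
class TitrationProtocol:
    """Volumes and stock concentrations of a cuvette titration.

    Defaults reproduce the standard schedule: 1.3 mL of 200 nM flavin
    titrated with fifty 5 uL aliquots of 5 uM apoenzyme (250 uL added
    in total).
    """

    v0: float = 1300.0          # initial cuvette volume, uL
    flavin_stock: float = 200.0  # initial flavin concentration, nM
    titrant_conc: float = 5000.0  # apoenzyme stock, nM
    aliquot_volume: float = 5.0  # uL per addition
    n_additions: int = 50

    def __post_init__(self) -> None:
        if min(self.v0, self.flavin_stock, self.titrant_conc, self.aliquot_volume) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.n_additions < 1:
            raise ValueError("n_additions must be at least 1")

    @property
    def total_added_volume(self) -> float:
        """Total titrant volume delivered over the full schedule (uL)."""
        return self.n_additions * self.aliquot_volume


@dataclass(frozen=True)
class TitrationPoint:
    """One titration reading: total concentrations (nM) and fluorescence (AU)."""

    flavin_total: float
    apo_total: float
    fluorescence: float

    def __post_init__(self) -> None:
        if self.flavin_total <= 0:
            raise ValueError("flavin_total must be positive")
        if self.apo_total < 0:
            raise ValueError("apo_total must be non-negative")


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered sequence of titration points."""

    points: tuple[TitrationPoint, ...]

    def __init__(self, points) -> None:
        object.__setattr__(self, "points", tuple(points))

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def flavin_total(self) -> np.ndarray:
        return np.array([p.flavin_total for p in self.points])

    @property
    def apo_total(self) -> np.ndarray:
        return np.array([p.apo_total for p in self.points])

    @property
    def fluorescence(self) -> np.ndarray:
        return np.array([p.fluorescence for p in self.points])


@dataclass(frozen=True)
class TightBindingParams:
    """Dissociation constant and fluorescence conversion factors.

    ``kd`` is in the same concentration unit as the titration totals
    (nM throughout this package). ``f_flavin`` converts free flavin
    concentration to fluorescence, ``f_complex`` the bound complex
    (quenched, so physically f_complex < f_flavin) and ``f_apo`` the
    added apoprotein, which absorbs any residual-holoenzyme background
    that rises linearly with titrant.
    """

    kd: float
    f_flavin: float
    f_complex: float
    f_apo: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.f_flavin <= 0:
            raise ValueError("f_flavin must be positive")
        if self.f_complex < 0 or self.f_apo < 0:
            raise ValueError("conversion factors must be non-negative")


@dataclass(frozen=True)
class TitrationFitResult:
    params: TightBindingParams
    standard_errors: dict[str, float]
    residual_sum_of_squares: float
    converged: bool
    message: str = ""
    n_points: int = 0

    def kd_identifiable(self, n_decades: float = 2.0) -> bool:
        """Whether the K_D confidence interval spans fewer than ``n_decades``
        orders of magnitude (approximate 95% Wald interval on log10 kd).

        Weak binders (e.g. riboflavin) typically fail this check.
        """
        se = self.standard_errors.get("kd", np.inf)
        if not np.isfinite(se):
            return False
        lo = self.params.kd - 1.96 * se
        hi = self.params.kd + 1.96 * se
        if lo <= 0:
            return False
        return np.log10(hi / lo) < n_decades


def concentrations_at_point(
    protocol: TitrationProtocol, i: int
) -> tuple[float, float]:
    """Dilution-corrected total concentrations after the i-th addition.

    With cumulative volume ``V_i = v0 + i * aliquot_volume``::

        flavin_total = flavin_stock * v0 / V_i
        apo_total    = titrant_conc * i * aliquot_volume / V_i

    Index 0 is the pre-addition reading.
    """
    if not 0 <= i <= protocol.n_additions:
        raise IndexError(
            f"addition index {i} outside 0..{protocol.n_additions}"
        )
    v_added = i * protocol.aliquot_volume
    v_i = protocol.v0 + v_added
    flavin_total = protocol.flavin_stock * protocol.v0 / v_i
    apo_total = protocol.titrant_conc * v_added / v_i
    return flavin_total, apo_total


def complex_concentration(flavin_total, apo_total, kd):
    """Equilibrium apoprotein-flavin complex concentration.

    Physical (smaller) root of
    ``c^2 - (ft + at + kd) c + ft * at = 0``, computed in the
    cancellation-free form ``c = 2 ft at / (s + sqrt(s^2 - 4 ft at))``
    with ``s = ft + at + kd``. Accepts scalars or arrays.

    Always satisfies ``0 <= c <= min(flavin_total, apo_total)``. The
    larger root exceeds that bound and is unphysical.
    """
    ft = np.asarray(flavin_total, dtype=float)
    at = np.asarray(apo_total, dtype=float)
    if np.any(ft < 0) or np.any(at < 0):
        raise ValueError("total concentrations must be non-negative")
    if np.any(np.asarray(kd) <= 0):
        raise ValueError("kd must be positive")
    s = ft + at + kd
    disc = np.sqrt(s * s - 4.0 * ft * at)
    c = 2.0 * ft * at / (s + disc)
    if np.ndim(flavin_total) == 0 and np.ndim(apo_total) == 0 and np.ndim(kd) == 0:
        return float(c)
    return c


def predicted_fluorescence(params: TightBindingParams, flavin_total, apo_total):
    """Model fluorescence at given total concentrations (scalar or array)."""
    c = complex_concentration(flavin_total, apo_total, params.kd)
    ft = np.asarray(flavin_total, dtype=float)
    at = np.asarray(apo_total, dtype=float)
    f = (
        params.f_flavin * (ft - c)
        + params.f_complex * c
        + params.f_apo * (at - c)
    )
    if np.ndim(flavin_total) == 0 and np.ndim(apo_total) == 0:
        return float(f)
    return f


def _initial_guess(series: TitrationSeries) -> np.ndarray:
    """Heuristic starting point: f_flavin from the first (no-titrant) point,
    f_complex from the endpoint plateau, kd at a tenth of the starting
    flavin concentration."""
    ft = series.flavin_total
    at = series.apo_total
    fl = series.fluorescence
    f_flavin = max(fl[0] / ft[0], 1e-8)
    # at the endpoint nearly all flavin is bound for a tight binder
    f_complex = max(fl[-1] / ft[-1] - f_flavin * 0.05, 1e-10)
    f_apo = max(0.01 * f_flavin, 1e-10)
    kd = 0.1 * ft[0]
    return np.array([kd, f_flavin, f_complex, f_apo])


def fit_titration(
    series: TitrationSeries,
    init: TightBindingParams | None = None,
    weights: np.ndarray | None = None,
) -> TitrationFitResult:
    """Least-squares fit of the tight-binding fluorescence model.

    Parameters are bounded positive. Standard errors come from the local
    curvature (Gauss-Newton covariance ``(J'J)^-1 * RSS/(n-p)``).
    Unweighted by default; pass ``weights`` (multiplied into the
    residuals) for a weighted fit.

    Raises
    ------
    ValueError
        On fewer than 8 points or a degenerate series with no titrant.
    """
    if len(series) < 8:
        raise ValueError("need at least 8 titration points to fit 4 parameters")
    ft = series.flavin_total
    at = series.apo_total
    fl = series.fluorescence
    if np.all(at == 0):
        raise ValueError("degenerate series: apo_total is zero everywhere")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != fl.shape:
            raise ValueError("weights must match the number of points")

    if init is not None:
        x0 = np.array([init.kd, init.f_flavin, init.f_complex, init.f_apo])
    else:
        x0 = _initial_guess(series)

    def residuals(x):
        kd, f_flavin, f_complex, f_apo = x
        c = complex_concentration(ft, at, kd)
        model = f_flavin * (ft - c) + f_complex * c + f_apo * (at - c)
        r = model - fl
        return r * weights if weights is not None else r

    lower = np.array([1e-12, 1e-12, 0.0, 0.0])
    sol = least_squares(residuals, x0, bounds=(lower, np.inf), method="trf")
    rss = float(np.sum(sol.fun**2))
    n, p = len(fl), 4
    ses = {name: np.inf for name in ("kd", "f_flavin", "f_complex", "f_apo")}
    converged = bool(sol.success) and np.all(np.isfinite(sol.x))
    if converged and n > p:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (n - p)
            diag = np.clip(np.diag(cov), 0.0, None)
            ses = dict(zip(("kd", "f_flavin", "f_complex", "f_apo"), np.sqrt(diag)))
        except np.linalg.LinAlgError:
            pass
    kd, f_flavin, f_complex, f_apo = sol.x
    params = TightBindingParams(
        kd=max(kd, 1e-12),
        f_flavin=max(f_flavin, 1e-12),
        f_complex=f_complex,
        f_apo=f_apo,
    )
    result = TitrationFitResult(
        params=params,
        standard_errors={k: float(v) for k, v in ses.items()},
        residual_sum_of_squares=rss,
        converged=converged,
        message=sol.message,
        n_points=n,
    )
    if converged and not result.kd_identifiable():
        warnings.warn(
            "K_D is poorly identified (confidence interval spans more than "
            "two orders of magnitude); binding may be too weak for this "
            "protocol",
            stacklevel=2,
        )
    return result


def subtract_control(series: TitrationSeries, control: TitrationSeries) -> TitrationSeries:
    """Point-by-point control (buffer-titration) subtraction.

    Both series must come from the same addition grid; concentrations
    are retained from the sample series.
    """
    if len(series) != len(control):
        raise ValueError("sample and control series have different lengths")
    if not np.allclose(series.apo_total, control.apo_total, rtol=1e-9, atol=1e-12):
        raise ValueError("sample and control series are on different addition grids")
    return TitrationSeries(
        TitrationPoint(p.flavin_total, p.apo_total, p.fluorescence - q.fluorescence)
        for p, q in zip(series, control)
    )
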
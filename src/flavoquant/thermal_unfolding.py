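"""Two-transition thermal-unfolding fits for CD melt curves.

A two-domain fusion protein (maltose-binding protein tag + thermostable
enzyme domain) unfolds non-cooperatively: the CD signal versus
temperature shows two separate steps, one per domain. The melt is
modelled as the sum of two logistic transitions over a shared flat
baseline:

    y(T) = baseline + amp1 / (1 + exp((tm1 - T) / w1))
                    + amp2 / (1 + exp((tm2 - T) / w2))

with midpoints tm1 < tm2 (enforced by fitting tm2 = tm1 + dt, dt > 0)
and widths w1, w2 > 0. This is the simplest "double sigmoidal" model
consistent with a two-step melt; sloped native/denatured baselines are
not fitted by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

__all__ = ["MeltCurve", "TwoTransitionFit", "two_transition_model", "fit_melt"]


@dataclass(frozen=True)
class MeltCurve:
    """CD ellipticity versus temperature (deg C), e.g. monitored at 224 nm."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("temperature and signal must be matching 1-D arrays")
        if len(t) < 20:
            raise ValueError("need at least 20 points to fit a melt")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class TwoTransitionFit:
    """Parameters of a two-step melt.

    ``tm1 < tm2`` always; ``amp2 = 0`` (with ``tm2 = nan``) marks a
    single-transition fallback fit.
    """

    baseline: float
    amp1: float
    amp2: float
    tm1: float
    tm2: float
    w1: float
    w2: float
    standard_errors: dict[str, float] | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.w1 <= 0 or (self.amp2 != 0 and self.w2 <= 0):
            raise ValueError("transition widths must be positive")
        if self.amp2 != 0 and not self.tm1 < self.tm2:
            raise ValueError("midpoints must satisfy tm1 < tm2")


def two_transition_model(T, fit: TwoTransitionFit):
    """Evaluate the double-logistic melt model at temperature(s) T."""
    T = np.asarray(T, dtype=float)
    y = fit.baseline + fit.amp1 / (1.0 + np.exp((fit.tm1 - T) / fit.w1))
    if fit.amp2 != 0:
        y = y + fit.amp2 / (1.0 + np.exp((fit.tm2 - T) / fit.w2))
    return float(y) if y.ndim == 0 else y


def _guess_midpoints(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Locate the two transitions from peaks of the smoothed derivative."""
    dy = np.gradient(y, t)
    k = max(len(t) // 30, 1)
    kernel = np.ones(k) / k
    smooth = np.convolve(np.abs(dy), kernel, mode="same")
    min_sep = max(int(5.0 / np.median(np.diff(t))), 1)
    peaks, props = find_peaks(smooth, distance=min_sep, height=0)
    if len(peaks) >= 2:
        top = peaks[np.argsort(props["peak_heights"])[-2:]]
        return float(t[top.min()]), float(t[top.max()])
    lo, hi = t[0], t[-1]
    return lo + 0.35 * (hi - lo), lo + 0.75 * (hi - lo)


def fit_melt(curve: MeltCurve, init: TwoTransitionFit | None = None) -> TwoTransitionFit:
    """Least-squares two-transition fit of a melt curve.

    The midpoint ordering tm1 < tm2 is built into the parameterization
    (tm2 = tm1 + dt with dt bounded positive). When the two-transition
    model is degenerate — the second amplitude collapses or the
    midpoints coincide — the fit falls back to a single logistic with a
    warning.

    Standard errors are Gauss-Newton estimates; the tm2 error combines
    the tm1 and dt uncertainties including their covariance.
    """
    t, y = curve.temperature, curve.signal
    if init is not None:
        x0 = np.array([
            init.baseline, init.amp1, init.amp2, init.tm1,
            max(init.tm2 - init.tm1, 0.5), init.w1, init.w2,
        ])
    else:
        tm1_0, tm2_0 = _guess_midpoints(t, y)
        rise = y[-1] - y[0]
        x0 = np.array([y[0], rise / 2.0, rise / 2.0, tm1_0, tm2_0 - tm1_0, 2.0, 2.0])

    span = t[-1] - t[0]
    scale = max(float(np.ptp(y)), 1e-12)
    lower = [-np.inf, -10 * scale, -10 * scale, t[0] - span, 0.25, 0.05, 0.05]
    upper = [np.inf, 10 * scale, 10 * scale, t[-1] + span, 2 * span, span, span]
    x0 = np.clip(x0, lower, upper)

    def residuals(x):
        b, a1, a2, tm1, dt, w1, w2 = x
        model = (
            b
            + a1 / (1.0 + np.exp((tm1 - t) / w1))
            + a2 / (1.0 + np.exp((tm1 + dt - t) / w2))
        )
        return model - y

    sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
    b, a1, a2, tm1, dt, w1, w2 = sol.x
    rss = float(np.sum(sol.fun**2))
    n, p = len(t), 7

    degenerate = (
        not sol.success
        or min(abs(a1), abs(a2)) < 1e-3 * max(abs(a1) + abs(a2), scale)
        or dt <= 0.3
    )
    if degenerate:
        warnings.warn(
            "second transition not resolved; falling back to a single-"
            "sigmoid fit",
            stacklevel=2,
        )
        return _fit_single(curve)

    ses: dict[str, float] = {}
    if n > p:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / (n - p)
            diag = np.clip(np.diag(cov), 0.0, None)
            names = ["baseline", "amp1", "amp2", "tm1", "dt", "w1", "w2"]
            ses = dict(zip(names, np.sqrt(diag)))
            # var(tm2) = var(tm1) + var(dt) + 2 cov(tm1, dt)
            var_tm2 = max(cov[3, 3] + cov[4, 4] + 2 * cov[3, 4], 0.0)
            ses["tm2"] = float(np.sqrt(var_tm2))
            del ses["dt"]
        except np.linalg.LinAlgError:
            pass

    if dt < 2.0:
        warnings.warn(
            "melting midpoints are nearly coincident; confidence intervals "
            "are unreliable",
            stacklevel=2,
        )

    return TwoTransitionFit(
        baseline=float(b), amp1=float(a1), amp2=float(a2),
        tm1=float(tm1), tm2=float(tm1 + dt), w1=float(w1), w2=float(w2),
        standard_errors=ses or None, converged=bool(sol.success),
    )


def _fit_single(curve: MeltCurve) -> TwoTransitionFit:
    """Single-logistic fallback for curves with one resolvable transition."""
    t, y = curve.temperature, curve.signal

    def residuals(x):
        b, a1, tm1, w1 = x
        return b + a1 / (1.0 + np.exp((tm1 - t) / w1)) - y

    rise = y[-1] - y[0]
    tm0 = float(t[np.argmin(np.abs(y - (y[0] + rise / 2)))])
    x0 = np.array([y[0], rise, tm0, 2.0])
    span = t[-1] - t[0]
    scale = max(float(np.ptp(y)), 1e-12)
    sol = least_squares(
        residuals, x0,
        bounds=([-np.inf, -10 * scale, t[0] - span, 0.05], [np.inf, 10 * scale, t[-1] + span, span]),
        method="trf",
    )
    b, a1, tm1, w1 = sol.x
    rss = float(np.sum(sol.fun**2))
    n, p = len(t), 4
    ses = None
    if n > p and sol.success:
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / (n - p)
            diag = np.clip(np.diag(cov), 0.0, None)
            ses = dict(zip(["baseline", "amp1", "tm1", "w1"], np.sqrt(diag)))
        except np.linalg.LinAlgError:
            pass
    return TwoTransitionFit(
        baseline=float(b), amp1=float(a1), amp2=0.0,
        tm1=float(tm1), tm2=float("nan"), w1=float(w1), w2=float("nan"),
        standard_errors=ses, converged=bool(sol.success),
    )
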
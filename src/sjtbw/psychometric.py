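"""Gaussian simultaneity-curve fitting and temporal-binding-window indices.

The simultaneous-response rate over SOA is modeled as an unnormalised
Gaussian

    y(t) = a * exp(-(t - b)^2 / (2 c^2)),

with ``a`` the peak rate, ``b`` the point of subjective simultaneity (PSS)
and ``c`` the scale, all with t in seconds.  The headline binding-window
index is the half width at half height, HWHH = c * sqrt(2 ln 2) (~1.18 c);
several alternative width indices from the simultaneity-judgment literature
are derived from the same fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .trial_prep import BinnedRates

#: HWHH per unit Gaussian scale c: sqrt(2 ln 2).
HWHH_PER_C = math.sqrt(2.0 * math.log(2.0))

_BOUNDS_LO = (1e-9, -1.0, 0.01)
_BOUNDS_HI = (1.2, 1.0, 5.0)
_C_STARTS_S = (0.2, 0.4, 0.8)


class FitError(ValueError):
    """Raised when the Gaussian curve cannot be fit to the binned rates."""


@dataclass
class GaussianFit:
    """Least-squares Gaussian fit to binned simultaneity rates.

    Coefficients use seconds; ``sse`` is the sum of squared residuals over
    the occupied windows actually used.
    """

    a: float
    b: float
    c: float
    sse: float
    converged: bool
    n_windows_used: int

    def predict(self, t_s: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_s, dtype=float)
        return self.a * np.exp(-((t - self.b) ** 2) / (2.0 * self.c**2))


def gaussian_curve(t_s, a, b, c):
    t = np.asarray(t_s, dtype=float)
    return a * np.exp(-((t - b) ** 2) / (2.0 * c**2))


def _occupied_rates(binned: BinnedRates) -> tuple[np.ndarray, np.ndarray]:
    mask = binned.occupied
    t_s = binned.window_centers_ms[mask] / 1000.0
    y = binned.rate[mask]
    return t_s, y


def fit_gaussian(binned: BinnedRates) -> GaussianFit:
    """Fit the Gaussian simultaneity curve by unweighted least squares.

    Only occupied windows enter the loss, each with equal weight.  The
    optimiser is bounded trust-region least squares restarted from three
    widths (0.2, 0.4, 0.8 s); the start for ``b`` is the center of the
    highest-rate window, ties broken toward 0 ms.

    Raises
    ------
    FitError
        If fewer than four windows are occupied, or every rate is zero
        (no peak to fit).
    """
    t_s, y = _occupied_rates(binned)
    if len(t_s) < 4:
        raise FitError(
            f"need at least 4 occupied windows to fit 3 parameters, "
            f"got {len(t_s)}")
    if np.all(y == 0.0):
        raise FitError("all simultaneous-response rates are zero; no peak")

    ymax = float(np.max(y))
    peaks = np.flatnonzero(y == ymax)
    b0 = float(t_s[peaks[np.argmin(np.abs(t_s[peaks]))]])
    a0 = min(max(ymax, 1e-6), _BOUNDS_HI[0])
    b0 = float(np.clip(b0, _BOUNDS_LO[1], _BOUNDS_HI[1]))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return gaussian_curve(t_s, *theta) - y

    best = None
    for c0 in _C_STARTS_S:
        res = optimize.least_squares(
            residuals, x0=[a0, b0, c0],
            bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res
    a, b, c = (float(v) for v in best.x)
    sse = float(np.sum(residuals(best.x) ** 2))
    return GaussianFit(a=a, b=b, c=c, sse=sse, converged=bool(best.success),
                       n_windows_used=len(t_s))


def goodness_of_fit(binned: BinnedRates, fit: GaussianFit) -> float:
    """Pearson correlation between observed and fitted rates.

    Computed over occupied windows only.  Returns NaN when either side has
    zero variance (the correlation is undefined there).
    """
    t_s, y = _occupied_rates(binned)
    if len(t_s) < 3:
        raise FitError("need at least 3 occupied windows for goodness-of-fit")
    yhat = np.asarray(fit.predict(t_s))
    if np.ptp(y) == 0.0 or np.ptp(yhat) == 0.0:
        return float("nan")
    r, _ = stats.pearsonr(y, yhat)
    return float(r)


@dataclass
class TBWIndices:
    """Width indices of the temporal binding window, in seconds.

    ``hwhh_s`` (half width at half height) is ``c * sqrt(2 ln 2)``;
    ``fwhh_s`` is twice that and ``sigma_s`` is the Gaussian scale itself.
    The absolute-threshold indices are only defined when the peak rate
    clears the threshold: ``width75_s``/``jnd75_s`` need a > 0.75 and
    ``delta50_s`` needs a > 0.5; otherwise they are None and
    ``undefined_reason`` says why.
    """

    hwhh_s: float
    fwhh_s: float
    sigma_s: float
    width75_s: Optional[float]
    jnd75_s: Optional[float]
    delta50_s: Optional[float]
    goodness_of_fit: Optional[float] = None
    undefined_reason: dict[str, str] | None = None


def _abs_threshold_halfwidth(a: float, c: float, level: float) -> Optional[float]:
    """Half-distance between the two SOAs where the curve crosses ``level``."""
    if a <= level:
        return None
    return c * math.sqrt(2.0 * math.log(a / level))


def tbw_indices(fit: GaussianFit,
                binned: Optional[BinnedRates] = None) -> TBWIndices:
    """Derive binding-window width indices from a converged fit.

    When ``binned`` is given, the Pearson goodness-of-fit is attached.
    """
    if not fit.converged:
        raise FitError("cannot derive indices from a non-converged fit")
    hwhh = fit.c * HWHH_PER_C
    jnd75 = _abs_threshold_halfwidth(fit.a, fit.c, 0.75)
    delta50 = _abs_threshold_halfwidth(fit.a, fit.c, 0.5)
    reasons: dict[str, str] = {}
    if jnd75 is None:
        reasons["width75_s"] = reasons["jnd75_s"] = (
            f"peak rate a = {fit.a:.3f} never reaches the 75% level")
    if delta50 is None:
        reasons["delta50_s"] = (
            f"peak rate a = {fit.a:.3f} never reaches the 50% level")
    gof = goodness_of_fit(binned, fit) if binned is not None else None
    return TBWIndices(
        hwhh_s=hwhh,
        fwhh_s=2.0 * hwhh,
        sigma_s=fit.c,
        width75_s=None if jnd75 is None else 2.0 * jnd75,
        jnd75_s=jnd75,
        delta50_s=delta50,
        goodness_of_fit=gof,
        undefined_reason=reasons or None,
    )
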
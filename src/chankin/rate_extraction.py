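"""Initial steady-state rates from 340 nm absorbance progress curves.

NADH absorbs at 340 nm with molar absorptivity 6220 M⁻¹cm⁻¹, so LDH
activity (NADH oxidation at saturating pyruvate) is a falling absorbance
trace.  Two extraction regimes are used, matching standard practice for
coupled dehydrogenase assays:

* starting NADH >= ~40 μM — the early trace is linear; ordinary least
  squares on an initial window gives the rate directly;
* starting NADH < 30 μM — the trace is exponential from the outset
  (substrate below Km); fit ``c(t) = A exp(-k t) + c_inf`` and report the
  initial rate ``v0 = A * k``.

Units: time in minutes, concentrations in μM, rates in μM·min⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import (
    CoverageError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "NADH_EPSILON_340",
    "ProgressCurve",
    "InitialRate",
    "absorbance_to_concentration",
    "initial_rate_linear",
    "initial_rate_exponential",
    "initial_rate_auto",
    "subtract_scatter_baseline",
]

#: Molar absorptivity of NADH at 340 nm, M⁻¹cm⁻¹.
NADH_EPSILON_340 = 6220.0

#: Initial-NADH threshold (μM) below which the exponential method is used.
EXPONENTIAL_REGIME_UM = 30.0


@dataclass(frozen=True)
class ProgressCurve:
    """An absorbance-vs-time trace at 340 nm."""

    times: np.ndarray  # minutes, strictly increasing
    absorbance: np.ndarray
    path_length: float = 1.0  # cm
    epsilon: float = NADH_EPSILON_340  # M⁻¹cm⁻¹

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "absorbance", np.asarray(self.absorbance, float))
        if len(self.times) != len(self.absorbance) or len(self.times) < 10:
            raise InvalidInputError("need >= 10 matched (time, absorbance) points")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.path_length <= 0 or self.epsilon <= 0:
            raise InvalidInputError("path_length and epsilon must be positive")


@dataclass(frozen=True)
class InitialRate:
    v0: float  # μM·min⁻¹
    method: str  # "linear" or "exponential"
    stderr: float = 0.0

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise InvalidInputError(f"initial rate must be nonnegative, got {self.v0}")


def absorbance_to_concentration(curve: ProgressCurve) -> np.ndarray:
    """Concentration series in μM via Beer–Lambert, c = A / (ε·l)."""
    return curve.absorbance / (curve.epsilon * curve.path_length) * 1e6


def initial_rate_linear(
    curve: ProgressCurve, window_fraction: float = 0.10
) -> InitialRate:
    """OLS slope over the initial window, negated to a positive oxidation rate.

    The window keeps the earliest points over which at most
    ``window_fraction`` of the starting NADH has been consumed (default 10%),
    where the trace is linear to good approximation.
    """
    conc = absorbance_to_concentration(curve)
    c0 = conc[0]
    consumed = c0 - conc
    in_window = consumed <= window_fraction * max(c0, np.finfo(float).tiny)
    # the window is the initial contiguous run
    stop = int(np.argmin(in_window)) if not in_window.all() else len(conc)
    if stop < 4:
        raise InsufficientDataError(
            f"only {stop} points inside the {window_fraction:.0%} linear window"
        )
    res = linregress(curve.times[:stop], conc[:stop])
    v0 = -res.slope
    stderr = float(res.stderr)
    if v0 < 0:
        if v0 >= -3.0 * max(stderr, 1e-12):
            v0 = 0.0  # flat trace, slope within noise of zero
        else:
            raise InvalidInputError("absorbance increases over the initial window")
    return InitialRate(v0=float(v0), method="linear", stderr=stderr)


def initial_rate_exponential(curve: ProgressCurve) -> InitialRate:
    """Fit ``c(t) = A exp(-k t) + c_inf`` and return v0 = A·k.

    Initialised from a log-linear regression of ``c - min(c)``; the offset
    ``c_inf`` absorbs incomplete conversion and any constant baseline.
    """
    t = curve.times
    c = absorbance_to_concentration(curve)

    c_inf0 = float(c.min())
    amp = c - c_inf0
    pos = amp > max(amp.max(), np.finfo(float).tiny) * 1e-6
    if pos.sum() >= 3:
        slope = linregress(t[pos], np.log(amp[pos])).slope
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-6)
    a0 = max(float(c[0] - c_inf0), np.finfo(float).tiny)

    def model(tt, a, k, c_inf):
        return a * np.exp(-k * tt) + c_inf

    try:
        popt, pcov = curve_fit(
            model, t, c, p0=[a0, k0, c_inf0], maxfev=20000
        )
    except RuntimeError as exc:
        resid = float(np.std(c))
        raise FitFailureError(
            f"exponential fit did not converge (data SD {resid:.3g} μM): {exc}"
        ) from exc
    a, k, _ = popt
    v0 = a * k
    # delta method: var(ak) = k² var(a) + a² var(k) + 2ak cov(a,k)
    var = (
        k * k * pcov[0, 0] + a * a * pcov[1, 1] + 2.0 * a * k * pcov[0, 1]
    )
    stderr = float(np.sqrt(max(var, 0.0)))
    if v0 < 0:
        if v0 >= -3.0 * max(stderr, 1e-12):
            v0 = 0.0
        else:
            raise FitFailureError(f"exponential fit gave negative initial rate {v0:.3g}")
    return InitialRate(v0=float(v0), method="exponential", stderr=stderr)


def initial_rate_auto(curve: ProgressCurve, window_fraction: float = 0.10) -> InitialRate:
    """Pick the extraction regime from the starting NADH concentration.

    Below 30 μM initial NADH the exponential method is used; at or above it
    (including the 30-40 μM gap) the linear method.
    """
    c0 = float(absorbance_to_concentration(curve)[0])
    if c0 < EXPONENTIAL_REGIME_UM:
        return initial_rate_exponential(curve)
    return initial_rate_linear(curve, window_fraction=window_fraction)


def subtract_scatter_baseline(curve: ProgressCurve, blank: ProgressCurve) -> ProgressCurve:
    """Subtract a scattering blank (e.g. slow GAPDH precipitation drift).

    The blank is linearly interpolated onto the sample time grid; its range
    must cover the sample's.
    """
    if blank.times[0] > curve.times[0] or blank.times[-1] < curve.times[-1]:
        raise CoverageError(
            f"blank covers [{blank.times[0]:g}, {blank.times[-1]:g}] min but the "
            f"curve spans [{curve.times[0]:g}, {curve.times[-1]:g}] min"
        )
    drift = np.interp(curve.times, blank.times, blank.absorbance)
    return ProgressCurve(
        times=curve.times,
        absorbance=curve.absorbance - drift,
        path_length=curve.path_length,
        epsilon=curve.epsilon,
    )
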
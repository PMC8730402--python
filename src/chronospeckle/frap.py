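"""FRAP trace normalization and exponential recovery fitting.

A fluorescence-recovery-after-photobleaching experiment records three
intensity channels after the bleach pulse: the bleached spot, an
unbleached control spot, and background.  Normalization subtracts
background from both signal channels and divides by the unbleached
spot, which corrects for acquisition photobleaching:

    I_norm(t) = (bleached - background) / (reference - background)

The normalized recovery is fit by nonlinear least squares to a single-
or double-exponential recovery,

    I(t) = c + A * (1 - exp(-k t))
    I(t) = c + A1 * (1 - exp(-k1 t)) + A2 * (1 - exp(-k2 t))

and the model with the larger R-squared is kept (ties within 1e-6 go to
the simpler model).  The recovery half-life t_1/2 — the time at which
the recovery reaches half of its total gain — is ln2/k for the single
model and a bracketed root for the double model.  Half-life tracks
condensate fluidity: slower recovery means a more gel-like speckle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .timeseries import TimeSeries

__all__ = [
    "FrapTrace",
    "FrapFit",
    "FrapFitError",
    "normalize_frap",
    "fit_recovery",
    "temporal_frap_summary",
]

#: acquisition defaults: one frame every 1.29 s, 50 frames post-bleach
DEFAULT_FRAME_INTERVAL_S = 1.29
DEFAULT_N_FRAMES = 50

_R2_TIE = 1e-6


class FrapFitError(RuntimeError):
    """Raised when no recovery model can be fit to a trace."""


@dataclass(frozen=True)
class FrapTrace:
    """Raw three-channel FRAP intensities on a common post-bleach grid."""

    times: np.ndarray
    bleached: np.ndarray
    reference: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        b = np.asarray(self.bleached, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        g = np.asarray(self.background, dtype=float)
        if not (t.size == b.size == r.size == g.size):
            raise ValueError("all channels must have equal length")
        if t.size < 10:
            raise ValueError("FRAP trace needs at least 10 frames")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must increase from 0")
        for name, arr in (("times", t), ("bleached", b), ("reference", r), ("background", g)):
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class FrapFit:
    """Fitted recovery model with half-life.

    ``amplitudes`` and ``rates`` have one entry for the single model,
    two for the double; ``offset`` is the post-bleach floor.
    """

    model: str  # "single" | "double"
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    offset: float
    r2: float
    half_life: float

    @property
    def plateau(self) -> float:
        return self.offset + sum(self.amplitudes)


def normalize_frap(trace: FrapTrace) -> TimeSeries:
    """Background-subtract and normalize to the unbleached reference."""
    ref = trace.reference - trace.background
    if np.any(ref <= 0):
        raise ValueError("reference must exceed background at every frame")
    return TimeSeries(trace.times, (trace.bleached - trace.background) / ref)


def _single(t, c, a, k):
    return c + a * (1.0 - np.exp(-k * t))


def _double(t, c, a1, k1, a2, k2):
    return c + a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return -math.inf
    return 1.0 - ss_res / ss_tot


def _initial_rate(t: np.ndarray, y: np.ndarray, c0: float, a0: float) -> float:
    """Rate guess from a log-linear fit of the residual gain."""
    resid = 1.0 - (y - c0) / a0
    good = (resid > 1e-3) & (t > 0)
    if np.count_nonzero(good) >= 3:
        slope = np.polyfit(t[good], np.log(resid[good]), 1)[0]
        if slope < 0:
            return -slope
    return math.log(2.0) / (t[-1] / 4.0)


def fit_recovery(norm: TimeSeries) -> FrapFit:
    """Fit single- and double-exponential recoveries, keep the better R².

    Initial values come from the data (offset from the first frame,
    plateau from the tail, rate from a log-linear fit) with three
    perturbed restarts per model; the best converged fit of each model
    competes on plain R².  Raises :class:`FrapFitError` when neither
    model converges or the trace shows no recovery.
    """
    t, y = norm.times, norm.values
    if len(norm) < 10:
        raise ValueError("need at least 10 points to fit a recovery")
    c0 = float(y[0])
    plateau0 = float(np.mean(y[-max(3, len(y) // 10):]))
    a0 = plateau0 - c0
    if a0 <= 0 or np.ptp(y) == 0:
        raise FrapFitError("trace shows no recovery above the post-bleach floor")
    k0 = _initial_rate(t, y, c0, a0)
    # slowest admissible rate: half-life no longer than 50x the record,
    # which keeps the fit identifiable and the half-life bracket finite
    k_min = math.log(2.0) / (50.0 * float(t[-1]))

    def try_fit(func, p0, bounds):
        try:
            popt, _ = curve_fit(func, t, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            return None
        return popt

    best_single = None
    for fac in (1.0, 0.3, 3.0):
        popt = try_fit(
            _single,
            [c0, a0, max(k0 * fac, k_min)],
            ([-np.inf, 0.0, k_min], [np.inf, np.inf, np.inf]),
        )
        if popt is not None:
            r2 = _r2(y, _single(t, *popt))
            if best_single is None or r2 > best_single[1]:
                best_single = (popt, r2)

    best_double = None
    for f1, f2 in ((3.0, 1 / 3), (10.0, 1.0), (1.0, 0.1)):
        popt = try_fit(
            _double,
            [c0, a0 / 2, max(k0 * f1, k_min), a0 / 2, max(k0 * f2, k_min)],
            ([-np.inf, 0.0, k_min, 0.0, k_min], [np.inf] * 5),
        )
        if popt is not None:
            r2 = _r2(y, _double(t, *popt))
            if best_double is None or r2 > best_double[1]:
                best_double = (popt, r2)

    if best_single is None and best_double is None:
        raise FrapFitError("neither recovery model converged")

    use_double = (
        best_double is not None
        and (best_single is None or best_double[1] > best_single[1] + _R2_TIE)
    )
    if use_double:
        (c, a1, k1, a2, k2), r2 = best_double
        half = _half_life_double((a1, a2), (k1, k2), t[-1])
        return FrapFit("double", (float(a1), float(a2)), (float(k1), float(k2)),
                       float(c), r2, half)
    (c, a, k), r2 = best_single
    return FrapFit("single", (float(a),), (float(k),), float(c), r2, math.log(2.0) / k)


def _half_life_double(amps: tuple[float, float], rates: tuple[float, float], t_max: float) -> float:
    """Time at which a multi-exponential recovery reaches half its gain."""
    a1, a2 = amps
    k1, k2 = rates
    total = a1 + a2
    if total <= 0:
        raise FrapFitError("non-positive total recovery gain")

    def gain(t):
        return a1 * (1 - math.exp(-k1 * t)) + a2 * (1 - math.exp(-k2 * t)) - 0.5 * total

    hi = 10.0 * t_max
    while gain(hi) < 0:  # recovery slower than the search bracket
        hi *= 10.0
        if hi > 1e9 * t_max:
            raise FrapFitError("recovery never reaches half its gain")
    return float(brentq(gain, 0.0, hi, xtol=1e-6))


def temporal_frap_summary(fits_by_time: dict[float, FrapFit]) -> TimeSeries:
    """Half-life series over experimental timepoints, for rhythm analysis."""
    if not fits_by_time:
        raise ValueError("no fits provided")
    times = np.array(sorted(fits_by_time))
    values = np.array([fits_by_time[t].half_life for t in times])
    return TimeSeries(times, values)
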
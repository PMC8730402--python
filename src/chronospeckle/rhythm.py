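"""Damped-sinusoid rhythm detection for uniformly sampled series.

The central tool is the matrix-pencil (eigenvalue/pencil) decomposition,
which writes a uniformly sampled signal as a sum of exponentially damped
cosines

    x_k = sum_j A_j * d_j**k * cos(2*pi*t_k/T_j + phi_j)

and recovers amplitude ``A_j``, period ``T_j``, per-sample damping factor
``d_j`` and phase ``phi_j`` for each component by solving a generalized
eigenproblem on the signal's Hankel matrix.  Unlike a periodogram this
resolves closely spaced periods from short records (e.g. superposed 24-h
and 12-h rhythms in a 48-h course sampled every 2 h) and yields a damping
factor per component, which is what the rhythm-classification windows act
on.

The damping convention is *per sampling interval* at the series' native
step: ``d = 1`` is a sustained oscillation, ``d < 1`` decays.  Use
:func:`decay_per_hour` to convert to a per-hour factor when comparing
series sampled at different rates.

Supporting operations: polynomial detrending, a periodogram wrapper,
rhythm-window classification, permutation-based FDR estimation, and
circular phase (acrophase) summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import polynomial as P
from scipy import signal as sps
from scipy.linalg import hankel

from .timeseries import TimeSeries

__all__ = [
    "SpectralComponent",
    "RhythmCriteria",
    "RhythmCall",
    "PhaseDistribution",
    "CIRCADIAN",
    "ULTRADIAN12",
    "detrend_polynomial",
    "matrix_pencil_decompose",
    "reconstruct",
    "dominant_component",
    "classify_component",
    "classify_series",
    "periodogram_psd",
    "permutation_fdr",
    "acrophase",
    "phase_distribution",
    "decay_per_hour",
]

# imaginary parts below this fraction of |z| are treated as real poles
_REAL_POLE_TOL = 1e-8


@dataclass(frozen=True)
class SpectralComponent:
    """One damped cosine: ``A * d**k * cos(2*pi*t/T + phi)``.

    ``period`` is ``inf`` for aperiodic (DC/trend) terms.  ``amplitude``
    is the cosine coefficient, i.e. half the peak-to-trough swing.
    """

    amplitude: float
    period: float
    decay_per_sample: float
    phase: float

    @property
    def is_oscillatory(self) -> bool:
        return np.isfinite(self.period)


@dataclass(frozen=True)
class RhythmCriteria:
    """Inclusive period/decay windows defining a rhythm class."""

    period_lo: float
    period_hi: float
    decay_lo: float = 0.8
    decay_hi: float = 1.2

    def __post_init__(self) -> None:
        if not (0 < self.period_lo < self.period_hi):
            raise ValueError("need 0 < period_lo < period_hi")
        if not (0 <= self.decay_lo < self.decay_hi):
            raise ValueError("need 0 <= decay_lo < decay_hi")

    def contains(self, c: SpectralComponent) -> bool:
        return (
            self.period_lo <= c.period <= self.period_hi
            and self.decay_lo <= c.decay_per_sample <= self.decay_hi
        )


#: Circadian window: period 21-25 h, per-sample decay 0.8-1.2.
CIRCADIAN = RhythmCriteria(21.0, 25.0, 0.8, 1.2)
#: ~12-hour ultradian window: period 10.5-13.5 h, per-sample decay 0.8-1.2.
ULTRADIAN12 = RhythmCriteria(10.5, 13.5, 0.8, 1.2)


@dataclass(frozen=True)
class RhythmCall:
    """Classification of one series: label plus its dominant component."""

    label: str  # "circadian" | "ultradian12" | "other"
    dominant: SpectralComponent | None
    fdr: float | None = None


@dataclass(frozen=True)
class PhaseDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    circular_mean: float
    resultant_length: float


def decay_per_hour(decay_per_sample: float, dt_h: float) -> float:
    """Convert a per-sample damping factor to a per-hour factor."""
    return float(decay_per_sample ** (1.0 / dt_h))


# --------------------------------------------------------------------------
# detrending
# --------------------------------------------------------------------------

def detrend_polynomial(ts: TimeSeries, degree: int = 2) -> tuple[TimeSeries, TimeSeries]:
    """Least-squares polynomial detrend; returns ``(trend, residual)``.

    ``trend + residual`` reconstructs the input exactly.  Applied before
    spectral analysis when a slow drift would otherwise dominate.
    """
    n = len(ts)
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if degree >= n - 1:
        raise ValueError(f"degree {degree} too high for series of length {n}")
    # centre/scale the abscissa for conditioning
    t = ts.times
    tc = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
    coefs = P.polyfit(tc, ts.values, degree)
    trend = P.polyval(tc, coefs)
    return ts.with_values(trend), ts.with_values(ts.values - trend)


# --------------------------------------------------------------------------
# matrix pencil
# --------------------------------------------------------------------------

def matrix_pencil_decompose(
    ts: TimeSeries,
    pencil_L: int | None = None,
    rank_tol: float = 1e-3,
) -> list[SpectralComponent]:
    """Decompose a uniformly sampled series into damped cosines.

    Model order is chosen by discarding singular values of the Hankel
    matrix below ``rank_tol`` times the largest.  Complex-conjugate pole
    pairs merge into one real damped cosine; real positive poles are
    reported as aperiodic (infinite-period) terms; real negative poles
    are Nyquist oscillations with period ``2*dt``.  Components come back
    sorted by descending amplitude.

    Raises ``ValueError`` for non-uniform sampling.
    """
    n = len(ts)
    if n < 4:
        raise ValueError("need at least 4 samples for pencil decomposition")
    dt = ts.uniform_dt
    if dt is None:
        raise ValueError("matrix pencil requires uniform sampling")
    x = ts.values
    t0 = ts.times[0]

    L = pencil_L if pencil_L is not None else n // 2
    if not (1 <= L <= n - 2):
        raise ValueError(f"pencil_L must be in [1, {n - 2}]")

    # Hankel data matrix, shape (n-L) x (L+1): Y[i, j] = x[i + j]
    Y = hankel(x[: n - L], x[n - L - 1 :])
    U, s, Vh = np.linalg.svd(Y, full_matrices=False)
    if s[0] <= 0:
        # identically-zero series: single null DC term
        return [SpectralComponent(0.0, math.inf, 1.0, 0.0)]
    M = int(np.sum(s > rank_tol * s[0]))
    M = min(M, L, n - L)

    # Signal-subspace shift invariance: the top-M right singular vectors
    # span the row space of the Vandermonde factor, so the poles are the
    # eigenvalues of pinv(V1) @ V2.
    V = Vh.conj().T[:, :M]  # (L+1) x M
    V1, V2 = V[:-1, :], V[1:, :]
    z = np.linalg.eigvals(np.linalg.pinv(V1) @ V2)

    # complex amplitudes by least squares against the data
    k = np.arange(n)
    Z = np.power.outer(z, k).T  # n x M, Z[k, i] = z_i**k
    c, *_ = np.linalg.lstsq(Z, x.astype(complex), rcond=None)

    comps = _merge_poles(z, c, dt, t0)
    comps.sort(key=lambda c: (-c.amplitude, c.period))
    return comps


def _merge_poles(
    z: np.ndarray, c: np.ndarray, dt: float, t0: float
) -> list[SpectralComponent]:
    """Fold conjugate pole pairs into real damped cosines."""
    comps: list[SpectralComponent] = []
    used = np.zeros(z.size, dtype=bool)
    for i in range(z.size):
        if used[i]:
            continue
        zi, ci = z[i], c[i]
        d = abs(zi)
        if d == 0:
            used[i] = True
            continue
        if abs(zi.imag) <= _REAL_POLE_TOL * d:
            used[i] = True
            a = ci.real
            if zi.real > 0:  # aperiodic trend / DC
                comps.append(
                    SpectralComponent(abs(a), math.inf, d, 0.0 if a >= 0 else math.pi)
                )
            else:  # Nyquist-frequency alternation, period 2*dt
                phi = _wrap_phase((0.0 if a >= 0 else math.pi) - math.pi * t0 / dt)
                comps.append(SpectralComponent(abs(a), 2.0 * dt, d, phi))
            continue
        # find the conjugate partner
        j = None
        for jj in range(i + 1, z.size):
            if not used[jj] and abs(z[jj] - zi.conjugate()) <= 1e-6 * d:
                j = jj
                break
        used[i] = True
        if j is not None:
            used[j] = True
            # average the pair for numerical symmetry
            zi = (zi + z[j].conjugate()) / 2
            ci = (ci + c[j].conjugate()) / 2
            d = abs(zi)
        omega = abs(math.atan2(zi.imag, zi.real))  # rad per sample, (0, pi]
        period = 2.0 * math.pi * dt / omega
        amp = 2.0 * abs(ci)
        phase_k = math.atan2(ci.imag, ci.real)
        if zi.imag < 0:  # use the positive-frequency member of the pair
            phase_k = -phase_k
        phi = _wrap_phase(phase_k - omega * t0 / dt)
        comps.append(SpectralComponent(amp, period, d, phi))
    return comps


def _wrap_phase(phi: float) -> float:
    """Wrap to (-pi, pi]."""
    phi = (phi + math.pi) % (2.0 * math.pi) - math.pi
    if phi == -math.pi:
        phi = math.pi
    return phi


def reconstruct(components: Iterable[SpectralComponent], times: np.ndarray, dt: float) -> np.ndarray:
    """Evaluate the damped-cosine sum on ``times`` (sampled at step ``dt``)."""
    times = np.asarray(times, dtype=float)
    k = (times - times[0]) / dt
    out = np.zeros_like(times)
    for comp in components:
        damp = comp.decay_per_sample**k
        if np.isfinite(comp.period):
            out += comp.amplitude * damp * np.cos(
                2.0 * np.pi * times / comp.period + comp.phase
            )
        else:
            out += comp.amplitude * damp * math.cos(comp.phase)
    return out


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def dominant_component(
    components: Sequence[SpectralComponent],
) -> SpectralComponent | None:
    """The oscillatory (finite-period) component of largest amplitude.

    Amplitude ties break toward the shorter period.  Returns ``None``
    when no oscillatory component is present.
    """
    osc = [c for c in components if c.is_oscillatory]
    if not osc:
        return None
    return min(osc, key=lambda c: (-c.amplitude, c.period))


def classify_component(
    c: SpectralComponent,
    circadian: RhythmCriteria = CIRCADIAN,
    ultradian: RhythmCriteria = ULTRADIAN12,
) -> str:
    """Label a component ``circadian`` / ``ultradian12`` / ``other``.

    Windows are inclusive at both endpoints; the circadian window is
    tested first (the default windows do not overlap).
    """
    if circadian.contains(c):
        return "circadian"
    if ultradian.contains(c):
        return "ultradian12"
    return "other"


def classify_series(
    ts: TimeSeries,
    detrend_degree: int | None = None,
    circadian: RhythmCriteria = CIRCADIAN,
    ultradian: RhythmCriteria = ULTRADIAN12,
    pencil_L: int | None = None,
    rank_tol: float = 1e-3,
) -> RhythmCall:
    """Decompose one series and label its dominant oscillation."""
    if detrend_degree is not None:
        _, ts = detrend_polynomial(ts, detrend_degree)
    comps = matrix_pencil_decompose(ts, pencil_L=pencil_L, rank_tol=rank_tol)
    dom = dominant_component(comps)
    if dom is None:
        return RhythmCall("other", None)
    return RhythmCall(classify_component(dom, circadian, ultradian), dom)


# --------------------------------------------------------------------------
# periodogram
# --------------------------------------------------------------------------

def periodogram_psd(
    ts: TimeSeries,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Periodogram PSD; returns ``(frequencies, power, peak_period)``.

    ``peak_period`` is the reciprocal of the positive frequency with the
    largest power, or ``None`` when the spectrum is flat zero (constant
    input).
    """
    dt = ts.uniform_dt
    if dt is None:
        raise ValueError("periodogram requires uniform sampling")
    freqs, power = sps.periodogram(ts.values, fs=1.0 / dt)
    pos = freqs > 0
    if not np.any(pos) or np.max(power[pos]) <= 0:
        return freqs, power, None
    fpeak = freqs[pos][np.argmax(power[pos])]
    return freqs, power, float(1.0 / fpeak)


# --------------------------------------------------------------------------
# permutation FDR
# --------------------------------------------------------------------------

def permutation_fdr(
    series_set: Sequence[TimeSeries],
    label_of_interest: str = "ultradian12",
    B: int = 1000,
    seed: int = 0,
    detrend_degree: int | None = None,
    circadian: RhythmCriteria = CIRCADIAN,
    ultradian: RhythmCriteria = ULTRADIAN12,
) -> float:
    """Permutation-based FDR for a set of rhythm calls.

    The observed count is the number of series whose dominant component
    earns ``label_of_interest``.  For each of ``B`` rounds one common
    permutation of the time order is applied to every series and the
    count repeated; FDR = mean permuted count / observed count, clipped
    to [0, 1].  Zero observed calls yields FDR 1 by convention.
    """
    if len(series_set) == 0:
        raise ValueError("series_set must be non-empty")
    if B < 100:
        raise ValueError("need at least 100 permutations")

    def _count(value_rows: list[np.ndarray]) -> int:
        n_hit = 0
        for ts, vals in zip(series_set, value_rows):
            call = classify_series(
                ts.with_values(vals),
                detrend_degree=detrend_degree,
                circadian=circadian,
                ultradian=ultradian,
            )
            if call.label == label_of_interest:
                n_hit += 1
        return n_hit

    c_obs = _count([ts.values for ts in series_set])
    if c_obs == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    n = len(series_set[0])
    perm_counts = np.empty(B)
    for b in range(B):
        order = rng.permutation(n)
        perm_counts[b] = _count([ts.values[order] for ts in series_set])
    return float(np.clip(perm_counts.mean() / c_obs, 0.0, 1.0))


# --------------------------------------------------------------------------
# circular phase statistics
# --------------------------------------------------------------------------

def acrophase(c: SpectralComponent) -> float:
    """Peak time of a component within one period, in [0, period)."""
    if not c.is_oscillatory:
        raise ValueError("acrophase undefined for aperiodic components")
    peak = (-c.phase * c.period / (2.0 * math.pi)) % c.period
    if peak >= c.period:  # float modulo can round up to the period itself
        peak -= c.period
    return float(peak)


def phase_distribution(
    peaks: Sequence[float], period: float, n_bins: int = 12
) -> PhaseDistribution:
    """Circular histogram and circular mean of peak times on [0, period)."""
    peaks = np.asarray(peaks, dtype=float) % period
    edges = np.linspace(0.0, period, n_bins + 1)
    counts, _ = np.histogram(peaks, bins=edges)
    angles = 2.0 * np.pi * peaks / period
    zbar = np.exp(1j * angles).mean() if peaks.size else 0.0
    r = abs(zbar)
    mean_time = float((np.angle(zbar) % (2.0 * np.pi)) * period / (2.0 * np.pi)) if r > 0 else math.nan
    return PhaseDistribution(edges, counts, mean_time, float(r))
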
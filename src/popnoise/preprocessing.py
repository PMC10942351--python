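"""Normalization of raw fluorescence traces and calcium-kernel tools.

Raw one-photon fluorescence decays over a session because of photobleaching.
The session-wide trend is estimated by fitting a bi-exponential
``f(t) = a*exp(b*t) + c*exp(d*t)`` to the mean signal across neurons; every
neuron is divided by the fitted trend and then z-scored.  The module also
builds the nuclear-GCaMP6s response kernel (difference of exponentials) used
to bring behavioral and stimulus regressors onto calcium timescales, and a
length-preserving causal convolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import convolve as _convolve

from .errors import AnalysisError, ConfigurationError

log = logging.getLogger("popnoise.preprocessing")

REGIONS = ("Tel", "Tec", "Cer", "Hind")


@dataclass
class ActivityMatrix:
    """Neurons x timepoints activity with per-neuron anatomical metadata.

    ``values[i, t]`` is the signal of neuron ``i`` at frame ``t`` (frame
    ``t`` acquired at ``t / frame_rate_hz`` seconds).  ``positions_um`` and
    ``regions`` may be ``None`` for toy matrices; file I/O requires them.
    """

    values: np.ndarray
    frame_rate_hz: float
    positions_um: np.ndarray | None = None
    regions: np.ndarray | None = None
    dropped_neurons: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ConfigurationError("activity must be a neurons x timepoints matrix with >= 2 timepoints")
        if self.frame_rate_hz <= 0:
            raise ConfigurationError("frame_rate_hz must be positive")
        if self.positions_um is not None:
            self.positions_um = np.asarray(self.positions_um, dtype=float)
            if self.positions_um.shape != (self.n_neurons, 3):
                raise ConfigurationError("positions_um must be (n_neurons, 3)")
        if self.regions is not None:
            self.regions = np.asarray(self.regions)
            if self.regions.shape != (self.n_neurons,):
                raise ConfigurationError("regions must be (n_neurons,)")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class BleachFit:
    """Bi-exponential photobleaching trend ``a*exp(b*t) + c*exp(d*t)``.

    Rates ``b`` and ``d`` are per second.  ``fallback_single`` flags fits
    where the bi-exponential optimizer did not converge and a
    single-exponential was used instead.
    """

    a: float
    b: float
    c: float
    d: float
    fallback_single: bool = False

    def trend(self, t_s: np.ndarray) -> np.ndarray:
        t_s = np.asarray(t_s, dtype=float)
        return self.a * np.exp(self.b * t_s) + self.c * np.exp(self.d * t_s)

    @classmethod
    def constant(cls, level: float = 1.0) -> "BleachFit":
        return cls(a=level / 2.0, b=0.0, c=level / 2.0, d=0.0)


@dataclass
class Kernel:
    """Causal finite-support convolution kernel sampled at ``dt_s``."""

    samples: np.ndarray
    dt_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt_s <= 0:
            raise ConfigurationError("kernel dt_s must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ConfigurationError("kernel samples must be a non-empty vector")

    @property
    def mass(self) -> float:
        return float(self.samples.sum())

    @property
    def argmax_s(self) -> float:
        return float(np.argmax(self.samples) * self.dt_s)


def _biexp(t, a, b, c, d):
    return a * np.exp(b * t) + c * np.exp(d * t)


def fit_bleach_trend(mean_signal: np.ndarray, dt_s: float = 1.0) -> BleachFit:
    """Fit a bi-exponential trend to the session-mean signal.

    Uses four initializations splitting fast/slow rates to avoid the
    symmetric local minimum where both exponentials collapse onto the same
    rate.  Falls back to a single exponential (flagged) if no bi-exponential
    start converges.
    """
    y = np.asarray(mean_signal, dtype=float)
    if y.size < 10:
        raise AnalysisError("need at least 10 samples to fit a bleach trend")
    if np.any(y <= 0):
        raise AnalysisError("bleach fit requires a strictly positive mean signal")
    t = np.arange(y.size) * float(dt_s)
    if np.ptp(y) < 1e-12 * abs(y.mean()):
        k = float(y.mean())
        return BleachFit(a=k / 2.0, b=0.0, c=k / 2.0, d=0.0)

    y0 = float(y[0])
    span = t[-1] if t[-1] > 0 else 1.0
    # overall log-rate from the endpoints; sign free (no decay constraint)
    r0 = float(np.log(max(y[-1], 1e-12) / y0) / span)
    if abs(r0) < 1e-12:
        r0 = -1.0 / span
    starts = [
        (y0 / 2, 4 * r0, y0 / 2, r0 / 4),
        (0.7 * y0, 2 * r0, 0.3 * y0, r0 / 8),
        (y0 / 2, r0, y0 / 2, r0 / 10),
        (0.3 * y0, 8 * r0, 0.7 * y0, r0 / 2),
    ]
    best = None
    best_sse = np.inf
    for p0 in starts:
        try:
            popt, _ = curve_fit(_biexp, t, y, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((_biexp(t, *popt) - y) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is not None:
        fit = BleachFit(a=float(best[0]), b=float(best[1]), c=float(best[2]), d=float(best[3]))
        if np.all(fit.trend(t) > 0):
            return fit
        log.warning("bi-exponential fit crossed zero; falling back to single exponential")
    # single-exponential fallback: log-linear least squares
    coef = np.polyfit(t, np.log(y), 1)
    return BleachFit(a=float(np.exp(coef[1])), b=float(coef[0]), c=0.0, d=0.0, fallback_single=True)


def normalize_activity(activity: ActivityMatrix, fit: BleachFit | None) -> ActivityMatrix:
    """Divide each neuron by the bleach trend, then z-score per neuron.

    Zero-variance neurons cannot be z-scored; they are dropped and their
    original indices recorded in ``dropped_neurons``.  Pass ``fit=None`` to
    skip detrending (unit trend).
    """
    t = activity.times_s
    if fit is None:
        trend = np.ones_like(t)
    else:
        trend = fit.trend(t)
        if np.any(trend <= 0):
            raise AnalysisError("fitted bleach trend must be positive over the recording")
    vals = activity.values / trend[None, :]
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 1e-12 * np.maximum(np.abs(mu[:, 0]), 1.0)
    dropped = np.flatnonzero(~keep)
    if dropped.size:
        log.info("normalize_activity: dropped %d zero-variance neurons: %s", dropped.size, dropped[:20])
    z = (vals[keep] - mu[keep]) / sd[keep]
    return ActivityMatrix(
        values=z,
        frame_rate_hz=activity.frame_rate_hz,
        positions_um=None if activity.positions_um is None else activity.positions_um[keep],
        regions=None if activity.regions is None else activity.regions[keep],
        dropped_neurons=dropped,
    )


def make_gcamp_kernel(rise_s: float = 0.3, decay_s: float = 3.5, dt_s: float = 0.2) -> Kernel:
    """Difference-of-exponentials calcium response kernel, peak-normalized.

    ``k(t) = exp(-t/decay) - exp(-t/rise)`` on ``t in [0, 5*decay)``.  The
    defaults approximate nuclear-localized GCaMP6s.
    """
    if dt_s <= 0:
        raise ConfigurationError("dt_s must be positive")
    if not (decay_s > rise_s > 0):
        raise ConfigurationError("require decay_s > rise_s > 0")
    t = np.arange(0.0, 5.0 * decay_s, dt_s)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ConfigurationError("degenerate kernel (no positive lobe)")
    return Kernel(samples=k / peak, dt_s=float(dt_s))


def convolve_causal(series: np.ndarray, kernel: Kernel, dt_s: float | None = None) -> np.ndarray:
    """Length-preserving causal convolution of ``series`` with ``kernel``.

    The output at frame ``t`` depends only on inputs at frames ``<= t``.
    If ``dt_s`` is given it must match the kernel's sampling step.
    """
    if dt_s is not None and not np.isclose(dt_s, kernel.dt_s, rtol=1e-6, atol=0):
        raise ConfigurationError(
            f"sampling step mismatch: series dt {dt_s} vs kernel dt {kernel.dt_s}; resample first"
        )
    x = np.asarray(series, dtype=float)
    full = _convolve(x, kernel.samples, mode="full", method="auto")
    return full[: x.size]
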
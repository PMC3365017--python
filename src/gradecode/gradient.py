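"""Sucrose-gradient geometry, A260 traces, and ribosome-number calibration.

A linear sucrose gradient separates mRNAs by the number of ribosomes they
carry: the monosome (80S) peak sediments least, and each additional ribosome
pushes a transcript deeper.  Fractions are collected from the top and the
A260 absorbance is recorded continuously, so the polysome peaks appear as
local maxima in elution time.  Successive peaks compress as ribosome number
grows, which motivates the calibration model

    k = alpha + beta * ln(t)

relating ribosome count ``k`` to the elution time ``t`` of its A260 peak.
The fitted map converts any elution time (for example, a fraction midpoint)
into a continuous average ribosome number; values below one are meaningful
near the top of the gradient (sub-monosomal material) and are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "GradientGeometry",
    "A260Trace",
    "RibosomeCalibration",
    "find_peaks",
    "fit_ribosome_calibration",
    "time_to_ribosomes",
    "fraction_midpoint_times",
]


@dataclass(frozen=True)
class GradientGeometry:
    """Fraction boundaries of a collected gradient, in elution seconds.

    Fractions are numbered 1-based from the top of the gradient (lightest
    material).  ``boundaries`` has length ``n_fractions + 1`` and must be
    strictly increasing with ``boundaries[0] >= 0``.
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("boundaries must be a 1-d array of length >= 2")
        if b[0] < 0:
            raise ValueError("boundaries[0] must be >= 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_fractions(self) -> int:
        return self.boundaries.size - 1

    @classmethod
    def equal_fractions(cls, n_fractions: int, total_time: float) -> "GradientGeometry":
        """Equally spaced fractions over ``[0, total_time]`` seconds."""
        if n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if total_time <= 0:
            raise ValueError("total_time must be positive")
        return cls(np.linspace(0.0, float(total_time), n_fractions + 1))

    def midpoints(self) -> np.ndarray:
        return fraction_midpoint_times(self)


@dataclass(frozen=True)
class A260Trace:
    """Uniformly sampled absorbance-at-260nm trace (arbitrary units)."""

    times: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or t.size != a.size or t.size == 0:
            raise ValueError("times and absorbance must be equal-length 1-d arrays")
        dt = np.diff(t)
        if t.size > 1:
            if not np.all(dt > 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must have a constant step")
        if np.any(a < 0):
            raise ValueError("absorbance must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass(frozen=True)
class RibosomeCalibration:
    """Least-squares map k = alpha + beta*ln(t) from elution time to ribosome count."""

    alpha: float
    beta: float
    peak_times: np.ndarray = field(default_factory=lambda: np.array([]))
    first_count: int = 1
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive (deeper in gradient => more ribosomes)")
        object.__setattr__(self, "peak_times", np.asarray(self.peak_times, dtype=float))

    def __call__(self, t) -> np.ndarray:
        return time_to_ribosomes(self, t)

    def time_at(self, k) -> np.ndarray:
        """Inverse map: elution time at which the fit predicts ``k`` ribosomes."""
        return np.exp((np.asarray(k, dtype=float) - self.alpha) / self.beta)


def find_peaks(trace: A260Trace, min_prominence: float = 0.05,
               search_window: tuple[float, float] | None = None) -> np.ndarray:
    """Locate A260 peak times by topographic prominence.

    A local maximum qualifies when its height above the higher of its two
    flanking minima is at least ``min_prominence`` times the full range of the
    trace.  ``search_window`` restricts the result to a time interval; the
    caller typically starts it at the 80S (monosome) region so that 40S/60S
    subunit peaks are excluded.  Returns peak times sorted ascending; an empty
    array is a valid result.
    """
    if not 0 < min_prominence < 1:
        raise ValueError("min_prominence must lie in (0, 1)")
    y = trace.absorbance
    rng = float(y.max() - y.min())
    if rng == 0.0:
        return np.array([])
    idx, _ = signal.find_peaks(y, prominence=min_prominence * rng)
    times = trace.times[idx]
    if search_window is not None:
        lo, hi = search_window
        if lo < trace.times[0] or hi > trace.times[-1] or lo >= hi:
            raise ValueError("search_window must be a nonempty interval within the trace")
        times = times[(times >= lo) & (times <= hi)]
    return times


def fit_ribosome_calibration(peak_times, first_count: int = 1) -> RibosomeCalibration:
    """Fit k_i = alpha + beta*ln(t_i) with consecutive counts from ``first_count``."""
    t = np.asarray(peak_times, dtype=float)
    if t.size < 2:
        raise ValueError("at least two peaks are required to calibrate")
    if np.any(t <= 0):
        raise ValueError("peak times must be positive")
    if not np.all(np.diff(t) > 0):
        raise ValueError("peak times must be strictly increasing")
    k = np.arange(first_count, first_count + t.size, dtype=float)
    res = stats.linregress(np.log(t), k)
    pred = res.intercept + res.slope * np.log(t)
    rms = float(np.sqrt(np.mean((pred - k) ** 2)))
    return RibosomeCalibration(alpha=float(res.intercept), beta=float(res.slope),
                               peak_times=t, first_count=first_count, residual_rms=rms)


def time_to_ribosomes(calib: RibosomeCalibration, t) -> np.ndarray:
    """Continuous average ribosome number at elution time ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("elution time must be positive")
    out = calib.alpha + calib.beta * np.log(t)
    return out if out.ndim else float(out)


def fraction_midpoint_times(geom: GradientGeometry) -> np.ndarray:
    """Midpoint elution time of each fraction, 1-based order from the top."""
    b = geom.boundaries
    return 0.5 * (b[:-1] + b[1:])
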
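"""Detrending and Lomb-Scargle periodograms of unevenly sampled RT series.

Because targets (and hence correct-response RTs) occur at irregular times,
spectral content is estimated with the classical normalized Lomb-Scargle
periodogram rather than an FFT. For angular frequency w = 2*pi*f and the
phase origin tau defined by tan(2*w*tau) = sum sin(2*w*t_j) / sum
cos(2*w*t_j),

    P(f) = 1/(2*s2) * ( [sum x_j cos w(t_j - tau)]^2 / sum cos^2 w(t_j - tau)
                      + [sum x_j sin w(t_j - tau)]^2 / sum sin^2 w(t_j - tau) )

with s2 the sample variance of the (mean-centered) values, so white noise
has expected power near 1 at every frequency. ``lomb_scargle_oracle``
recomputes the same quantity by an explicit least-squares sinusoid fit and
exists as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RTSeries:
    """An unevenly sampled series of correct-response RTs."""

    participant_id: str
    times: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # milliseconds

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class Periodogram:
    participant_id: str
    frequencies: np.ndarray  # Hz, ascending
    power: np.ndarray  # normalized, dimensionless
    f_min: float
    f_max: float
    oversampling: float


def detrend(series: RTSeries) -> RTSeries:
    """Remove the ordinary-least-squares line in time; times unchanged."""
    if series.n < 3:
        raise ValueError("need at least 3 points to detrend")
    coef = np.polyfit(series.times, series.values, 1)
    resid = series.values - np.polyval(coef, series.times)
    return RTSeries(series.participant_id, series.times.copy(), resid)


def frequency_grid(series: RTSeries, oversampling: float = 1.0) -> np.ndarray:
    """Evaluation frequencies from 1/T to the pseudo-Nyquist n/(2T).

    T is the observed span, the step is 1/(oversampling * T) — the standard
    from/to/ofac construction for uneven sampling.
    """
    T = series.span
    if T <= 0:
        raise ValueError("time span must be positive")
    if oversampling <= 0:
        raise ValueError("oversampling must be positive")
    start = 1.0 / T
    stop = series.n / (2.0 * T)
    step = 1.0 / (oversampling * T)
    k = int(np.floor((stop - start) / step + 1e-9))
    return start + step * np.arange(k + 1)


def _ls_power(times: np.ndarray, values: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    x = values - values.mean()
    s2 = float(np.var(values, ddof=1))
    if s2 <= 0:
        raise ValueError("zero-variance series: normalized power undefined")
    w = 2.0 * np.pi * np.asarray(freqs, dtype=float)[:, None]
    wt = w * times[None, :]
    two_wt = 2.0 * wt
    tau_phase = 0.5 * np.arctan2(np.sin(two_wt).sum(axis=1), np.cos(two_wt).sum(axis=1))
    theta = wt - tau_phase[:, None]
    c = np.cos(theta)
    s = np.sin(theta)
    xc = c @ x
    xs = s @ x
    cc = (c * c).sum(axis=1)
    ss = (s * s).sum(axis=1)
    return (xc**2 / cc + xs**2 / ss) / (2.0 * s2)


def lomb_scargle(
    series: RTSeries,
    frequencies: np.ndarray | None = None,
    oversampling: float = 1.0,
    detrend_first: bool = True,
    normalize: bool = True,
) -> Periodogram:
    """Normalized Lomb-Scargle periodogram of an RT series.

    By default the series is linearly detrended first and power is
    variance-normalized; ``normalize=False`` returns the raw least-squares
    power (half the explained sum of squares at each frequency).
    """
    work = detrend(series) if detrend_first else series
    if frequencies is None:
        frequencies = frequency_grid(work, oversampling)
    frequencies = np.asarray(frequencies, dtype=float)
    power = _ls_power(work.times, work.values, frequencies)
    if not normalize:
        power = power * float(np.var(work.values, ddof=1))
    return Periodogram(
        participant_id=series.participant_id,
        frequencies=frequencies,
        power=power,
        f_min=float(frequencies[0]),
        f_max=float(frequencies[-1]),
        oversampling=float(oversampling),
    )


def lomb_scargle_oracle(series: RTSeries, f: float) -> float:
    """Normalized LS power at one frequency via an explicit sinusoid fit.

    Fits a*cos(2*pi*f*t) + b*sin(2*pi*f*t) to the mean-centered values by
    least squares and returns (explained sum of squares) / (2 * sample
    variance) — algebraically identical to the tau-rotated form but computed
    through a different route, so it serves as an independent oracle.
    """
    x = series.values - series.values.mean()
    s2 = float(np.var(series.values, ddof=1))
    if s2 <= 0:
        raise ValueError("zero-variance series: normalized power undefined")
    arg = 2.0 * np.pi * f * series.times
    A = np.column_stack([np.cos(arg), np.sin(arg)])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    fitted = A @ coef
    ess = float(fitted @ fitted)
    return ess / (2.0 * s2)


def series_from_session(rt_series, participant_id: str) -> RTSeries:
    """Build an :class:`RTSeries` from a classified session's hit table."""
    return RTSeries(
        participant_id=participant_id,
        times=rt_series["onset_time_s"].to_numpy(dtype=float),
        values=rt_series["rt_ms"].to_numpy(dtype=float),
    )
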
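"""Time-series cleaning: frame-wise displacement, scrubbing, detrend,
band-pass and end trimming.

The cleaning order is fixed as truncate -> scrub -> detrend -> bandpass
-> trim ends.  Scrubbed frames are dropped (not interpolated); the
returned censor mask lets downstream correlation propagate the censoring
as pair-wise deletion if it works on the full-length series instead.
"""

from __future__ import annotations

import numpy as np

from .core import CensorMask, InvalidConfigError, MotionTrace, NeurofluidError, TimeSeries

__all__ = [
    "compute_fd",
    "scrub",
    "bandpass_ideal",
    "detrend_poly",
    "preprocess",
    "percent_signal_change",
    "clean_series",
]

#: Default sphere radii (mm) for converting rotations to arc length.
FD_RADIUS_HUMAN = 50.0
FD_RADIUS_MOUSE = 5.0


def compute_fd(motion: MotionTrace, sphere_radius: float = FD_RADIUS_HUMAN) -> np.ndarray:
    """Frame-wise displacement in mm (backward-difference convention).

    FD(0) = 0; FD(i) = sum of absolute backward differences of the three
    translations plus the three rotations converted to arc length on a
    sphere of ``sphere_radius`` (50 mm human, 5 mm mouse by default).
    Adding a constant offset to any parameter leaves FD unchanged.
    """
    if motion.n < 2:
        raise InvalidConfigError("need at least 2 frames to compute FD")
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1) * sphere_radius
    return np.concatenate([[0.0], dt + dr])


def scrub(
    ts: TimeSeries, fd: np.ndarray, threshold: float = 0.35
) -> tuple[TimeSeries, CensorMask]:
    """Drop frames whose FD strictly exceeds ``threshold`` (mm).

    The 0.35 mm default and the strict ("larger than") boundary follow
    the resting-state protocol this package reproduces; a frame at
    exactly the threshold is kept.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size != ts.n:
        raise InvalidConfigError("FD length must match the series")
    keep = fd <= threshold
    if not keep.any() or keep.sum() < 2:
        raise NeurofluidError("scrubbing censored (nearly) all frames; series unusable")
    mask = CensorMask(keep=keep, threshold=threshold)
    return ts.with_values(ts.values[keep]), mask


def detrend_poly(values: np.ndarray, order: int = 2) -> np.ndarray:
    """Remove a least-squares polynomial trend of the given order."""
    x = np.arange(values.size, dtype=float)
    coef = np.polynomial.polynomial.polyfit(x, values, deg=order)
    return values - np.polynomial.polynomial.polyval(x, coef)


def bandpass_ideal(values: np.ndarray, dt: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase ideal (boxcar) frequency-domain band-pass.

    Bins with ``low <= f <= high`` are kept, everything else (including
    DC) is zeroed.  Deterministic and exactly additive over disjoint
    bands, which the pulsation analysis relies on.
    """
    lo, hi = band
    nyq = 0.5 / dt
    if not (0 <= lo < hi):
        raise InvalidConfigError("band must satisfy 0 <= low < high")
    if lo >= nyq:
        raise InvalidConfigError(f"band {band} lies entirely above Nyquist {nyq:.4g} Hz")
    spec = np.fft.rfft(values)
    freqs = np.fft.rfftfreq(values.size, d=dt)
    mask = (freqs >= lo) & (freqs <= hi)
    return np.fft.irfft(spec * mask, n=values.size)


def preprocess(
    ts: TimeSeries,
    detrend_order: int = 2,
    band: tuple[float, float] = (0.01, 0.1),
    trim: tuple[int, int] = (5, 5),
    keep_first: int | None = None,
) -> TimeSeries:
    """Second-order detrend, 0.01-0.1 Hz band-pass, end trimming.

    ``keep_first`` truncates the series to its initial frames before
    anything else (late frames carry more motion); ``trim`` then removes
    ``(head, tail)`` frames after filtering to shed filter edge
    artifacts.  Defaults match the human resting-state protocol (first
    150 scans analysed, 5 scans trimmed from each end); the mouse
    protocol uses trim=(250, 250).
    """
    v = ts.values
    if keep_first is not None:
        if keep_first < 2:
            raise InvalidConfigError("keep_first must be >= 2")
        v = v[:keep_first]
    head, tail = trim
    if v.size < head + tail + 2:
        raise InvalidConfigError("series shorter than 2*trim + 2 frames")
    lo, hi = band
    if not (0 < lo < hi < 0.5 / ts.dt):
        raise InvalidConfigError("band must lie inside (0, Nyquist)")
    v = detrend_poly(v, order=detrend_order)
    v = bandpass_ideal(v, ts.dt, band)
    if tail:
        v = v[head : v.size - tail]
    else:
        v = v[head:]
    return TimeSeries(v, ts.dt, t0=ts.t0 + head * ts.dt)


def percent_signal_change(ts: TimeSeries, baseline: int | str = "mean") -> TimeSeries:
    """Convert to percent signal change: 100*(v - b)/b.

    ``baseline`` is either the number of initial frames whose mean
    defines the baseline, or ``"mean"`` for the whole-series mean.
    """
    if baseline == "mean":
        b = ts.values.mean()
    else:
        k = int(baseline)
        if k < 1 or k > ts.n:
            raise InvalidConfigError("baseline frame count out of range")
        b = ts.values[:k].mean()
    if b == 0:
        raise NeurofluidError("baseline mean is zero; percent change undefined")
    return ts.with_values(100.0 * (ts.values - b) / b)


def clean_series(
    ts: TimeSeries,
    motion: MotionTrace | None = None,
    fd_threshold: float = 0.35,
    sphere_radius: float = FD_RADIUS_HUMAN,
    detrend_order: int = 2,
    band: tuple[float, float] = (0.01, 0.1),
    trim: tuple[int, int] = (5, 5),
    keep_first: int | None = None,
) -> tuple[TimeSeries, CensorMask | None]:
    """Full cleaning pipeline: truncate -> scrub -> detrend -> bandpass -> trim."""
    mask = None
    if keep_first is not None:
        ts = ts.with_values(ts.values[:keep_first])
    if motion is not None:
        if motion.n < ts.n:
            raise InvalidConfigError("motion trace shorter than the series")
        fd = compute_fd(
            MotionTrace(motion.translations[: ts.n], motion.rotations[: ts.n]),
            sphere_radius,
        )
        ts, mask = scrub(ts, fd, fd_threshold)
    ts = preprocess(ts, detrend_order=detrend_order, band=band, trim=trim)
    return ts, mask
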
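"""Arterial pulsation power from fast MRI time series.

The flow-related enhancement signal of a fast gradient-echo acquisition
follows the arterial pulse.  Each voxel/ROI series is normalised by its
temporal mean, Fourier transformed, and the variance in a 2 Hz-wide
band around the detected cardiac peak is taken as the arterial
pulsation power.  At TR = 70 ms the Nyquist limit is ~7.14 Hz, so the
first cardiac harmonic (~9.16 Hz for a heart rate of 4.58 Hz) folds to
~5.13 Hz and can fall inside the cardiac band — the alias is computed
explicitly and reported either way.

The band filter is an ideal zero-phase frequency-domain mask, so band
variances are exactly additive over disjoint bands (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DetectionError, InvalidConfigError, NeurofluidError, TimeSeries

__all__ = [
    "Spectrum",
    "PulsationResult",
    "normalize_and_spectrum",
    "alias_fold",
    "detect_cardiac_peak",
    "pulsation_power",
    "temporal_sd_map",
    "CARDIAC_SEARCH_BAND",
]

#: Physiological heart-rate search band, Hz (150-350 beats/min).
CARDIAC_SEARCH_BAND = (2.5, 5.8)


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum; sum(power) equals the temporal variance."""

    freqs: np.ndarray
    power: np.ndarray
    dt: float

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    def band_power(self, lo: float, hi: float) -> float:
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        return float(self.power[sel].sum())


@dataclass(frozen=True)
class PulsationResult:
    cardiac_freq: float
    band: tuple[float, float]
    power: float  # variance of the band-filtered mean-normalized signal
    temporal_sd: float
    aliased_harmonics: tuple[float, ...]
    harmonic_in_band: bool


def _mean_normalize(values: np.ndarray) -> np.ndarray:
    m = values.mean()
    if m <= 0:
        raise NeurofluidError("temporal mean must be positive for mean normalization")
    return values / m - 1.0


def normalize_and_spectrum(ts: TimeSeries) -> Spectrum:
    """Mean-normalise and return the one-sided power spectrum.

    Scaling is chosen so that the spectrum sums to the (population)
    temporal variance of the normalised signal, making band power the
    variance of the ideally band-filtered signal.
    """
    x = _mean_normalize(ts.values)
    n = x.size
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    if n % 2 == 0:
        power[1:-1] *= 2.0  # Nyquist bin is unpaired
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=ts.dt)
    return Spectrum(freqs=freqs, power=power, dt=ts.dt)


def alias_fold(f: float, dt: float) -> float:
    """Fold a frequency into [0, Nyquist]: ``|f - round(f*dt)/dt|``."""
    if f < 0:
        raise InvalidConfigError("frequency must be nonnegative")
    return abs(f - round(f * dt) / dt)


def detect_cardiac_peak(
    spec: Spectrum,
    search_band: tuple[float, float] = CARDIAC_SEARCH_BAND,
    prior: float | None = None,
) -> float:
    """Frequency of maximum power inside the physiological search band.

    A recorded heart-rate ``prior`` (e.g. from pulse oximetry) narrows
    the search to prior +/- 1 Hz.
    """
    lo, hi = search_band
    if prior is not None:
        lo, hi = max(lo, prior - 1.0), min(hi, prior + 1.0)
    if lo >= hi or hi > spec.nyquist + 1e-12:
        raise InvalidConfigError("search band outside the spectrum range")
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not sel.any():
        raise DetectionError("no spectral bins inside the search band")
    p = spec.power[sel]
    if np.allclose(p, p[0]):
        raise DetectionError("flat spectrum in the cardiac search band")
    return float(spec.freqs[sel][np.argmax(p)])


def pulsation_power(
    ts: TimeSeries,
    cardiac: float,
    width: float = 2.0,
    width_is_half: bool = False,
    harmonic: float | None = None,
) -> PulsationResult:
    """Variance of the mean-normalised signal in a band around the
    cardiac peak.

    ``width`` is the *total* band width (2 Hz default, i.e. cardiac
    +/- 1 Hz); set ``width_is_half`` to interpret it as the half width.
    The band is clipped at Nyquist.  The aliased first harmonic
    (``harmonic`` defaults to 2x the cardiac frequency) is not widened
    into the band; it contributes only when its folded frequency
    naturally falls inside, and is reported either way.
    """
    half = width if width_is_half else width / 2.0
    lo, hi = cardiac - half, cardiac + half
    spec = normalize_and_spectrum(ts)
    lo = max(lo, 0.0)
    hi = min(hi, spec.nyquist)
    if lo >= hi:
        raise InvalidConfigError("cardiac band empty after clipping at Nyquist")
    h = 2.0 * cardiac if harmonic is None else harmonic
    h_alias = alias_fold(h, ts.dt)
    power = spec.band_power(lo, hi)
    x = _mean_normalize(ts.values)
    return PulsationResult(
        cardiac_freq=cardiac,
        band=(lo, hi),
        power=power,
        temporal_sd=float(x.std(ddof=1)),
        aliased_harmonics=(h_alias,),
        harmonic_in_band=bool(lo <= h_alias <= hi),
    )


def temporal_sd_map(volume4d: np.ndarray) -> np.ndarray:
    """Per-voxel SD of the mean-normalised time course.

    Maps the amplitude of signal fluctuation; invariant under global
    intensity scaling.  Voxels with nonpositive mean are NaN.
    """
    vol = np.asarray(volume4d, dtype=float)
    if vol.ndim != 4 or vol.shape[-1] < 2:
        raise InvalidConfigError("need a 4-D volume with >= 2 frames")
    m = vol.mean(axis=-1)
    out = np.full(vol.shape[:3], np.nan)
    ok = m > 0
    norm = vol[ok] / m[ok, None]
    out[ok] = norm.std(axis=-1, ddof=1)
    return out
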
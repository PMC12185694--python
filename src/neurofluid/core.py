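"""Core containers shared across the analysis stages.

A :class:`TimeSeries` is the unit object of the coupling and pulsation
analyses: a uniformly sampled 1-D signal with its sampling interval.
Values may be raw scanner units (a.u.) or percent of baseline; the
container is agnostic.  A :class:`MotionTrace` carries the six
rigid-body realignment parameters used only to compute frame-wise
displacement (no motion *correction* happens here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeurofluidError",
    "InvalidConfigError",
    "NoEnhancementError",
    "DetectionError",
    "FitError",
    "TimeSeries",
    "MotionTrace",
    "CensorMask",
]


class NeurofluidError(ValueError):
    """Base class for domain errors raised by this package."""


class InvalidConfigError(NeurofluidError):
    """A configuration value violates its invariants (e.g. band beyond Nyquist)."""


class NoEnhancementError(NeurofluidError):
    """A tracer curve shows no positive signal change; kinetics are undefined."""


class DetectionError(NeurofluidError):
    """A spectral peak search found nothing to detect."""


class FitError(NeurofluidError):
    """A nonlinear fit failed to converge after restarts."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        Samples, one per frame.
    dt : float
        Sampling interval in seconds (or minutes for tracer curves;
        the consumer decides the unit and must be consistent).
    t0 : float
        Time of the first sample, same unit as ``dt``.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise InvalidConfigError("TimeSeries needs a 1-D array of length >= 2")
        if not self.dt > 0:
            raise InvalidConfigError("TimeSeries dt must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    def with_values(self, values: np.ndarray, t0: float | None = None) -> "TimeSeries":
        return TimeSeries(values, self.dt, self.t0 if t0 is None else t0)


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body motion parameters per frame.

    ``translations`` is an ``(n, 3)`` array in mm, ``rotations`` an
    ``(n, 3)`` array in radians (pitch, roll, yaw).
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.translations, dtype=float))
        r = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if t.shape != r.shape or t.shape[1] != 3:
            raise InvalidConfigError("motion parameters must be two (n, 3) arrays")
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)

    @property
    def n(self) -> int:
        return self.translations.shape[0]


@dataclass(frozen=True)
class CensorMask:
    """Boolean keep/drop decision per frame, with the threshold that produced it."""

    keep: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "keep", np.asarray(self.keep, dtype=bool))

    @property
    def n_dropped(self) -> int:
        return int((~self.keep).sum())
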
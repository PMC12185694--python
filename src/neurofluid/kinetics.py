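"""Tracer-kinetic parameters of dynamic Gd-enhanced signals.

From a fractional-signal-change curve the module extracts: area under
the curve (AUC, optionally normalised by a whole-brain AUC), contrast
arrival time (first post-injection frame exceeding 20 % of the maximum
signal change), time-to-peak, effective time-to-peak (time-to-peak
minus arrival), influx rate (least-squares rising slope between arrival
and peak) and the efflux decay time from a 3-parameter exponential fit
``A*exp(-t/Decay) + C`` on the post-peak tail, with the clock starting
at the peak frame.

Times are reported at frame resolution (3.33 min per volume in the
dynamic protocol emulated here); no sub-frame interpolation is done
because the arrival definition is a threshold crossing on sampled
frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import FitError, InvalidConfigError, NeurofluidError, NoEnhancementError, TimeSeries

__all__ = [
    "GdCurve",
    "KineticParams",
    "normalize_gd",
    "auc",
    "arrival_time",
    "time_to_peak",
    "influx_rate",
    "decay_fit",
    "extract_kinetics",
    "kinetic_maps",
]


@dataclass(frozen=True)
class GdCurve:
    """A tracer curve in fractional signal change (0.2 = +20 %).

    ``injection_index`` is the first post-injection frame; frames from
    it onward enter the AUC and the kinetic definitions.
    """

    values: np.ndarray
    frame_dt: float  # minutes per frame
    baseline_frames: int = 3
    injection_index: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.baseline_frames < 1:
            raise InvalidConfigError("baseline_frames must be >= 1")
        if self.injection_index is None:
            object.__setattr__(self, "injection_index", self.baseline_frames)
        if self.injection_index < self.baseline_frames:
            raise InvalidConfigError("injection_index must be >= baseline_frames")
        if self.injection_index >= v.size:
            raise InvalidConfigError("injection_index beyond the end of the curve")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Frame times in minutes from the start of the scan."""
        return self.frame_dt * np.arange(self.n)

    @property
    def post(self) -> np.ndarray:
        return self.values[self.injection_index :]


@dataclass(frozen=True)
class DecayFit:
    A: float
    decay: float  # minutes
    C: float
    rss: float
    converged: bool = True


@dataclass(frozen=True)
class KineticParams:
    """The six kinetic quantities of one curve (times in minutes)."""

    auc: float
    arrival_time: float
    ttp: float
    effective_ttp: float
    influx_rate: float  # fractional signal change per minute
    A: float
    decay: float
    C: float
    fit_rss: float


def normalize_gd(raw: TimeSeries | np.ndarray, baseline_frames: int = 3,
                 frame_dt: float | None = None,
                 injection_index: int | None = None) -> GdCurve:
    """Express a raw intensity curve as signal change relative to the
    mean of the first ``baseline_frames`` frames: ``v/b - 1``."""
    if isinstance(raw, TimeSeries):
        values, dt = raw.values, raw.dt
    else:
        values = np.asarray(raw, dtype=float)
        if frame_dt is None:
            raise InvalidConfigError("frame_dt required for a bare array")
        dt = frame_dt
    if baseline_frames < 1 or baseline_frames > values.size:
        raise InvalidConfigError("baseline_frames out of range")
    b = values[:baseline_frames].mean()
    if b <= 0:
        raise NeurofluidError("nonpositive baseline mean; normalization undefined")
    return GdCurve(
        values=values / b - 1.0,
        frame_dt=dt,
        baseline_frames=baseline_frames,
        injection_index=injection_index,
    )


def auc(curve: GdCurve, whole_brain_auc: float | None = None) -> float:
    """Sum of signal change over post-injection frames; divided by
    ``whole_brain_auc`` when given (accounts for how much contrast
    actually reached the brain in each animal)."""
    total = float(curve.post.sum())
    if whole_brain_auc is not None:
        if whole_brain_auc == 0:
            raise NeurofluidError("whole-brain AUC is zero; cannot normalize")
        total /= whole_brain_auc
    return total


def _max_signal_change(curve: GdCurve) -> float:
    m = float(curve.post.max()) if curve.post.size else 0.0
    if m <= 0:
        raise NoEnhancementError("no positive signal change after injection")
    return m


def arrival_time(curve: GdCurve) -> float:
    """Time (minutes) of the first post-injection frame whose value
    strictly exceeds 20 % of the maximum signal change."""
    m = _max_signal_change(curve)
    idx = np.nonzero(curve.post > 0.2 * m)[0]
    if idx.size == 0:  # unreachable when m > 0, kept as a guard
        raise NoEnhancementError("no frame exceeds the 20% arrival threshold")
    return float((curve.injection_index + idx[0]) * curve.frame_dt)


def time_to_peak(curve: GdCurve) -> float:
    """Time (minutes) of the global post-injection maximum (earliest
    frame on a plateau of equal maxima)."""
    _max_signal_change(curve)
    i = int(np.argmax(curve.post))  # argmax returns the first maximum
    return float((curve.injection_index + i) * curve.frame_dt)


def influx_rate(curve: GdCurve, arrival: float, ttp: float,
                two_point: bool = False) -> float:
    """Rising slope (signal change per minute) between arrival and peak.

    Least-squares slope over all frames with ``arrival <= t <= ttp``
    (inclusive); ``two_point=True`` uses only the two endpoints.
    """
    if not arrival < ttp:
        raise InvalidConfigError("need arrival < time-to-peak")
    t = curve.times
    sel = (t >= arrival - 1e-9) & (t <= ttp + 1e-9)
    if sel.sum() < 2:
        raise NeurofluidError("fewer than 2 frames between arrival and peak")
    tt, vv = t[sel], curve.values[sel]
    if two_point:
        return float((vv[-1] - vv[0]) / (tt[-1] - tt[0]))
    return float(np.polyfit(tt, vv, 1)[0])


def _decay_model(t, A, decay, C):
    return A * np.exp(-t / decay) + C


def decay_fit(curve: GdCurve, ttp: float, max_restarts: int = 4) -> DecayFit:
    """3-parameter exponential fit ``A*exp(-(t - t_peak)/Decay) + C`` on
    the post-peak frames (peak included, clock starting at the peak).

    Initialisation: C0 = last value, A0 = peak - last value, Decay0 =
    time for the curve to fall halfway from peak to last value (fallback
    half the post-peak span).  Decay is constrained positive.  On
    non-convergence the fit restarts from perturbed initial values and
    finally raises :class:`FitError` rather than returning silent NaNs.
    """
    t = curve.times
    peak_idx = int(round(ttp / curve.frame_dt))
    if not 0 <= peak_idx < curve.n:
        raise InvalidConfigError("ttp outside the curve")
    if curve.n - 1 - peak_idx < 4:
        raise InvalidConfigError("need at least 4 frames after the peak")
    tt = t[peak_idx:] - t[peak_idx]
    vv = curve.values[peak_idx:]
    c0 = vv[-1]
    a0 = vv[0] - vv[-1]
    half = vv[-1] + 0.5 * (vv[0] - vv[-1])
    below = np.nonzero(vv <= half)[0]
    decay0 = tt[below[0]] if below.size and tt[below[0]] > 0 else 0.5 * tt[-1]
    if a0 == 0:
        a0 = max(abs(vv).max(), 1e-6)
    p0 = (a0, max(decay0, curve.frame_dt), c0)
    last_err: Exception | None = None
    for k in range(max_restarts + 1):
        factor = 1.0 if k == 0 else (0.5, 2.0, 4.0, 0.25)[k - 1]
        try:
            popt, _ = curve_fit(
                _decay_model,
                tt,
                vv,
                p0=(p0[0], p0[1] * factor, p0[2]),
                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=1e-10,
                ftol=1e-10,
                maxfev=20000,
            )
            rss = float(np.sum((vv - _decay_model(tt, *popt)) ** 2))
            return DecayFit(A=float(popt[0]), decay=float(popt[1]), C=float(popt[2]),
                            rss=rss)
        except RuntimeError as err:  # pragma: no cover - rare
            last_err = err
    raise FitError(f"decay fit did not converge after restarts: {last_err}")


def extract_kinetics(curve: GdCurve, whole_brain_auc: float | None = None) -> KineticParams:
    """All kinetic parameters of one curve."""
    arr = arrival_time(curve)
    ttp = time_to_peak(curve)
    rate = influx_rate(curve, arr, ttp) if ttp > arr else np.nan
    fit = decay_fit(curve, ttp)
    return KineticParams(
        auc=auc(curve, whole_brain_auc),
        arrival_time=arr,
        ttp=ttp,
        effective_ttp=ttp - arr,
        influx_rate=rate,
        A=fit.A,
        decay=fit.decay,
        C=fit.C,
        fit_rss=fit.rss,
    )


def kinetic_maps(
    volume4d: np.ndarray,
    brain_mask: np.ndarray,
    baseline_frames: int = 3,
    injection_index: int | None = None,
    frame_dt: float = 3.33,
) -> dict[str, np.ndarray]:
    """Per-voxel kinetic maps over a brain mask.

    Each masked voxel's time course is baseline-normalised and run
    through the full kinetic extraction.  The whole-brain AUC (mean
    voxel AUC over the mask) normalises the AUC map.  Voxels where
    extraction fails (no enhancement, fit failure) are flagged in the
    ``qc`` map and left NaN in the parameter maps — never interpolated.
    """
    vol = np.asarray(volume4d, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if vol.ndim != 4 or mask.shape != vol.shape[:3]:
        raise InvalidConfigError("need a 4-D volume and a matching 3-D mask")
    names = ["auc", "arrival_time", "ttp", "effective_ttp", "influx_rate",
             "A", "decay", "C", "fit_rss"]
    maps = {name: np.full(vol.shape[:3], np.nan) for name in names}
    maps["qc"] = np.zeros(vol.shape[:3], dtype=bool)
    coords = np.argwhere(mask)
    curves: dict[tuple, GdCurve] = {}
    aucs = []
    for c in coords:
        raw = vol[tuple(c)]
        try:
            curve = normalize_gd(raw, baseline_frames, frame_dt, injection_index)
            curves[tuple(c)] = curve
            aucs.append(auc(curve))
        except NeurofluidError:
            maps["qc"][tuple(c)] = True
    wb_auc = float(np.mean(aucs)) if aucs else None
    for c, curve in curves.items():
        try:
            kp = extract_kinetics(curve, whole_brain_auc=wb_auc)
        except NeurofluidError:
            maps["qc"][c] = True
            continue
        for name in names:
            maps[name][c] = getattr(kp, name if name != "fit_rss" else "fit_rss")
    return maps
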
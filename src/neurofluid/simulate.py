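"""Synthetic data generators with known ground truth.

Every downstream stage of the package (coupling, tracer kinetics,
pulsation, CBF) is exercised on signals produced here.  The generators
emulate the statistical structure of the real acquisitions:

* low-frequency (0.01-0.1 Hz) band-limited BOLD oscillations with a
  sign-inverted, lagged CSF inflow counterpart,
* intracisternal Gd time-intensity curves with a flat baseline, a
  ramped influx, a peak and an exponential efflux tail,
* fast gradient-echo arterial inflow signals with cardiac (~4.58 Hz),
  respiratory and vasomotion components sampled at 70 ms so the first
  cardiac harmonic aliases naturally,
* pCASL label/control pairs exactly consistent with the CBF
  quantification formula, so quantification is a round trip.

Each generator returns a :class:`GroundTruth` record of every true
parameter, keyed so that recovery can be scored by the tests.

Determinism: one global integer seed; each generator draws from its own
substream derived from ``(stream offset, seed, unit index)`` so streams
are independent and reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import InvalidConfigError, MotionTrace, TimeSeries
from .asl import ASLParameters, ASLSeries, CBF_UNIT_SCALE

__all__ = [
    "SimConfig",
    "GdKineticsConfig",
    "ASLSimConfig",
    "GroundTruth",
    "band_limited_noise",
    "gen_coupled_bold_csf",
    "gen_coupled_cohort",
    "gen_motion_trace",
    "gen_gd_curve",
    "gen_pulsatile_signal",
    "gen_asl_dataset",
    "infusion_duration",
    "scan_duration",
]

# Fixed substream offsets (one per generator family).
_STREAM_COUPLED = 11
_STREAM_MOTION = 23
_STREAM_GD = 37
_STREAM_PULSE = 53
_STREAM_ASL = 71


def _rng(seed: int, stream: int, unit: int = 0) -> np.random.Generator:
    return np.random.default_rng([stream, int(seed), int(unit)])


@dataclass(frozen=True)
class GdKineticsConfig:
    """True parameters of a synthetic Gd time-intensity curve.

    Times are in frames on a ``frame_dt``-minute grid (3.33 min per
    volume for the dynamic 3D T1-weighted protocol).  The curve is flat
    at zero through the baseline, ramps from ``ramp_start_frame`` to the
    peak at ``ttp_frame``, then decays as ``A*exp(-t/decay) + C`` with
    the clock starting at the peak.  Peak signal change is ``A + C``
    (fractional units; 0.4 means +40 % over baseline).
    """

    baseline_frames: int = 3
    ramp_start_frame: int = 6
    ttp_frame: int = 12
    A: float = 0.38
    decay: float = 30.0  # minutes
    C: float = 0.02
    frame_dt: float = 3.33  # minutes per volume
    n_frames: int = 40
    noise_sd: float = 0.0  # absolute, fractional-signal-change units
    rise: str = "linear"  # or "sigmoid"

    @property
    def peak_amp(self) -> float:
        return self.A + self.C


@dataclass(frozen=True)
class ASLSimConfig:
    """Ground-truth CBF and tissue T1 for the synthetic pCASL dataset."""

    cbf_true: float = 100.0  # ml/100 g/min
    t1t: float = 1900.0  # ms
    shape: tuple[int, int, int] = (4, 4, 2)
    si_c: float = 1000.0  # a.u.


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions: human-like resting-state fMRI (TR 2.68 s, 150 analysed
    frames, 0.01-0.1 Hz band, lag -1 scan), mouse-like fast pulsation
    imaging (TR 70 ms, 2500 frames, heart rate 4.58 Hz) and the Gd /
    pCASL protocols above."""

    seed: int = 0
    n_subjects: int = 20
    n_frames: int = 150
    dt: float = 2.68  # seconds per frame
    band: tuple[float, float] = (0.01, 0.1)  # Hz
    true_lag: int = -1  # frames; negative = BOLD precedes CSF
    coupling_amp: float = 1.0
    noise_sd: float = 0.3  # relative to the unit-SD BOLD signal
    # pulsation imaging
    cardiac_freq: float = 4.58  # Hz
    resp_freq: float = 1.5  # Hz (90 breaths/min)
    vasomotion_freq: float = 0.05  # Hz
    cardiac_amp: float = 0.05
    harmonic_ratio: float = 0.4  # first-harmonic amplitude / cardiac amplitude
    resp_amp: float = 0.02
    vasomotion_amp: float = 0.01
    pulse_noise_sd: float = 0.0
    pulse_dt: float = 0.07  # seconds
    pulse_n_frames: int = 2500
    kinetics: GdKineticsConfig = field(default_factory=GdKineticsConfig)
    asl: ASLSimConfig = field(default_factory=ASLSimConfig)

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.n_subjects < 1:
            raise InvalidConfigError("counts must be >= 1 (n_frames >= 2)")
        if not self.dt > 0 or not self.pulse_dt > 0:
            raise InvalidConfigError("dt must be > 0")
        lo, hi = self.band
        if not (0 < lo < hi < 0.5 / self.dt):
            raise InvalidConfigError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist "
                f"({0.5 / self.dt:.4g} Hz)"
            )
        if abs(self.true_lag) > 10:
            raise InvalidConfigError("true_lag must be within +/-10 frames")
        if not self.kinetics.decay > 0:
            raise InvalidConfigError("decay must be > 0")
        if self.asl.cbf_true < 0 or not self.asl.t1t > 0:
            raise InvalidConfigError("cbf_true must be >= 0 and t1t > 0")


@dataclass
class GroundTruth:
    """Ledger of the true parameters used by a generator call."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]


def band_limited_noise(
    n: int, dt: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Gaussian process with power confined to ``band``.

    White noise is masked in the frequency domain with an ideal boxcar
    over ``band`` (inclusive bin edges) and transformed back, then
    scaled to unit sample SD.  Exact band control, deterministic.
    """
    lo, hi = band
    if not (0 < lo < hi < 0.5 / dt):
        raise InvalidConfigError("band must lie strictly inside (0, Nyquist)")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise InvalidConfigError("band contains no resolvable frequency bins")
    x = np.fft.irfft(spec * mask, n=n)
    sd = x.std(ddof=1)
    return x / sd


def gen_coupled_bold_csf(
    cfg: SimConfig, subject: int = 0
) -> tuple[TimeSeries, TimeSeries, GroundTruth]:
    """One subject's anticorrelated BOLD / CSF-inflow pair.

    The CSF signal is a sign-inverted copy of the band-limited BOLD
    signal shifted by ``true_lag`` frames (negative lag = BOLD earlier,
    i.e. CSF is a delayed copy), plus white noise of SD ``noise_sd``:

        csf(t) = -coupling_amp * bold(t + true_lag) + noise

    The lag is applied by integer shift on an over-generated series with
    the wrapped segment discarded from both ends, so the true lag is
    exact and free of edge transients.
    """
    rng = _rng(cfg.seed, _STREAM_COUPLED, subject)
    lag = int(cfg.true_lag)
    m = abs(lag)
    base = band_limited_noise(cfg.n_frames + m, cfg.dt, cfg.band, rng)
    if lag <= 0:
        bold_v = base[m:]
        shifted = base[: base.size - m]
    else:
        bold_v = base[: base.size - m]
        shifted = base[m:]
    csf_v = -cfg.coupling_amp * shifted + cfg.noise_sd * rng.standard_normal(
        cfg.n_frames
    )
    truth = GroundTruth(
        {
            "subject": subject,
            "true_lag": lag,
            "coupling_amp": cfg.coupling_amp,
            "noise_sd": cfg.noise_sd,
            "dt": cfg.dt,
            "n_frames": cfg.n_frames,
            "band": cfg.band,
        }
    )
    return TimeSeries(bold_v, cfg.dt), TimeSeries(csf_v, cfg.dt), truth


def gen_coupled_cohort(
    cfg: SimConfig,
) -> list[tuple[TimeSeries, TimeSeries, GroundTruth]]:
    """All ``cfg.n_subjects`` BOLD/CSF pairs, independent substreams."""
    return [gen_coupled_bold_csf(cfg, s) for s in range(cfg.n_subjects)]


def gen_motion_trace(
    cfg: SimConfig,
    spike_frames: Sequence[int] = (),
    spike_size: float = 0.5,
    drift_amp: float = 0.01,
) -> MotionTrace:
    """Smooth low-amplitude drift plus translation jumps at given frames.

    A jump is a sustained step of ``spike_size`` mm in x from the spike
    frame onward, producing exactly one frame-wise-displacement spike.
    """
    n = cfg.n_frames
    for f in spike_frames:
        if not 0 < f < n:
            raise InvalidConfigError(f"spike frame {f} outside 1..{n - 1}")
    t = np.arange(n, dtype=float)
    trans = np.zeros((n, 3))
    rot = np.zeros((n, 3))
    if drift_amp > 0:
        # slow (well below scrub threshold per frame) sinusoidal drift
        for j, period in enumerate((97.0, 131.0, 173.0)):
            trans[:, j] = drift_amp * np.sin(2 * np.pi * t / period)
            rot[:, j] = (drift_amp / 50.0) * np.sin(2 * np.pi * t / (period + 10))
    for f in spike_frames:
        trans[f:, 0] += spike_size
    return MotionTrace(trans, rot)


def _rise_profile(kind: str, m: int) -> np.ndarray:
    """Fractional rise over m intervals, from 0 at index 0 to 1 at index m."""
    u = np.arange(m + 1) / m
    if kind == "linear":
        return u
    if kind == "sigmoid":
        z = 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5)))
        return (z - z[0]) / (z[-1] - z[0])
    raise InvalidConfigError(f"unknown rise shape {kind!r}")


def gen_gd_curve(cfg: SimConfig, unit: int = 0):
    """Synthetic Gd time-intensity curve in fractional signal change.

    Returns ``(curve, truth)`` where ``curve`` is a
    :class:`~neurofluid.kinetics.GdCurve`.  The tail after the peak is
    exactly ``A*exp(-(t - t_peak)/decay) + C``; the rise from
    ``ramp_start_frame`` to the peak is linear by default (matching the
    influx-slope definition) or sigmoid behind the ``rise`` flag.
    """
    from .kinetics import GdCurve  # local import to avoid a cycle

    k = cfg.kinetics
    if k.baseline_frames < 3:
        raise InvalidConfigError("baseline_frames must be >= 3")
    if not (k.baseline_frames <= k.ramp_start_frame < k.ttp_frame < k.n_frames):
        raise InvalidConfigError("need baseline <= ramp start < ttp < n_frames")
    rng = _rng(cfg.seed, _STREAM_GD, unit)
    v = np.zeros(k.n_frames)
    m = k.ttp_frame - k.ramp_start_frame
    v[k.ramp_start_frame : k.ttp_frame + 1] = k.peak_amp * _rise_profile(k.rise, m)
    tail = np.arange(k.n_frames - k.ttp_frame) * k.frame_dt
    v[k.ttp_frame :] = k.A * np.exp(-tail / k.decay) + k.C
    if k.noise_sd > 0:
        v = v + k.noise_sd * rng.standard_normal(k.n_frames)
    curve = GdCurve(
        values=v,
        frame_dt=k.frame_dt,
        baseline_frames=k.baseline_frames,
        injection_index=k.baseline_frames,
    )
    truth = GroundTruth(
        {
            "unit": unit,
            "ramp_start_frame": k.ramp_start_frame,
            "ttp_frame": k.ttp_frame,
            "ttp_minutes": k.ttp_frame * k.frame_dt,
            "peak_amp": k.peak_amp,
            "A": k.A,
            "decay": k.decay,
            "C": k.C,
            "noise_sd": k.noise_sd,
            "frame_dt": k.frame_dt,
            "injection_index": k.baseline_frames,
            "rise": k.rise,
        }
    )
    return curve, truth


def gen_pulsatile_signal(cfg: SimConfig, unit: int = 0) -> tuple[TimeSeries, GroundTruth]:
    """Fast-MRI arterial inflow signal with unit temporal mean.

    Sum of sinusoids at the cardiac frequency and its first harmonic
    (generated in continuous time and sampled at ``pulse_dt``, so the
    harmonic aliases naturally when above Nyquist), the respiration
    rate, a vasomotion component in 0.01-0.1 Hz, plus white noise.
    """
    nyq = 0.5 / cfg.pulse_dt
    if not 0 < cfg.cardiac_freq < nyq:
        raise InvalidConfigError("cardiac_freq must lie below the sampling Nyquist")
    rng = _rng(cfg.seed, _STREAM_PULSE, unit)
    t = np.arange(cfg.pulse_n_frames) * cfg.pulse_dt
    phases = rng.uniform(0, 2 * np.pi, size=4)
    harmonic_amp = cfg.harmonic_ratio * cfg.cardiac_amp
    v = (
        1.0
        + cfg.cardiac_amp * np.sin(2 * np.pi * cfg.cardiac_freq * t + phases[0])
        + harmonic_amp * np.sin(2 * np.pi * 2 * cfg.cardiac_freq * t + phases[1])
        + cfg.resp_amp * np.sin(2 * np.pi * cfg.resp_freq * t + phases[2])
        + cfg.vasomotion_amp * np.sin(2 * np.pi * cfg.vasomotion_freq * t + phases[3])
    )
    if cfg.pulse_noise_sd > 0:
        v = v + cfg.pulse_noise_sd * rng.standard_normal(t.size)
    truth = GroundTruth(
        {
            "unit": unit,
            "cardiac_freq": cfg.cardiac_freq,
            "cardiac_amp": cfg.cardiac_amp,
            "harmonic_freq": 2 * cfg.cardiac_freq,
            "harmonic_amp": harmonic_amp,
            "resp_freq": cfg.resp_freq,
            "resp_amp": cfg.resp_amp,
            "vasomotion_freq": cfg.vasomotion_freq,
            "vasomotion_amp": cfg.vasomotion_amp,
            "noise_sd": cfg.pulse_noise_sd,
            "dt": cfg.pulse_dt,
        }
    )
    return TimeSeries(v, cfg.pulse_dt), truth


def gen_asl_dataset(
    cfg: SimConfig, params: ASLParameters | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """pCASL label/control volumes consistent with the CBF formula.

    The control signal is a constant ``si_c``; the label signal is
    obtained by inverting the quantification formula at ``cbf_true``,
    so quantifying the generated data is an exact round trip.
    Returns ``(label, control, t1_map, truth)``.
    """
    p = params if params is not None else ASLParameters()
    a = cfg.asl
    control = np.full(a.shape, a.si_c, dtype=float)
    t1_map = np.full(a.shape, a.t1t, dtype=float)
    si_pd = control / (1.0 - np.exp(-p.tr / t1_map))
    cbf_per_ms = a.cbf_true / CBF_UNIT_SCALE
    diff = (
        cbf_per_ms
        * 2.0
        * p.alpha
        * t1_map
        * si_pd
        * (1.0 - np.exp(-p.lt / t1_map))
        / (p.lambda_ * np.exp(p.pld / p.t1b))
    )
    label = control - diff
    truth = GroundTruth(
        {
            "cbf_true": a.cbf_true,
            "t1t": a.t1t,
            "si_c": a.si_c,
            "params": asdict(p),
            "shape": a.shape,
        }
    )
    return label, control, t1_map, truth


def gen_asl_series(
    cfg: SimConfig, params: ASLParameters | None = None
) -> tuple[ASLSeries, GroundTruth]:
    """Convenience wrapper returning an :class:`ASLSeries` container."""
    label, control, t1_map, truth = gen_asl_dataset(cfg, params)
    return ASLSeries(si_c=control, si_l=label, t1t=t1_map), truth


def infusion_duration(volume_ul: float = 8.0, rate_ul_per_min: float = 0.5) -> float:
    """Duration in minutes of a constant-rate intracisternal infusion."""
    if rate_ul_per_min <= 0:
        raise InvalidConfigError("infusion rate must be > 0")
    return volume_ul / rate_ul_per_min


def scan_duration(n_frames: int, dt: float) -> float:
    """Total acquisition time ``n_frames * dt`` (unit of ``dt``)."""
    if n_frames < 1 or dt <= 0:
        raise InvalidConfigError("need n_frames >= 1 and dt > 0")
    return n_frames * dt
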
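"""Tracer-kinetic extraction: normalization, AUC, arrival, peak, influx
slope and the exponential decay fit against independent oracles."""

import dataclasses

import numpy as np
import pytest

from neurofluid.core import InvalidConfigError, NeurofluidError, NoEnhancementError
from neurofluid.kinetics import (
    GdCurve,
    arrival_time,
    auc,
    decay_fit,
    extract_kinetics,
    influx_rate,
    kinetic_maps,
    normalize_gd,
    time_to_peak,
)
from neurofluid.simulate import GdKineticsConfig, SimConfig, gen_gd_curve


def _curve(values, dt=1.0, baseline=1, injection=None):
    return GdCurve(np.asarray(values, float), frame_dt=dt,
                   baseline_frames=baseline, injection_index=injection)


class TestNormalize:
    def test_twenty_percent_enhancement(self):
        c = normalize_gd(np.array([100.0, 100, 100, 120]), baseline_frames=3, frame_dt=1.0)
        assert c.values[3] == pytest.approx(0.20)

    def test_flat_curve_is_zero(self):
        c = normalize_gd(np.full(6, 250.0), baseline_frames=3, frame_dt=1.0)
        np.testing.assert_allclose(c.values, 0.0, atol=1e-12)

    def test_uneven_baseline_mean(self):
        c = normalize_gd(np.array([90.0, 100, 110, 150]), baseline_frames=3, frame_dt=1.0)
        assert c.values[3] == pytest.approx(0.50)

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(NeurofluidError):
            normalize_gd(np.array([0.0, 0, 0, 5]), baseline_frames=3, frame_dt=1.0)


class TestAUC:
    def test_zero_signal_gives_zero(self):
        c = _curve(np.zeros(12), baseline=3)
        assert auc(c) == 0.0

    def test_unit_signal_counts_frames(self):
        v = np.zeros(13)
        v[3:] = 1.0  # injection_index defaults to baseline_frames = 3
        assert auc(_curve(v, baseline=3)) == 10.0

    def test_self_normalization_is_one(self):
        v = np.concatenate([np.zeros(3), np.linspace(0.1, 0.5, 7)])
        c = _curve(v, baseline=3)
        assert auc(c, whole_brain_auc=auc(c)) == pytest.approx(1.0)

    def test_auc_invariant_to_post_injection_permutation(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([np.zeros(3), rng.uniform(0, 1, 10)])
        c1 = _curve(v, baseline=3)
        v2 = v.copy()
        v2[3:] = rng.permutation(v[3:])
        c2 = _curve(v2, baseline=3)
        assert auc(c1) == pytest.approx(auc(c2), rel=1e-12)
        # ...but arrival and TTP are order-sensitive
        assert (arrival_time(c1), time_to_peak(c1)) != (arrival_time(c2), time_to_peak(c2))


class TestArrivalAndPeak:
    def test_step_to_max(self):
        v = np.zeros(10)
        v[6:] = 1.0
        c = _curve(v, baseline=1, injection=1)
        assert arrival_time(c) == 6.0
        assert time_to_peak(c) == 6.0

    def test_linear_ramp_crosses_twenty_percent_at_frame_three(self):
        # ramp 0..1 over frames 0..10: first value > 0.2 is 0.3 at frame 3
        v = np.linspace(0, 1, 11)
        c = GdCurve(v, frame_dt=1.0, baseline_frames=1, injection_index=1)
        assert arrival_time(c) == 3.0

    def test_subthreshold_noise_ignored(self):
        v = np.zeros(20)
        v[2:10] = 0.15  # below 0.2 * max (max = 1.0)
        v[12:] = 1.0
        c = _curve(v, baseline=1, injection=1)
        assert arrival_time(c) == 12.0

    def test_plateau_takes_earliest_maximum(self):
        v = np.zeros(10)
        v[4:8] = 1.0
        c = _curve(v, baseline=1, injection=1)
        assert time_to_peak(c) == 4.0

    def test_no_enhancement_errors(self):
        c = _curve(np.zeros(10) - 0.01, baseline=1, injection=1)
        with pytest.raises(NoEnhancementError):
            arrival_time(c)


class TestInfluxRate:
    def test_exact_line_slope(self):
        t = np.arange(12.0)
        v = 0.07 * t
        c = _curve(v, baseline=1, injection=1)
        assert influx_rate(c, arrival=2.0, ttp=10.0) == pytest.approx(0.07)

    def test_two_point_hand_slope(self):
        v = np.zeros(8)
        v[2], v[6] = 0.2, 1.0
        c = _curve(v, baseline=1, injection=1)
        # (1.0 - 0.2) / (6 - 2) = 0.2 per unit time
        assert influx_rate(c, 2.0, 6.0, two_point=True) == pytest.approx(0.2)

    def test_flat_window_gives_zero(self):
        c = _curve(np.full(10, 0.5), baseline=1, injection=1)
        assert influx_rate(c, 2.0, 6.0) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_frames_errors(self):
        c = _curve(np.arange(10.0), dt=1.0, baseline=1, injection=1)
        with pytest.raises(InvalidConfigError):
            influx_rate(c, 5.0, 5.0)


def _tail_curve(A, decay, C, n=30, dt=1.0, peak_idx=4, noise=0.0, seed=0):
    t = np.arange(n) * dt
    v = np.zeros(n)
    v[:peak_idx] = np.linspace(0, A + C, peak_idx, endpoint=False)
    v[peak_idx:] = A * np.exp(-(t[peak_idx:] - t[peak_idx]) / decay) + C
    if noise:
        v = v + np.random.default_rng(seed).normal(0, noise, n)
    return GdCurve(v, frame_dt=dt, baseline_frames=1, injection_index=1)


class TestDecayFit:
    def test_noiseless_round_trip(self):
        c = _tail_curve(10.0, 30.0, 2.0, n=40)
        fit = decay_fit(c, ttp=4.0)
        assert fit.A == pytest.approx(10.0, rel=1e-6)
        assert fit.decay == pytest.approx(30.0, rel=1e-6)
        assert fit.C == pytest.approx(2.0, rel=1e-6)

    def test_zero_offset_matches_log_linear_oracle(self):
        # with C = 0, ln v is linear in t: slope = -1/decay
        c = _tail_curve(5.0, 12.0, 0.0, n=30)
        fit = decay_fit(c, ttp=4.0)
        tail = c.values[4:]
        tt = (c.times[4:] - c.times[4])
        slope, intercept = np.polyfit(tt, np.log(tail), 1)
        assert fit.decay == pytest.approx(-1.0 / slope, rel=1e-6)
        assert fit.A == pytest.approx(np.exp(intercept), rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_fit_agrees_with_grid_search(self, seed):
        # coarse brute-force grid over (A, decay, C); the NLS fit must
        # land within one grid step of the grid minimum.  The tail spans
        # 4.5 decay constants so the three parameters are identifiable.
        c = _tail_curve(10.0, 8.0, 2.0, n=40, noise=0.5, seed=seed)  # SNR ~ 20
        fit = decay_fit(c, ttp=4.0)
        tt = c.times[4:] - c.times[4]
        vv = c.values[4:]
        As = np.arange(7.0, 13.1, 0.5)
        Ds = np.arange(5.0, 12.1, 0.5)
        Cs = np.arange(0.0, 4.1, 0.25)
        model = As[:, None, None, None] * np.exp(
            -tt[None, None, None, :] / Ds[None, :, None, None]
        ) + Cs[None, None, :, None]
        rss = ((model - vv) ** 2).sum(axis=-1)
        ia, id_, ic = np.unravel_index(np.argmin(rss), rss.shape)
        assert abs(fit.A - As[ia]) <= 0.5
        assert abs(fit.decay - Ds[id_]) <= 0.5
        assert abs(fit.C - Cs[ic]) <= 0.25

    def test_too_few_post_peak_frames_errors(self):
        c = _tail_curve(5.0, 10.0, 0.0, n=8)
        with pytest.raises(InvalidConfigError):
            decay_fit(c, ttp=5.0)


class TestRecoveryProperties:
    def test_effective_ttp_identity(self, cfg):
        curve, _ = gen_gd_curve(cfg)
        kp = extract_kinetics(curve)
        assert kp.effective_ttp == kp.ttp - kp.arrival_time

    def test_noisy_recovery_median_errors(self):
        # 20 noisy curves at SNR 20 (a quick version of the full
        # 100-curve recovery run in the acceptance suite)
        errs_d, errs_t = [], []
        for rep in range(20):
            cfg = SimConfig(seed=rep, kinetics=GdKineticsConfig(noise_sd=0.02))
            curve, truth = gen_gd_curve(cfg)
            kp = extract_kinetics(curve)
            errs_d.append(abs(kp.decay - truth["decay"]) / truth["decay"])
            errs_t.append(abs(kp.ttp - truth["ttp_minutes"]) / truth["ttp_minutes"])
        assert np.median(errs_d) < 0.10
        assert np.median(errs_t) < 0.05

    def test_decay_estimate_monotone_in_true_decay(self):
        # paired on shared noise seeds: +50% true decay -> larger estimate
        for rep in range(8):
            ests = []
            for decay in (20.0, 30.0):
                cfg = SimConfig(
                    seed=rep,
                    kinetics=GdKineticsConfig(decay=decay, noise_sd=0.02),
                )
                curve, _ = gen_gd_curve(cfg)
                ests.append(extract_kinetics(curve).decay)
            assert ests[1] > ests[0]


class TestKineticMaps:
    def _phantom(self, kcfg, shape=(6, 6, 4)):
        cfg = SimConfig(kinetics=kcfg)
        curve, truth = gen_gd_curve(cfg)
        raw = 1000.0 * (1.0 + curve.values)
        vol = np.broadcast_to(raw, shape + (raw.size,)).copy()
        return vol, truth

    def test_uniform_phantom_recovers_truth_everywhere(self):
        vol, truth = self._phantom(GdKineticsConfig())
        mask = np.ones(vol.shape[:3], dtype=bool)
        maps = kinetic_maps(vol, mask, baseline_frames=3, frame_dt=3.33)
        assert not maps["qc"].any()
        np.testing.assert_allclose(maps["decay"], truth["decay"], rtol=1e-5)
        np.testing.assert_allclose(maps["ttp"], truth["ttp_minutes"], rtol=1e-9)
        # uniform phantom: every voxel AUC equals the whole-brain AUC
        np.testing.assert_allclose(maps["auc"], 1.0, rtol=1e-9)

    def test_two_region_phantom_is_bimodal_in_decay(self):
        vol_a, _ = self._phantom(GdKineticsConfig(decay=20.0), shape=(6, 6, 2))
        vol_b, _ = self._phantom(GdKineticsConfig(decay=40.0), shape=(6, 6, 2))
        vol = np.concatenate([vol_a, vol_b], axis=2)
        mask = np.ones(vol.shape[:3], dtype=bool)
        maps = kinetic_maps(vol, mask, baseline_frames=3, frame_dt=3.33)
        decays = maps["decay"][mask]
        assert np.allclose(np.unique(np.round(decays, 3)), [20.0, 40.0], atol=0.01)

    def test_zero_enhancement_voxel_flagged_in_qc(self):
        vol, _ = self._phantom(GdKineticsConfig())
        vol[0, 0, 0, :] = 1000.0  # flat voxel: no enhancement
        mask = np.ones(vol.shape[:3], dtype=bool)
        maps = kinetic_maps(vol, mask, baseline_frames=3, frame_dt=3.33)
        assert maps["qc"][0, 0, 0]
        assert np.isnan(maps["decay"][0, 0, 0])
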
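"""Time-of-flight branch: compensation, filtering, arrival detection, speeds."""

import numpy as np
import pytest
from scipy import signal

import swelast as sw
from swelast.errors import ConfigError, InvalidMeasurementError, NoDetectionError
from swelast.tof import (
    THRESHOLD_FRACTION,
    ProbeCalibration,
    TOFEstimate,
    record_tof,
)

FS = 100e3


def _burst(t, t0, f_exc, n_cycles=1.0):
    from swelast.simulate import burst_waveform
    return burst_waveform(t - t0, f_exc, n_cycles=n_cycles)


class TestCompensate:
    def test_specimen_equals_air_gives_zero(self):
        t = np.arange(1000) / FS
        v = np.sin(2 * np.pi * 300.0 * t)
        rec = sw.TWERecord(t=t, v_specimen=v, v_air=v, f_exc=300.0,
                           distance=3e-3)
        np.testing.assert_array_equal(sw.compensate(rec), 0.0)

    def test_noiseless_generator_cancellation(self, liver_twe_medium):
        rec = sw.simulate_twe(liver_twe_medium, f_exc=400.0,
                              internal_delay=0.5e-3, crosstalk_gain=0.8)
        clean = sw.simulate_twe(liver_twe_medium, f_exc=400.0,
                                internal_delay=0.5e-3, crosstalk_gain=0.0)
        np.testing.assert_allclose(sw.compensate(rec), clean.v_specimen,
                                   atol=1e-12)

    def test_averaging_reduces_noise_sqrt_n(self, liver_twe_medium):
        # across many seeds, the 10-average residual noise std is ~ sqrt(10)
        # smaller than the single-shot noise std
        stds_1, stds_10 = [], []
        for seed in range(500):
            kw = dict(f_exc=400.0, snr_db=20.0, duration=0.05, seed=seed)
            r1 = sw.simulate_twe(liver_twe_medium, n_averages=1, **kw)
            r10 = sw.simulate_twe(liver_twe_medium, n_averages=10, **kw)
            clean = sw.simulate_twe(liver_twe_medium, duration=0.05,
                                    f_exc=400.0)
            stds_1.append((sw.compensate(r1) - clean.v_specimen).std())
            stds_10.append((sw.compensate(r10) - clean.v_specimen).std())
        ratio = np.mean(stds_1) / np.mean(stds_10)
        assert ratio == pytest.approx(np.sqrt(10.0), rel=0.05)

    def test_mismatched_time_base_rejected(self):
        t = np.arange(1000) / FS
        with pytest.raises(ConfigError):
            sw.TWERecord(t=t, v_specimen=np.zeros(1000),
                         v_air=np.zeros(999), f_exc=300.0, distance=3e-3)


class TestLowpass:
    def test_passband_tone_preserved(self):
        t = np.arange(int(0.1 * FS)) / FS
        x = np.sin(2 * np.pi * 400.0 * t)
        y = sw.lowpass(x, 400.0, FS)
        assert np.abs(y[1000:-1000]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_attenuated(self):
        t = np.arange(int(0.1 * FS)) / FS
        x = np.sin(2 * np.pi * 4000.0 * t)
        y = sw.lowpass(x, 400.0, FS)  # tone at 10x f_exc
        assert 20 * np.log10(np.abs(y[1000:-1000]).max()) < -40.0

    def test_zero_phase_keeps_symmetric_peak(self):
        t = np.arange(int(0.05 * FS)) / FS
        x = signal.windows.gaussian(t.size, std=200)
        y = sw.lowpass(x, 400.0, FS)
        assert abs(int(np.argmax(y)) - int(np.argmax(x))) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            sw.lowpass(np.zeros(100), 20e3, FS)


class TestEstimateTOF:
    @pytest.mark.parametrize("f_exc", [200.0, 400.0, 800.0])
    def test_ideal_burst_back_corrections_exact(self, f_exc):
        t0 = 5.0e-3
        t = np.arange(int(0.05 * FS)) / FS
        x = _burst(t, t0, f_exc)
        est = sw.estimate_tof(x, FS, f_exc)
        dt = 1.0 / FS
        for got in (est.t_threshold, est.t_first_peak, est.t_neg_peak,
                    est.t_combined):
            assert got == pytest.approx(t0, abs=1.01 * dt)

    def test_three_raw_detections_in_order(self):
        f_exc = 400.0
        t = np.arange(int(0.05 * FS)) / FS
        est = sw.estimate_tof(_burst(t, 4e-3, f_exc), FS, f_exc)
        period = 1.0 / f_exc
        raw = [est.t_threshold + THRESHOLD_FRACTION * period,
               est.t_first_peak + period / 4.0,
               est.t_neg_peak + 3.0 * period / 4.0]
        assert raw == sorted(raw)

    def test_translation_equivariance(self):
        f_exc = 400.0
        t = np.arange(int(0.05 * FS)) / FS
        e1 = sw.estimate_tof(_burst(t, 4e-3, f_exc), FS, f_exc)
        e2 = sw.estimate_tof(_burst(t, 7e-3, f_exc), FS, f_exc)
        assert e2.t_combined - e1.t_combined == pytest.approx(3e-3, abs=1e-9)

    def test_amplitude_scale_invariance(self):
        f_exc = 400.0
        t = np.arange(int(0.05 * FS)) / FS
        x = _burst(t, 4e-3, f_exc)
        e1 = sw.estimate_tof(x, FS, f_exc)
        e2 = sw.estimate_tof(17.3 * x, FS, f_exc)
        assert e1 == e2

    def test_pure_noise_raises_no_detection(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 5000)
        with pytest.raises(NoDetectionError) as exc_info:
            sw.estimate_tof(x, FS, 400.0)
        assert "peak" in exc_info.value.diagnostics

    def test_estimators_agree_within_tenth_period_after_filter(
            self, liver_twe_medium):
        for f_exc in (200.0, 400.0, 600.0, 800.0):
            rec = sw.simulate_twe(liver_twe_medium, f_exc=f_exc,
                                  duration=0.05)
            est = record_tof(rec)
            spread = max(est.t_threshold, est.t_first_peak, est.t_neg_peak) \
                - min(est.t_threshold, est.t_first_peak, est.t_neg_peak)
            assert spread < 0.1 / f_exc


class TestSpeed:
    def test_delay_free_arithmetic(self):
        est = TOFEstimate(2e-3, 2e-3, 2e-3, 2e-3, 400.0)
        cal = ProbeCalibration(internal_delay=0.0, distance=3e-3)
        assert sw.speed(est, cal) == pytest.approx(1.5)

    def test_delay_subtracted(self):
        est = TOFEstimate(2.5e-3, 2.5e-3, 2.5e-3, 2.5e-3, 400.0)
        cal = ProbeCalibration(internal_delay=0.5e-3, distance=3e-3)
        assert sw.speed(est, cal) == pytest.approx(1.5)

    def test_tof_below_delay_invalid(self):
        est = TOFEstimate(1e-3, 1e-3, 1e-3, 1e-3, 400.0)
        cal = ProbeCalibration(internal_delay=2e-3, distance=3e-3)
        with pytest.raises(InvalidMeasurementError):
            sw.speed(est, cal)


class TestCalibrateDelay:
    def _records(self, medium, delay, seeds=None, snr=None):
        freqs = [200.0, 400.0, 600.0, 800.0]
        recs = [sw.simulate_twe(medium, f_exc=fe, internal_delay=delay,
                                crosstalk_gain=0.4, duration=0.05,
                                snr_db=snr, n_averages=10,
                                seed=0 if seeds is None else seeds + i)
                for i, fe in enumerate(freqs)]
        refs = [float(sw.phase_velocity(medium, 2 * np.pi * fe))
                for fe in freqs]
        return recs, refs

    def test_injected_delay_recovered(self, liver_twe_medium):
        recs, refs = self._records(liver_twe_medium, 0.8e-3)
        cal = sw.calibrate_delay(recs, refs)
        assert cal.internal_delay == pytest.approx(0.8e-3, abs=2e-5)

    def test_zero_delay_recovers_zero(self, liver_twe_medium):
        recs, refs = self._records(liver_twe_medium, 0.0)
        cal = sw.calibrate_delay(recs, refs)
        assert cal.internal_delay == pytest.approx(0.0, abs=2e-5)

    def test_unbiased_across_noise_realizations(self, liver_twe_medium):
        delays = []
        for s in range(200):
            recs, refs = self._records(liver_twe_medium, 0.8e-3,
                                       seeds=1000 + 4 * s, snr=30.0)
            delays.append(sw.calibrate_delay(recs, refs).internal_delay)
        assert abs(np.mean(delays) - 0.8e-3) < 0.02 * 0.8e-3

    def test_too_few_records_rejected(self, liver_twe_medium):
        recs, refs = self._records(liver_twe_medium, 0.0)
        with pytest.raises(ConfigError):
            sw.calibrate_delay(recs[:1], refs[:1])


class TestTWEDispersion:
    def test_noiseless_curve_matches_model(self, liver_twe_medium):
        freqs = [200.0, 400.0, 600.0, 800.0]
        recs = [sw.simulate_twe(liver_twe_medium, f_exc=fe, duration=0.05)
                for fe in freqs]
        cal = ProbeCalibration(internal_delay=0.0, distance=3e-3)
        curve = sw.twe_dispersion(recs, cal)
        c_model = sw.phase_velocity(liver_twe_medium, 2 * np.pi * curve.f)
        assert np.all(np.diff(curve.c) > 0)
        np.testing.assert_allclose(curve.c, c_model, rtol=0.02)

    def test_duplicate_frequency_aggregation(self, liver_twe_medium):
        recs = [sw.simulate_twe(liver_twe_medium, f_exc=fe, duration=0.05,
                                snr_db=30.0, seed=s)
                for fe, s in [(200.0, 1), (200.0, 2), (400.0, 3)]]
        cal = ProbeCalibration(internal_delay=0.0, distance=3e-3)
        curve = sw.twe_dispersion(recs, cal)
        assert list(curve.n) == [2, 1]
        speeds = []
        for rec in recs[:2]:
            speeds.append(sw.speed(record_tof(rec), cal))
        assert curve.c[0] == pytest.approx(np.mean(speeds))
        assert curve.c_std[0] == pytest.approx(np.std(speeds, ddof=1))

    def test_single_frequency_rejected(self, liver_twe_medium):
        recs = [sw.simulate_twe(liver_twe_medium, f_exc=200.0, duration=0.05)]
        cal = ProbeCalibration(internal_delay=0.0, distance=3e-3)
        with pytest.raises(ConfigError):
            sw.twe_dispersion(recs, cal)

    def test_undetectable_records_dropped(self, liver_twe_medium):
        good = [sw.simulate_twe(liver_twe_medium, f_exc=fe, duration=0.05)
                for fe in (200.0, 400.0)]
        rng = np.random.default_rng(0)
        t = good[0].t
        noise = sw.TWERecord(t=t, v_specimen=rng.normal(0, 1.0, t.size),
                             v_air=np.zeros(t.size), f_exc=600.0,
                             distance=3e-3)
        cal = ProbeCalibration(internal_delay=0.0, distance=3e-3)
        curve = sw.twe_dispersion(good + [noise], cal)
        assert list(curve.f) == [200.0, 400.0]
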
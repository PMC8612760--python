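"""Spike quantification conventions: amplitudes, thresholds, widths,
attenuation, evoked-AP counting and AHP measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dendrospike as ds
from dendrospike.detection import RegenerativeEvent, detect_and_classify
from dendrospike.metrics import (
    MeasurementSkipped,
    adp_amplitude,
    ahp_comparison,
    attenuation,
    count_evoked_aps,
    di_threshold_and_amplitude,
    metrics_table,
    width_half_amplitude,
)
from dendrospike.recording import SweepRecording, binomial_smooth
from dendrospike.synth import (
    EventClass,
    SynthSweepConfig,
    default_kernel,
    generate_sweep,
)
from dendrospike.synth import scenarios

FS = 50_000.0


def _first(events, label):
    return next(e for e in events if e.label == label)


class TestDiThresholdAndAmplitude:
    def test_noisefree_recovery_within_half_mv(self, di_sweep_noisefree):
        sweep, truth = di_sweep_noisefree
        events, _ = detect_and_classify(sweep)
        di = _first(events, "DI_spike")
        thr, amp = di_threshold_and_amplitude(di, sweep)
        assert abs(amp - truth[0].amplitude) < 0.5

    def test_no_deviation_raises(self, flat_sweep):
        """An 'event' whose span holds no deviation from the fit has no
        measurable threshold."""
        sweep, _ = flat_sweep
        i = sweep.index_at(500.0)
        fake = RegenerativeEvent(
            onset_index=i, peak_index=i + 50, end_index=i + 100,
            onset_time=500.0, peak_time=501.0, end_time=502.0,
            peak_vm=float(sweep.v_dend[i + 50]), amplitude=10.0,
            dvdt_peak=1.0, dvdt_pre=0.9, dvdt_ratio=0.9,
            latency_from_step=400.0, label="DI_spike")
        with pytest.raises(MeasurementSkipped):
            di_threshold_and_amplitude(fake, sweep)

    def test_population_mean_near_generator_amplitude(self):
        """DI spikes generated at the 25.4 mV threshold-drive amplitude
        are recovered near that mean across noisy sweeps."""
        amps = []
        for k in range(10):
            cfg = scenarios.di_config(np.random.default_rng(200 + k),
                                      seed=200 + k, noise_sd=0.3)
            sweep, _ = generate_sweep(cfg)
            events, _ = detect_and_classify(sweep)
            _, amp = di_threshold_and_amplitude(_first(events, "DI_spike"),
                                                sweep)
            amps.append(amp)
        assert abs(np.mean(amps) - 25.4) < 1.5

    def test_non_di_event_skipped(self, fast_adp_sweep_noisefree):
        sweep, _ = fast_adp_sweep_noisefree
        events, _ = detect_and_classify(sweep)
        with pytest.raises(MeasurementSkipped):
            di_threshold_and_amplitude(_first(events, "fast_ADP"), sweep)


class TestAdpAmplitude:
    def test_fast_adp_noisefree_recovery(self, fast_adp_sweep_noisefree):
        sweep, truth = fast_adp_sweep_noisefree
        events, aps = detect_and_classify(sweep)
        adp = _first(events, "fast_ADP")
        amp = adp_amplitude(adp, sweep, aps)
        true = next(g.amplitude for g in truth
                    if g.event_class is EventClass.fast_ADP)
        assert abs(amp - true) < 0.5

    def test_slow_adp_recovery(self, slow_adp_sweep):
        sweep, truth = slow_adp_sweep
        events, aps = detect_and_classify(sweep)
        amp = adp_amplitude(_first(events, "slow_ADP"), sweep, aps)
        assert abs(amp - 17.2) < 1.0

    def test_peak_obscured_by_evoked_ap_skipped(self, slow_adp_sweep):
        sweep, _ = slow_adp_sweep
        events, aps = detect_and_classify(sweep)
        adp = _first(events, "slow_ADP")
        adp.label = "fast_ADP"  # force the clear-peak rule path
        fake_aps = [adp.initiating_ap, adp.peak_time + 0.5]
        with pytest.raises(MeasurementSkipped):
            adp_amplitude(adp, sweep, fake_aps)

    def test_burst_preceded_initiating_ap_skipped(self, slow_adp_sweep):
        """The measurement is skipped when more than two APs precede the
        initiating AP."""
        sweep, _ = slow_adp_sweep
        events, aps = detect_and_classify(sweep)
        adp = _first(events, "slow_ADP")
        t0 = adp.initiating_ap
        crowded = [t0 - 30.0, t0 - 20.0, t0 - 10.0, t0] + \
                  [a.peak_time for a in aps]
        with pytest.raises(MeasurementSkipped):
            adp_amplitude(adp, sweep, crowded)


class TestWidthHalfAmplitude:
    def _triangle_sweep(self, amp=10.0, base_ms=10.0, at=500.0):
        cfg = SynthSweepConfig(step_amplitude=300.0, noise_sd=0.0, seed=0)
        sweep, _ = generate_sweep(cfg)
        dt = sweep.dt
        half = int(base_ms / 2 / dt)
        tri = np.concatenate([np.linspace(0, amp, half),
                              np.linspace(amp, 0, half)])
        i0 = sweep.index_at(at)
        sweep.v_dend[i0: i0 + tri.size] += tri
        ev = RegenerativeEvent(
            onset_index=i0, peak_index=i0 + half, end_index=i0 + tri.size,
            onset_time=at, peak_time=at + base_ms / 2,
            end_time=at + base_ms, peak_vm=float(sweep.v_dend[i0 + half]),
            amplitude=amp, dvdt_peak=2.0, dvdt_pre=1.0, dvdt_ratio=0.5,
            latency_from_step=at - 100.0, label="DI_spike")
        return sweep, ev

    def test_triangular_spike_matches_smoothed_oracle(self):
        """Width of a symmetric triangle equals the direct measurement on
        the N = 10 binomially smoothed fixture (5 ms before smoothing;
        smoothing widens it negligibly at 50 kHz)."""
        sweep, ev = self._triangle_sweep()
        thr = float(sweep.v_dend[ev.onset_index])
        w, capped = width_half_amplitude(ev, sweep, thr, 10.0)
        # oracle: crossings of the smoothed triangle at thr + 5 mV
        sm = binomial_smooth(sweep.v_dend, 10)
        above = np.nonzero(sm[ev.onset_index - 100: ev.end_index + 100]
                           >= thr + 5.0)[0]
        oracle = (above[-1] - above[0] + 1) * sweep.dt
        assert not capped
        assert abs(w - oracle) <= 2 * sweep.dt
        assert abs(w - 5.0) < 0.05

    def test_non_returning_plateau_capped_at_300(self):
        cfg = SynthSweepConfig(step_amplitude=300.0, noise_sd=0.0, seed=0)
        sweep, _ = generate_sweep(cfg)
        i0 = sweep.index_at(600.0)
        sweep.v_dend[i0:] += 20.0  # steps up and never returns
        ev = RegenerativeEvent(
            onset_index=i0, peak_index=i0 + 500, end_index=i0 + 1000,
            onset_time=600.0, peak_time=610.0, end_time=620.0,
            peak_vm=float(sweep.v_dend[i0 + 500]), amplitude=20.0,
            dvdt_peak=2.0, dvdt_pre=1.0, dvdt_ratio=0.5,
            latency_from_step=500.0, label="DI_spike")
        thr = float(sweep.v_dend[i0 - 1])
        w, capped = width_half_amplitude(ev, sweep, thr, 20.0)
        assert capped and w == 300.0

    def test_small_spike_skipped(self):
        sweep, ev = self._triangle_sweep(amp=4.0)
        with pytest.raises(MeasurementSkipped):
            width_half_amplitude(ev, sweep, -38.0, 4.0)

    def test_evoked_ap_skipped(self):
        sweep, ev = self._triangle_sweep()
        ev.evoked_ap = ev.peak_time + 2.0
        with pytest.raises(MeasurementSkipped):
            width_half_amplitude(ev, sweep, -38.0, 10.0)


class TestAttenuation:
    def test_arithmetic(self):
        assert attenuation(25.0, 5.0) == 5.0
        assert attenuation(7.3, 7.3) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0), st.floats(0.1, 10.0))
    def test_scale_invariance_under_common_gain(self, d, s, g):
        assert np.isclose(attenuation(d * g, s * g), attenuation(d, s))

    def test_masked_or_nonpositive_skipped(self):
        with pytest.raises(MeasurementSkipped):
            attenuation(25.0, 0.0)
        with pytest.raises(MeasurementSkipped):
            attenuation(25.0, 5.0, masked=True)

    def test_generator_attenuation_recovered(self):
        """Dual-recording amplitude ratio of DI spikes reproduces the
        configured 6.97 attenuation factor."""
        di = default_kernel(EventClass.DI_spike)
        cfg = SynthSweepConfig(step_amplitude=400.0, noise_sd=0.0, seed=0,
                               event_schedule=[(di, 500.0)])
        sweep, _ = generate_sweep(cfg)
        base, _ = generate_sweep(
            SynthSweepConfig(step_amplitude=400.0, noise_sd=0.0, seed=0))
        d_amp = float(np.max(sweep.v_dend - base.v_dend))
        s_amp = float(np.max(sweep.v_soma - base.v_soma))
        assert abs(attenuation(d_amp, s_amp) - 6.97) < 0.1


def brute_force_evoked_count(ap_times, t_init, t_return,
                             window_ms=300.0, max_isi_ms=100.0):
    """Independent rule evaluator: literal sequential application of the
    return-to-baseline / 300 ms window / <100 ms ISI conditions."""
    count = 0
    prev = t_init
    for t in sorted(ap_times):
        if t <= t_init:
            continue
        if t >= t_return or t - t_init > window_ms or t - prev >= max_isi_ms:
            break
        count += 1
        prev = t
    return count


class TestCountEvokedAps:
    def _sweep_with_plateau(self, t_return, ap_times, fs=10_000.0):
        """Flat baseline, step to +10 mV depolarization that drops back
        below baseline + 3.5 mV at ``t_return``; brief APs added."""
        dt = 1000.0 / fs
        n = int(900.0 / dt) + 1
        t = np.arange(n) * dt
        v = np.full(n, -70.0)
        i_inj = np.zeros(n)
        step = (t >= 100.0) & (t < 800.0)
        i_inj[step] = 300.0
        v[step & (t < t_return)] += 10.0
        v[step & (t >= t_return)] += 1.0  # below the +3.5 mV margin
        for ap in ap_times:
            k = int(round((ap - t[0]) / dt))
            v[max(k - 3, 0): k + 4] += 80.0
        sweep = SweepRecording(time=t, v_dend=v, i_inj=i_inj,
                               sampling_rate=fs, step_onset=100.0,
                               step_offset=800.0)
        return sweep

    def _event(self, sweep, t_init):
        i = sweep.index_at(t_init + 2.0)
        return RegenerativeEvent(
            onset_index=i, peak_index=i + 10, end_index=i + 20,
            onset_time=t_init + 2.0, peak_time=t_init + 3.0,
            end_time=t_init + 4.0, peak_vm=0.0, amplitude=15.0,
            dvdt_peak=1.0, dvdt_pre=0.9, dvdt_ratio=0.9,
            latency_from_step=t_init - 98.0, label="slow_ADP",
            initiating_ap=t_init)

    def test_isi_rule_terminates_count(self):
        """APs at +40, +120 and +260 ms after the initiating AP with the
        membrane depolarized throughout: the 140 ms gap before the third
        AP fails the <100 ms ISI rule, so exactly 2 APs count."""
        t0 = 200.0
        aps = [t0, t0 + 40.0, t0 + 120.0, t0 + 260.0]
        sweep = self._sweep_with_plateau(t_return=790.0, ap_times=aps)
        ev = self._event(sweep, t0)
        assert count_evoked_aps(ev, aps, sweep) == 2

    def test_return_to_baseline_rule(self):
        """An AP after V_m has fallen back to baseline + 3 mV does not
        count."""
        t0 = 200.0
        aps = [t0, t0 + 60.0]
        sweep = self._sweep_with_plateau(t_return=250.0, ap_times=aps)
        ev = self._event(sweep, t0)
        assert count_evoked_aps(ev, aps, sweep) == 0

    def test_exact_agreement_with_brute_force_on_random_fixtures(self):
        """1,000 randomized AP-train/voltage fixtures: the counter agrees
        exactly with the independent rule evaluator."""
        rng = np.random.default_rng(42)
        mismatches = 0
        for _ in range(1000):
            t0 = 150.0 + rng.uniform(0, 100.0)
            gaps = rng.uniform(20.0, 150.0, size=rng.integers(0, 6))
            aps = [t0]
            t = t0
            for g in gaps:
                # keep decisions unambiguous: stay away from the rule
                # boundaries (100 ms ISI, 300 ms window)
                if abs(g - 100.0) < 4.0:
                    g += 8.0
                t += g
                if abs((t - t0) - 300.0) < 4.0:
                    t += 8.0
                if t > 760.0:
                    break
                aps.append(t)
            t_return = float(rng.uniform(t0 + 10.0, 780.0))
            while any(abs(t_return - a) < 6.0 for a in aps):
                t_return += 7.0
            sweep = self._sweep_with_plateau(t_return=t_return, ap_times=aps)
            ev = self._event(sweep, t0)
            got = count_evoked_aps(ev, aps, sweep)
            want = brute_force_evoked_count(aps, t0, t_return)
            mismatches += got != want
        assert mismatches == 0

    def test_di_never_more_than_one_evoked_ap(self):
        """On generator sweeps DI spikes evoke at most one AP."""
        for k in range(6):
            cfg = scenarios.di_config(np.random.default_rng(300 + k),
                                      seed=300 + k, evoke_ap=True)
            sweep, _ = generate_sweep(cfg)
            events, _ = detect_and_classify(sweep)
            di = _first(events, "DI_spike")
            n = 1 if di.evoked_ap is not None else 0
            assert n <= 1


class TestAhpComparison:
    def test_identical_waveforms_give_unity_and_zero(self):
        from dendrospike.synth.kernels import APShape
        ap = APShape(amplitude=60.0, ahp_depth=2.0)
        wave = ap.render(FS)
        v = np.full(int(FS), -40.0)
        idx = []
        for t0 in (5000, 15000, 25000, 35000):
            v[t0: t0 + wave.size] += wave
            idx.append(t0 + int(np.argmax(wave)))
        ratio, dv = ahp_comparison(idx[:2], idx[2:], v, FS)
        assert np.isclose(ratio, 1.0, atol=1e-6)
        assert np.isclose(dv, 0.0, atol=1e-6)

    def test_missing_class_skipped(self):
        with pytest.raises(MeasurementSkipped):
            ahp_comparison([], [100], np.zeros(1000), FS)

    def test_generator_repolarization_contrast_recovered(self):
        """Ca2+-spike-evoked APs rendered at 1.29x repolarization rate and
        2.68 mV deeper AHP are recovered from full sweeps."""
        ratios, dvs = [], []
        for k in range(5):
            cfg = scenarios.ahp_comparison_config(
                np.random.default_rng(400 + k), seed=400 + k)
            sweep, _ = generate_sweep(cfg)
            events, _ = detect_and_classify(sweep)
            di = _first(events, "DI_spike")
            baps = [e for e in events if e.label == "bAP"]
            ca = [e.peak_index for e in baps
                  if di.evoked_ap and abs(e.peak_time - di.evoked_ap) < 0.5]
            s = [e.peak_index for e in baps if e.peak_index not in ca]
            r, dv = ahp_comparison(ca, s, sweep.v_dend, sweep.sampling_rate)
            ratios.append(r)
            dvs.append(dv)
        assert abs(np.mean(ratios) - 1.29) < 0.05
        assert abs(np.mean(dvs) - (-2.68)) < 0.3


class TestMetricsTable:
    def test_skip_reasons_reported_not_dropped(self, slow_adp_sweep):
        sweep, _ = slow_adp_sweep
        events, aps = detect_and_classify(sweep)
        df = metrics_table(sweep, events, aps)
        assert len(df) == len(events)
        assert "skip_reason" in df.columns
        adp_rows = df[df.label == "slow_ADP"]
        assert (adp_rows.n_evoked_aps == 3).all()
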
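"""Synthetic generator contracts: kernels, sweeps, linescans, cohorts."""

import numpy as np
import pytest

import dendrospike as ds
from dendrospike.detection import RegenerativeEvent, dvdt_ratio
from dendrospike.recording import Dye, Phenotype, RoiCompartment
from dendrospike.synth import (
    EventClass,
    EventKernelParams,
    LinescanConfig,
    SweepConfigError,
    SynthCohortConfig,
    SynthSweepConfig,
    default_kernel,
    generate_ca_linescan,
    generate_cohort,
    generate_di_amplitude_series,
    generate_sweep,
    render_kernel,
)
from dendrospike.synth.sweeps import GroundTruthEvent

FS = 50_000.0


def _ratio_of_kernel(params):
    """dV/dt ratio of a rendered kernel embedded in a padded trace."""
    wave = render_kernel(params, FS)
    pad = int(0.020 * FS)  # 20 ms of flat baseline
    v = np.concatenate([np.zeros(pad), wave, np.zeros(pad)])
    peak = pad + int(np.argmax(wave))
    ev = RegenerativeEvent(
        onset_index=pad, peak_index=peak, end_index=min(peak + pad, v.size - 1),
        onset_time=0.0, peak_time=0.0, end_time=0.0, peak_vm=0.0,
        amplitude=params.amplitude, dvdt_peak=1.0, dvdt_pre=0.0,
        dvdt_ratio=0.0, latency_from_step=0.0)
    return dvdt_ratio(ev, v, FS)


class TestRenderKernel:
    def test_zero_amplitude_is_all_zero(self):
        p = default_kernel(EventClass.DI_spike, amplitude=0.0)
        assert np.all(render_kernel(p, FS) == 0.0)

    @pytest.mark.parametrize("cls", list(EventClass))
    def test_peak_equals_amplitude_and_decays_out(self, cls):
        p = default_kernel(cls)
        wave = render_kernel(p, FS)
        assert np.isclose(np.max(wave), p.amplitude, rtol=1e-6)
        assert wave[-1] < 0.1 * p.amplitude
        assert wave[0] == 0.0

    def test_abrupt_kernel_fast_initiation(self):
        """Abrupt kernels reach >=80% of peak dV/dt within 0.5 ms."""
        p = EventKernelParams(EventClass.bAP, 80.0, 0.3, 0.9)
        wave = render_kernel(p, FS)
        d = np.gradient(wave, 1000.0 / FS)
        k = int(0.5e-3 * FS)
        assert np.max(d[:k]) >= 0.8 * np.max(d)

    def test_concave_kernel_monotone_accelerating_rise(self):
        p = EventKernelParams(EventClass.DI_spike, 25.0, 4.0, 5.6)
        wave = render_kernel(p, FS)
        rise = wave[: int(p.rise_duration / 1000.0 * FS // 2)]
        d = np.diff(rise)
        assert np.all(np.diff(d) >= -1e-12)  # dV/dt monotonically grows

    def test_abrupt_kernel_low_dvdt_ratio(self):
        p = EventKernelParams(EventClass.bAP, 80.0, 0.3, 0.9)
        assert _ratio_of_kernel(p) < 0.3

    def test_concave_kernel_high_dvdt_ratio(self):
        p = EventKernelParams(EventClass.DI_spike, 25.0, 4.0, 5.6)
        assert _ratio_of_kernel(p) > 0.5

    def test_invalid_arguments_rejected(self):
        p = default_kernel(EventClass.bAP)
        with pytest.raises(ValueError):
            render_kernel(p, -1.0)
        with pytest.raises(ValueError):
            EventKernelParams(EventClass.bAP, 60.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            EventKernelParams(EventClass.DI_spike, 25.0, 4.0, 5.6,
                              onset_shape="abrupt")


class TestGenerateSweep:
    def test_noisefree_empty_schedule_is_deterministic_step(self):
        cfg = SynthSweepConfig(step_amplitude=300.0, noise_sd=0.0, seed=0)
        sweep, truth = generate_sweep(cfg)
        assert truth == []
        pre = sweep.v_dend[sweep.time < cfg.step_onset]
        assert np.allclose(pre, cfg.baseline_vm)
        steady = sweep.v_dend[(sweep.time > 900) & (sweep.time < 1100)]
        expected = cfg.baseline_vm + 105.0 * 300.0 * 1e-3
        assert np.allclose(steady, expected, atol=1e-6)

    def test_di_somatic_counterpart_attenuated(self):
        """A 25 mV DI spike at attenuation 7 appears as ~3.57 mV at soma."""
        di = default_kernel(EventClass.DI_spike, amplitude=25.0)
        cfg = SynthSweepConfig(step_amplitude=400.0, noise_sd=0.0, seed=0,
                               event_schedule=[(di, 400.0)],
                               attenuation={EventClass.DI_spike: 7.0})
        sweep, truth = generate_sweep(cfg)
        assert np.isclose(truth[0].soma_amplitude, 25.0 / 7.0)
        charging = SynthSweepConfig(step_amplitude=400.0, noise_sd=0.0, seed=0)
        base, _ = generate_sweep(charging)
        deflection = np.max(sweep.v_soma - base.v_soma)
        assert np.isclose(deflection, 25.0 / 7.0, rtol=0.01)

    def test_same_seed_bit_identical(self):
        rngs = [np.random.default_rng(5), np.random.default_rng(5)]
        from dendrospike.synth.scenarios import slow_adp_config
        a, _ = generate_sweep(slow_adp_config(rngs[0], seed=9))
        b, _ = generate_sweep(slow_adp_config(rngs[1], seed=9))
        assert np.array_equal(a.v_dend, b.v_dend)
        assert np.array_equal(a.v_soma, b.v_soma)

    def test_overlapping_same_class_events_rejected(self):
        di = default_kernel(EventClass.DI_spike)
        cfg = SynthSweepConfig(step_amplitude=400.0, seed=0,
                               event_schedule=[(di, 400.0), (di, 401.0)])
        with pytest.raises(SweepConfigError):
            generate_sweep(cfg)

    def test_onset_outside_step_rejected(self):
        di = default_kernel(EventClass.DI_spike)
        cfg = SynthSweepConfig(step_amplitude=400.0, seed=0,
                               event_schedule=[(di, 50.0)])
        with pytest.raises(SweepConfigError):
            generate_sweep(cfg)

    def test_label_conservation(self):
        """Every scheduled event appears exactly once in the ground truth
        and contributes a waveform deflection at its peak."""
        from dendrospike.synth.scenarios import make_classification_sweeps
        for sweep, truth in make_classification_sweeps(6, seed=4,
                                                       noise_sd=0.0):
            cfg_flat = SynthSweepConfig(
                step_amplitude=float(sweep.i_inj.max() or sweep.i_inj.min()),
                noise_sd=0.0, seed=0)
            flat, _ = generate_sweep(cfg_flat)
            resid = sweep.v_dend - flat.v_dend
            for gt in truth:
                assert resid[sweep.index_at(gt.peak_ms)] > 0.5 * min(
                    gt.amplitude, 5.0)

    def test_attenuation_consistency_noise_free(self):
        """Dendritic/somatic amplitude ratio equals the configured factor
        to within 1% on noise-free sweeps."""
        for cls in (EventClass.DI_spike, EventClass.fast_ADP):
            k = default_kernel(cls)
            cfg = SynthSweepConfig(step_amplitude=400.0, noise_sd=0.0, seed=0,
                                   event_schedule=[(k, 500.0)])
            sweep, truth = generate_sweep(cfg)
            base, _ = generate_sweep(
                SynthSweepConfig(step_amplitude=400.0, noise_sd=0.0, seed=0))
            d_amp = np.max(sweep.v_dend - base.v_dend)
            s_amp = np.max(sweep.v_soma - base.v_soma)
            assert np.isclose(d_amp / s_amp, cfg.attenuation[cls], rtol=0.01)

    def test_ttx_mode_removes_na_events_and_shrinks_di(self):
        from dendrospike.synth import TTX_CA_FRACTION
        sched = [(default_kernel(EventClass.bAP), 300.0),
                 (default_kernel(EventClass.DI_spike), 500.0)]
        cfg = SynthSweepConfig(step_amplitude=400.0, noise_sd=0.0, seed=0,
                               event_schedule=sched, ttx_mode=True)
        sweep, truth = generate_sweep(cfg)
        assert [gt.event_class for gt in truth] == [EventClass.DI_spike]
        assert np.isclose(truth[0].amplitude, 25.4 * TTX_CA_FRACTION)


class TestDiAmplitudeSeries:
    def test_at_threshold_amplitude_is_a0(self):
        pairs = generate_di_amplitude_series([300.0], 300.0, 25.4, 0.47, 0.0)
        assert np.isclose(pairs[0][1], 25.4)

    def test_one_tau_drive_gives_a0_over_e(self):
        # x = 0.47 with tau = 0.47 -> amplitude = 25.4 / e ~ 9.34 mV
        i = 300.0 * (1 + 0.47)
        pairs = generate_di_amplitude_series([i], 300.0, 25.4, 0.47, 0.0)
        assert np.isclose(pairs[0][1], 25.4 * np.exp(-1.0), atol=1e-9)
        assert np.isclose(pairs[0][1], 9.34, atol=0.01)

    def test_log_linearity(self):
        levels = [300, 360, 420, 480, 540, 600]
        for tau in (0.2, 0.47, 1.5):
            pairs = generate_di_amplitude_series(levels, 300.0, 25.4, tau, 0.0)
            x = (np.array(levels) - 300.0) / 300.0
            y = np.log([p[1] for p in pairs])
            slope = np.polyfit(x, y, 1)[0]
            assert np.isclose(slope, -1.0 / tau, rtol=1e-9)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            generate_di_amplitude_series([300.0], 300.0, 25.4, 0.0, 0.0)


class TestLinescan:
    def test_no_events_flat_dff(self):
        from dendrospike.calcium import dff
        cfg = LinescanConfig(roi_distance=200.0, noise_sd=0.0)
        ls = generate_ca_linescan([], cfg)
        assert np.allclose(dff(ls, 100.0), 0.0)

    def test_fast_spike_restricted_to_subtree(self):
        ev = [GroundTruthEvent(EventClass.DI_spike, 400.0, 412.0, 25.4)]
        same = generate_ca_linescan(ev, LinescanConfig(
            roi_distance=200.0, roi_compartment=RoiCompartment.same_subtree,
            noise_sd=0.0))
        other = generate_ca_linescan(ev, LinescanConfig(
            roi_distance=200.0, roi_compartment=RoiCompartment.other_subtree,
            noise_sd=0.0))
        a_same = np.max(same.fluorescence) - 100.0
        a_other = np.max(other.fluorescence) - 100.0
        assert a_other < 0.2 * a_same

    def test_slow_spike_global_even_in_basal(self):
        ev = [GroundTruthEvent(EventClass.slow_ADP, 400.0, 424.0, 17.2)]
        same = generate_ca_linescan(ev, LinescanConfig(
            roi_distance=200.0, roi_compartment=RoiCompartment.same_subtree,
            noise_sd=0.0))
        basal = generate_ca_linescan(ev, LinescanConfig(
            roi_distance=150.0, roi_compartment=RoiCompartment.basal,
            noise_sd=0.0))
        a_same = np.max(same.fluorescence) - 100.0
        a_basal = np.max(basal.fluorescence) - 100.0
        assert np.isclose(a_basal, a_same, rtol=0.01)

    def test_unknown_dye_rejected(self):
        with pytest.raises(ValueError):
            generate_ca_linescan([], LinescanConfig(roi_distance=0.0,
                                                    dye="fura2"))


class TestCohort:
    def test_zero_sd_gives_exact_means(self):
        morph = {"DI": {"te_coverage": (84.0, 0.0), "trunk_length": (57.0, 0.0),
                        "n_primary_trunks": (1.0, 0.0),
                        "branch_points": (6.0, 0.0),
                        "pipette_distance": (260.0, 0.0)}}
        cells = generate_cohort(SynthCohortConfig(
            n_cells={"DI": 10}, morphology=morph, seed=0))
        assert all(c.te_coverage == 84.0 for c in cells)
        assert all(c.branch_points_to_soma == 6 for c in cells)

    def test_large_cohort_means_near_configured(self):
        """Law of large numbers: continuous morphology means within 2 SEM."""
        cells = generate_cohort(SynthCohortConfig(
            n_cells={"ADP_only": 200, "DI": 200}, seed=0))
        from dendrospike.synth.cohorts import DEFAULT_MORPHOLOGY
        for ph in (Phenotype.ADP_only, Phenotype.DI):
            group = [c for c in cells if c.phenotype is ph]
            for field, get in (("te_coverage", lambda c: c.te_coverage),
                               ("trunk_length", lambda c: c.trunk_length),
                               ("pipette_distance",
                                lambda c: c.pipette_distance)):
                mean, sd = DEFAULT_MORPHOLOGY[ph][field]
                sem = sd / np.sqrt(len(group))
                observed = np.mean([get(c) for c in group])
                # truncation at zero inflates the mean slightly; 2 SEM
                # plus that shift bounds the error
                assert abs(observed - mean) < 2 * sem + 1.0, (ph, field)

    def test_single_trunk_group_is_exactly_one(self):
        cells = generate_cohort(SynthCohortConfig(
            n_cells={"ADP_only": 50}, seed=1))
        assert all(c.n_primary_trunks == 1 for c in cells)

    def test_adp_only_cells_never_contain_di_events(self):
        cells = generate_cohort(SynthCohortConfig(
            n_cells={"ADP_only": 3, "DI": 3}, seed=2, with_sweeps=True,
            sweeps_per_cell=2))
        for c in cells:
            classes = {gt.event_class for gt in c.events}
            if c.phenotype is Phenotype.ADP_only:
                assert EventClass.DI_spike not in classes
            if c.phenotype is Phenotype.DI:
                assert EventClass.DI_spike in classes

    def test_cohort_extension_preserves_earlier_cells(self):
        """Per-cell substreams: growing the cohort never changes cells
        already generated."""
        small = generate_cohort(SynthCohortConfig(n_cells={"DI": 5}, seed=3))
        large = generate_cohort(SynthCohortConfig(n_cells={"DI": 9}, seed=3))
        for a, b in zip(small, large):
            assert a.te_coverage == b.te_coverage
            assert a.branch_points_to_soma == b.branch_points_to_soma

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthCohortConfig(n_cells={"DI": 0})
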
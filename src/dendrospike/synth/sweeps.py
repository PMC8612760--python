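"""Synthetic current-clamp sweep generation with ground-truth labels.

A sweep is assembled as::

    v_dend = baseline + step charging (double exponential) + sum of event
             kernels + white Gaussian noise
    v_soma = baseline + charging * steady-state transfer + somatic event
             counterparts + noise

Somatic counterparts: backpropagating APs are somatic-origin events, so
the soma carries the full AP waveform (leading the dendritic kernel by a
fraction of a millisecond); dendritic-origin events (Na+ spikes, ADPs,
DI spikes) appear at the soma scaled down by a per-class attenuation
factor.

Every scheduled event is recorded in a ground-truth label set (class,
onset, peak, true amplitude), which downstream detection and metric
recovery tests score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..recording import Condition, SweepRecording
from .kernels import (
    APShape,
    EventClass,
    EventKernelParams,
    OnsetShape,
    render_kernel,
)

#: Dendrite->soma amplitude attenuation per dendritic-origin event class.
#: ADP and DI values are the reported dual-recording population means;
#: local Na+ spikes attenuate roughly tenfold.
DEFAULT_ATTENUATION = {
    EventClass.Na_spike: 10.0,
    EventClass.fast_ADP: 5.06,
    EventClass.slow_ADP: 5.06,
    EventClass.DI_spike: 6.97,
}

#: Amplitude fraction of the Ca2+-only DI spike component remaining when
#: Na+ channels are blocked (TTX), from the reported 8.2 / 26.9 mV pair.
TTX_CA_FRACTION = 8.2 / 26.9


class SweepConfigError(ValueError):
    """Raised for invalid synthetic sweep configurations."""


@dataclass
class GroundTruthEvent:
    """True identity and anchors of one rendered event."""

    event_class: EventClass
    onset_ms: float
    peak_ms: float
    amplitude: float  # mV, dendritic
    soma_amplitude: float = 0.0  # mV, somatic counterpart
    evokes_ap: bool = False
    initiated_by_ap: bool = False


@dataclass
class SynthSweepConfig:
    """Configuration of one synthetic sweep.

    Defaults emulate the acquisition protocol of the emulated recordings:
    1-s depolarizing steps digitized at 50 kHz, baseline near -70 mV,
    dendritic input resistance ~105 MOhm.  ``event_schedule`` holds
    (kernel parameters, onset time in sweep ms) pairs; onsets must fall
    inside the step window.  ``ttx_mode`` removes Na+-dependent events
    (bAPs, Na+ spikes) and reduces DI kernels to their Ca2+-only fraction
    while preserving the concave initial rise.
    """

    step_amplitude: float  # pA
    sampling_rate: float = 50_000.0  # Hz
    step_duration: float = 1000.0  # ms
    pre_ms: float = 100.0
    post_ms: float = 100.0
    baseline_vm: float = -70.0  # mV
    noise_sd: float = 0.3  # mV
    attenuation: dict = field(default_factory=lambda: dict(DEFAULT_ATTENUATION))
    event_schedule: list = field(default_factory=list)
    di_amplitude_decay: float = 0.47  # tau of normalized amplitude vs drive
    ttx_mode: bool = False
    ttx_ca_fraction: float = TTX_CA_FRACTION
    seed: int = 0
    # passive model
    input_resistance: float = 105.0  # MOhm
    tau_fast: float = 2.0  # ms, pipette/fast charging component
    tau_slow: float = 25.0  # ms, membrane component
    w_fast: float = 0.3  # weight of the fast charging component
    transfer_ds: float = 0.25  # dendrite->soma steady-state voltage transfer
    transfer_sd: float = 0.60  # soma->dendrite transfer (somatic injection)
    injection_site: str = "dend"
    with_soma: bool = True
    # somatic AP rendering for bAP-class events
    soma_ap: APShape = field(default_factory=lambda: APShape(
        amplitude=100.0, rise_time=0.25, fall_time=1.0, ahp_depth=3.0))
    soma_lead: float = 0.2  # ms the somatic AP peak leads the dendritic bAP
    # optional dendritic AP waveform overrides keyed by the bAP event's
    # ``coupling`` tag (used to emulate AHP differences of Ca-evoked APs)
    dend_ap_shapes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SweepConfigError("sampling_rate must be positive")
        if self.step_duration <= 0:
            raise SweepConfigError("step_duration must be positive")
        for cls, f in self.attenuation.items():
            if f < 1.0:
                raise SweepConfigError(
                    f"attenuation for {cls} must be >= 1 (dendritic origin)")
        if self.injection_site not in ("dend", "soma"):
            raise SweepConfigError("injection_site must be 'dend' or 'soma'")

    @property
    def step_onset(self) -> float:
        return self.pre_ms

    @property
    def step_offset(self) -> float:
        return self.pre_ms + self.step_duration

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.step_duration + self.post_ms


def _charging(t: np.ndarray, onset: float, offset: float, amplitude_mv: float,
              tau_fast: float, tau_slow: float, w_fast: float) -> np.ndarray:
    """Double-exponential step charging/discharging waveform (mV)."""
    w_slow = 1.0 - w_fast
    v = np.zeros_like(t)
    on = (t >= onset) & (t < offset)
    ts = t[on] - onset
    v[on] = amplitude_mv * (1.0 - w_fast * np.exp(-ts / tau_fast)
                            - w_slow * np.exp(-ts / tau_slow))
    after = t >= offset
    v_off = amplitude_mv * (1.0 - w_fast * np.exp(-(offset - onset) / tau_fast)
                            - w_slow * np.exp(-(offset - onset) / tau_slow))
    ta = t[after] - offset
    v[after] = v_off * (w_fast * np.exp(-ta / tau_fast)
                        + w_slow * np.exp(-ta / tau_slow))
    return v


def _add_at(trace: np.ndarray, start_idx: int, waveform: np.ndarray) -> None:
    """Add a waveform into a trace starting at ``start_idx`` (clipped)."""
    if start_idx >= trace.size:
        return
    if start_idx < 0:
        waveform = waveform[-start_idx:]
        start_idx = 0
    end = min(start_idx + waveform.size, trace.size)
    trace[start_idx:end] += waveform[: end - start_idx]


def _validate_schedule(config: SynthSweepConfig) -> None:
    by_class: dict = {}
    for params, onset in config.event_schedule:
        if not (config.step_onset <= onset <= config.step_offset):
            raise SweepConfigError(
                f"event onset {onset} ms outside step window")
        by_class.setdefault(params.event_class, []).append((onset, params))
    for cls, entries in by_class.items():
        entries.sort()
        for (o1, p1), (o2, _p2) in zip(entries, entries[1:]):
            if o2 - o1 < p1.rise_duration:
                raise SweepConfigError(
                    f"overlapping {cls.value} events at {o1} and {o2} ms "
                    "(closer than one rise time)")


def generate_sweep(config: SynthSweepConfig,
                   cell_id: str = "synth",
                   sweep_id: str = "sweep0",
                   ) -> tuple[SweepRecording, list[GroundTruthEvent]]:
    """Render one synthetic sweep and its ground-truth label set.

    Deterministic: identical config + seed give bit-identical traces.
    """
    _validate_schedule(config)
    fs = config.sampling_rate
    dt = 1000.0 / fs
    n = int(round(config.total_ms / dt)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(config.seed)

    i_inj = np.zeros(n)
    on_mask = (t >= config.step_onset) & (t < config.step_offset)
    i_inj[on_mask] = config.step_amplitude

    # passive charging, MOhm * pA * 1e-3 -> mV
    deflection = config.input_resistance * config.step_amplitude * 1e-3
    charge = _charging(t, config.step_onset, config.step_offset, deflection,
                       config.tau_fast, config.tau_slow, config.w_fast)

    if config.injection_site == "dend":
        v_dend = config.baseline_vm + charge
        v_soma = config.baseline_vm + charge * config.transfer_ds
    else:
        v_soma = config.baseline_vm + charge
        v_dend = config.baseline_vm + charge * config.transfer_sd

    schedule = sorted(config.event_schedule, key=lambda e: e[1])
    if config.ttx_mode:
        schedule = [(p, o) for p, o in schedule
                    if p.event_class not in (EventClass.bAP, EventClass.Na_spike)]

    # onset times of bAP events, used to truncate spikes that evoke an AP
    bap_onsets = [o for p, o in schedule if p.event_class is EventClass.bAP]

    truth: list[GroundTruthEvent] = []
    for params, onset in schedule:
        cls = params.event_class
        amp = params.amplitude
        if config.ttx_mode and cls is EventClass.DI_spike:
            amp = amp * config.ttx_ca_fraction
        if cls is EventClass.Na_spike and params.latency_from_step is not None:
            onset = config.step_onset + params.latency_from_step

        if cls is EventClass.bAP:
            shape = config.dend_ap_shapes.get(params.coupling)
            if shape is not None:
                kernel = shape.render(fs)
                peak_ms = onset + shape.peak_latency
                amp = shape.amplitude
            else:
                rp = EventKernelParams(cls, amp, params.rise_time,
                                       params.decay_time)
                kernel = render_kernel(rp, fs)
                peak_ms = onset + rp.rise_duration
            _add_at(v_dend, int(round(onset / dt)), kernel)
            # full somatic AP, peak leading the dendritic counterpart
            soma_wave = config.soma_ap.render(fs)
            soma_start = peak_ms - config.soma_lead - config.soma_ap.peak_latency
            _add_at(v_soma, int(round(soma_start / dt)), soma_wave)
            truth.append(GroundTruthEvent(cls, onset, peak_ms, amp,
                                          config.soma_ap.amplitude))
            continue

        rp = EventKernelParams(cls, amp, params.rise_time, params.decay_time,
                               onset_shape=params.onset_shape,
                               latency_from_step=params.latency_from_step,
                               coupling=params.coupling)
        kernel = render_kernel(rp, fs)
        peak_ms = onset + rp.rise_duration
        evokes = params.coupling == "evokes_ap"
        if evokes and not config.ttx_mode:
            # the evoked AP cuts the spike off: replace the decay beyond the
            # AP onset with a fast release so AP-locked AHP metrics are clean
            nxt = [b for b in bap_onsets if b >= peak_ms]
            if nxt:
                cut = int(round((nxt[0] - onset) / dt))
                if 0 < cut < kernel.size:
                    tail = np.arange(kernel.size - cut) * dt
                    kernel = kernel.copy()
                    kernel[cut:] = kernel[cut] * np.exp(-tail / 0.3)
        _add_at(v_dend, int(round(onset / dt)), kernel)
        att = config.attenuation.get(cls, 1.0)
        _add_at(v_soma, int(round(onset / dt)), kernel / att)
        truth.append(GroundTruthEvent(
            cls, onset, peak_ms, amp, amp / att,
            evokes_ap=evokes,
            initiated_by_ap=params.coupling == "initiated_by_ap"))

    if config.noise_sd > 0:
        v_dend = v_dend + rng.normal(0.0, config.noise_sd, n)
        v_soma = v_soma + rng.normal(0.0, config.noise_sd, n)

    sweep = SweepRecording(
        time=t, v_dend=v_dend, i_inj=i_inj, sampling_rate=fs,
        step_onset=config.step_onset, step_offset=config.step_offset,
        v_soma=v_soma if config.with_soma else None,
        cell_id=cell_id, sweep_id=sweep_id,
        condition=Condition.TTX if config.ttx_mode else Condition.control)
    return sweep, truth


def generate_di_amplitude_series(
        i_inj_levels: Sequence[float], i_threshold: float, a0: float,
        tau: float, noise_sd: float, seed: int = 0,
        ) -> list[tuple[float, float]]:
    """DI spike amplitude across injected-current levels.

    Amplitude follows the exponential decay law observed for DI spikes:
    ``amplitude(I) = a0 * exp(-x / tau)`` with normalized drive
    ``x = (I - i_threshold) / i_threshold``, plus Gaussian noise.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    levels = np.asarray(i_inj_levels, dtype=float)
    if np.any(levels < i_threshold):
        raise ValueError("all i_inj levels must be >= i_threshold")
    if i_threshold <= 0:
        raise ValueError("i_threshold must be positive")
    rng = np.random.default_rng(seed)
    x = (levels - i_threshold) / i_threshold
    amp = a0 * np.exp(-x / tau)
    if noise_sd > 0:
        amp = amp + rng.normal(0.0, noise_sd, levels.size)
    return list(zip(levels.tolist(), amp.tolist()))


def hyperpolarizing_sweep(seed: int = 0, injection_site: str = "dend",
                          step_amplitude: float = -50.0,
                          noise_sd: float = 0.0,
                          **overrides) -> SweepRecording:
    """Convenience 50 pA / 300 ms hyperpolarizing protocol sweep, used for
    input-resistance and voltage-transfer measurements."""
    config = SynthSweepConfig(
        step_amplitude=step_amplitude, step_duration=300.0,
        pre_ms=100.0, post_ms=100.0, noise_sd=noise_sd, seed=seed,
        injection_site=injection_site, **overrides)
    sweep, _ = generate_sweep(config)
    return sweep
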
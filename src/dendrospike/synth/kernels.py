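"""Voltage-event kernels for the synthetic sweep generator.

Two onset families cover the phenomenology of dendritic recordings:

* ``abrupt`` — the sharp initiation ("kink") of backpropagating APs and
  local dendritic Na+ spikes: a raised-cosine rise over ``rise_time``
  followed by exponential decay.  Peak dV/dt occurs mid-rise, well inside
  the first 0.5 ms for sub-millisecond rise times.

* ``concave`` — the gradually accelerating onset of dendritically
  initiated (DI) Ca2+ spikes and afterdepolarizations: an exponential
  ramp v ∝ (e^{t/τ} − 1) over a rise window of 3·``rise_time`` (τ =
  ``rise_time``), so dV/dt grows monotonically through the whole rise,
  then exponential decay with ``decay_time``.  Slow envelopes
  (``decay_time`` > 50 ms) repolarize briefly right after the peak
  before settling into the sustained plateau (a small fast decay
  component), so the envelope peak is a well-defined event anchor
  rather than the corner of a near-flat plateau.

Amplitudes are relative to the local pre-event voltage (kernels start at
0 mV and are added to baseline + step charging).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np


class EventClass(str, Enum):
    bAP = "bAP"
    Na_spike = "Na_spike"
    fast_ADP = "fast_ADP"
    slow_ADP = "slow_ADP"
    DI_spike = "DI_spike"


class OnsetShape(str, Enum):
    abrupt = "abrupt"
    concave = "concave"


#: Onset family per event class.  bAPs and Na+ spikes initiate with a kink;
#: Ca2+-mediated events develop gradually.
ONSET_OF_CLASS = {
    EventClass.bAP: OnsetShape.abrupt,
    EventClass.Na_spike: OnsetShape.abrupt,
    EventClass.fast_ADP: OnsetShape.concave,
    EventClass.slow_ADP: OnsetShape.concave,
    EventClass.DI_spike: OnsetShape.concave,
}


@dataclass
class EventKernelParams:
    """Shape parameters for one rendered event.

    ``rise_time`` is the raised-cosine rise duration for abrupt kernels
    and the exponential ramp time constant for concave kernels (the ramp
    lasts 3 time constants).  ``decay_time`` is the post-peak exponential
    time constant.  ``latency_from_step`` is meaningful for Na+ spikes,
    which ride the initial charging phase of the step.
    """

    event_class: EventClass
    amplitude: float  # mV
    rise_time: float  # ms
    decay_time: float  # ms
    onset_shape: Optional[OnsetShape] = None
    latency_from_step: Optional[float] = None
    coupling: Optional[str] = None  # free-form link, e.g. "evokes_ap"

    def __post_init__(self) -> None:
        self.event_class = EventClass(self.event_class)
        if self.onset_shape is None:
            self.onset_shape = ONSET_OF_CLASS[self.event_class]
        self.onset_shape = OnsetShape(self.onset_shape)
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.rise_time <= 0 or self.decay_time <= 0:
            raise ValueError("rise_time and decay_time must be > 0")
        expected = ONSET_OF_CLASS[self.event_class]
        if self.event_class in (EventClass.bAP, EventClass.Na_spike) \
                and self.onset_shape is not OnsetShape.abrupt:
            raise ValueError(f"{self.event_class.value} must have abrupt onset")
        if self.event_class is EventClass.DI_spike \
                and self.onset_shape is not OnsetShape.concave:
            raise ValueError("DI_spike must have concave onset")
        del expected

    @property
    def rise_duration(self) -> float:
        """Total rise duration in ms (onset to peak)."""
        if self.onset_shape is OnsetShape.abrupt:
            return self.rise_time
        return 3.0 * self.rise_time


def render_kernel(params: EventKernelParams, sampling_rate: float) -> np.ndarray:
    """Render an event waveform at ``sampling_rate`` Hz.

    The waveform starts at 0 mV, peaks at ``params.amplitude`` and decays
    below 10% of the amplitude by the end (the rendered tail spans five
    decay time constants).
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    dt = 1000.0 / sampling_rate  # ms per sample
    rise_dur = params.rise_duration
    total = rise_dur + 5.0 * params.decay_time
    n = max(int(round(total / dt)) + 1, 2)
    t = np.arange(n) * dt
    a = params.amplitude
    if a == 0:
        return np.zeros(n)
    v = np.empty(n)
    rising = t <= rise_dur
    if params.onset_shape is OnsetShape.abrupt:
        v[rising] = a * 0.5 * (1.0 - np.cos(np.pi * t[rising] / rise_dur))
    else:
        tau = params.rise_time
        v[rising] = a * np.expm1(t[rising] / tau) / np.expm1(rise_dur / tau)
    td = t[~rising] - rise_dur
    if params.onset_shape is OnsetShape.concave and params.decay_time > 50.0:
        # slow envelope: brief partial repolarization, then the plateau
        v[~rising] = a * (0.15 * np.exp(-td / 5.0)
                          + 0.85 * np.exp(-td / params.decay_time))
    else:
        v[~rising] = a * np.exp(-td / params.decay_time)
    return v


@dataclass
class APShape:
    """Action-potential waveform parameters, including the fast AHP.

    The repolarization is a raised cosine from peak down to
    ``-ahp_depth`` over ``fall_time``; the AHP then relaxes back with
    ``ahp_recovery_tau``.  Faster repolarization (shorter ``fall_time``)
    and deeper AHP are how Ca2+-spike-evoked APs are emulated.
    """

    amplitude: float = 100.0  # mV above local membrane potential
    rise_time: float = 0.3  # ms
    fall_time: float = 1.2  # ms
    ahp_depth: float = 0.0  # mV below local membrane potential
    ahp_recovery_tau: float = 10.0  # ms

    def render(self, sampling_rate: float) -> np.ndarray:
        dt = 1000.0 / sampling_rate
        total = self.rise_time + self.fall_time + 6.0 * self.ahp_recovery_tau
        n = int(round(total / dt)) + 1
        t = np.arange(n) * dt
        v = np.zeros(n)
        a, d = self.amplitude, self.ahp_depth
        m1 = t <= self.rise_time
        v[m1] = a * 0.5 * (1.0 - np.cos(np.pi * t[m1] / self.rise_time))
        m2 = (t > self.rise_time) & (t <= self.rise_time + self.fall_time)
        phase = (t[m2] - self.rise_time) / self.fall_time
        v[m2] = a - (a + d) * 0.5 * (1.0 - np.cos(np.pi * phase))
        m3 = t > self.rise_time + self.fall_time
        v[m3] = -d * np.exp(-(t[m3] - self.rise_time - self.fall_time)
                            / self.ahp_recovery_tau)
        return v

    @property
    def peak_latency(self) -> float:
        """Time from waveform start to AP peak, ms."""
        return self.rise_time


# Default kernel parameter sets per event class.  Amplitudes follow the
# population means reported for distal CA3 trunk recordings (fast ADP
# 16.2 mV, DI spike 25.4 mV at threshold drive); kinetics are set so the
# rendered half-widths land in each class's reported range (DI ~6.4 ms,
# fast Ca2+ spikes < 20 ms, slow ADPs ≫ 60 ms).
DEFAULT_KERNELS = {
    EventClass.bAP: dict(amplitude=60.0, rise_time=0.3, decay_time=0.9),
    EventClass.Na_spike: dict(amplitude=30.0, rise_time=0.3, decay_time=1.2),
    EventClass.fast_ADP: dict(amplitude=16.2, rise_time=2.5, decay_time=8.0),
    EventClass.slow_ADP: dict(amplitude=17.2, rise_time=8.0, decay_time=220.0),
    EventClass.DI_spike: dict(amplitude=25.4, rise_time=4.0, decay_time=5.6),
}


def default_kernel(event_class: EventClass, **overrides) -> EventKernelParams:
    """Kernel parameters for an event class at package defaults."""
    event_class = EventClass(event_class)
    kw = dict(DEFAULT_KERNELS[event_class])
    kw.update(overrides)
    return EventKernelParams(event_class=event_class, **kw)
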
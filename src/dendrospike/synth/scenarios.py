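"""Canonical sweep scenarios used for end-to-end verification.

Each scenario builds a :class:`SynthSweepConfig` whose event schedule
realizes one behavioural motif of the emulated recordings: trains of
backpropagating APs, short-latency local Na+ spikes, fast and slow
(burst-driving) ADPs, and DI spikes with or without an evoked AP.  The
scenarios drive the classification-accuracy and metric-recovery studies.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .kernels import APShape, EventClass, default_kernel
from .sweeps import GroundTruthEvent, SynthSweepConfig, generate_sweep

_BAP_RISE = 0.3  # ms; dendritic bAP kernel rise (peak = onset + rise)


def _cfg(step_pa: float, schedule: list, seed: int,
         noise_sd: float = 0.3, **kw) -> SynthSweepConfig:
    return SynthSweepConfig(step_amplitude=step_pa, event_schedule=schedule,
                            seed=seed, noise_sd=noise_sd, **kw)


def bap_train_config(rng: np.random.Generator, seed: int,
                     noise_sd: float = 0.3) -> SynthSweepConfig:
    """3-5 bAPs evoked across the step."""
    n = int(rng.integers(3, 6))
    t = 100.0 + float(rng.uniform(15.0, 40.0))
    sched = []
    for _ in range(n):
        sched.append((default_kernel(EventClass.bAP), t))
        t += float(rng.uniform(45.0, 90.0))
    return _cfg(300.0, sched, seed, noise_sd)


def na_spike_config(rng: np.random.Generator, seed: int,
                    noise_sd: float = 0.3) -> SynthSweepConfig:
    """Short-latency local Na+ spike on the charging phase, later bAPs."""
    lat = float(rng.uniform(2.0, 5.0))
    sched = [(default_kernel(EventClass.Na_spike, latency_from_step=lat),
              100.0 + lat)]
    t = 100.0 + float(rng.uniform(60.0, 120.0))
    for _ in range(2):
        sched.append((default_kernel(EventClass.bAP), t))
        t += float(rng.uniform(60.0, 120.0))
    return _cfg(700.0, sched, seed, noise_sd)


def fast_adp_config(rng: np.random.Generator, seed: int,
                    noise_sd: float = 0.3) -> SynthSweepConfig:
    """A bAP followed by a transient fast ADP with a clear peak."""
    t0 = 100.0 + float(rng.uniform(150.0, 550.0))
    sched = [
        (default_kernel(EventClass.bAP), t0),
        (default_kernel(EventClass.fast_ADP, coupling="initiated_by_ap"),
         t0 + _BAP_RISE + 1.0),
        (default_kernel(EventClass.bAP), t0 + float(rng.uniform(180.0, 260.0))),
    ]
    return _cfg(300.0, sched, seed, noise_sd)


def slow_adp_config(rng: np.random.Generator, seed: int,
                    noise_sd: float = 0.3,
                    evoked_ap_offsets: tuple = (40.0, 80.0, 120.0),
                    ) -> SynthSweepConfig:
    """An initiating bAP whose sustained slow ADP drives a burst of APs."""
    t0 = 100.0 + float(rng.uniform(150.0, 400.0))
    sched = [
        (default_kernel(EventClass.bAP), t0),
        (default_kernel(EventClass.slow_ADP, coupling="initiated_by_ap"),
         t0 + _BAP_RISE + 1.0),
    ]
    for off in evoked_ap_offsets:
        sched.append((default_kernel(EventClass.bAP),
                      t0 + off + float(rng.uniform(-3.0, 3.0))))
    return _cfg(300.0, sched, seed, noise_sd)


def di_config(rng: np.random.Generator, seed: int, noise_sd: float = 0.3,
              evoke_ap: bool = False, step_pa: float = 500.0,
              ttx_mode: bool = False) -> SynthSweepConfig:
    """An isolated DI spike, optionally evoking a tightly coupled AP."""
    t0 = 100.0 + float(rng.uniform(120.0, 700.0))
    di = default_kernel(EventClass.DI_spike,
                        coupling="evokes_ap" if evoke_ap else None)
    sched = [(di, t0)]
    if evoke_ap:
        peak = t0 + di.rise_duration
        sched.append((default_kernel(EventClass.bAP, coupling="ca_ap"),
                      peak + 3.0))
    return _cfg(step_pa, sched, seed, noise_sd, ttx_mode=ttx_mode)


SCENARIOS = ("bap_train", "na_spike", "fast_adp", "slow_adp", "di",
             "di_evoke")


def scenario_config(name: str, rng: np.random.Generator, seed: int,
                    noise_sd: float = 0.3) -> SynthSweepConfig:
    if name == "bap_train":
        return bap_train_config(rng, seed, noise_sd)
    if name == "na_spike":
        return na_spike_config(rng, seed, noise_sd)
    if name == "fast_adp":
        return fast_adp_config(rng, seed, noise_sd)
    if name == "slow_adp":
        return slow_adp_config(rng, seed, noise_sd)
    if name == "di":
        return di_config(rng, seed, noise_sd)
    if name == "di_evoke":
        return di_config(rng, seed, noise_sd, evoke_ap=True)
    raise ValueError(f"unknown scenario {name!r}")


def make_classification_sweeps(n_sweeps: int, seed: int,
                               noise_sd: float = 0.3) -> list:
    """Sweeps cycling through all scenarios, with per-sweep ground truth.

    Returns a list of (SweepRecording, [GroundTruthEvent]) pairs.  The
    per-sweep random streams derive from (seed, sweep index), so the set
    is reproducible and extensible.
    """
    out = []
    for i in range(n_sweeps):
        name = SCENARIOS[i % len(SCENARIOS)]
        rng = np.random.default_rng([seed, i])
        cfg = scenario_config(name, rng, seed=int(rng.integers(2 ** 31)),
                              noise_sd=noise_sd)
        sweep, truth = generate_sweep(cfg, sweep_id=f"{name}_{i:04d}")
        out.append((sweep, truth))
    return out


# ---------------------------------------------------------------------------
# AHP-comparison scenario
# ---------------------------------------------------------------------------

#: simple (s-AP) dendritic AP shape in the AHP scenario
S_AP_SHAPE = APShape(amplitude=60.0, rise_time=0.3, fall_time=1.2,
                     ahp_depth=2.0, ahp_recovery_tau=30.0)

#: Ca2+-spike-evoked AP: repolarization rate 1.29x that of the s-AP and
#: AHP deeper by 2.68 mV.  fall_time solves
#: (A + d_ca)/f_ca = 1.29 * (A + d_s)/f_s for the raised-cosine fall.
_D_CA = S_AP_SHAPE.ahp_depth + 2.68
_F_CA = (S_AP_SHAPE.fall_time
         * (S_AP_SHAPE.amplitude + _D_CA)
         / ((S_AP_SHAPE.amplitude + S_AP_SHAPE.ahp_depth) * 1.29))
CA_AP_SHAPE = APShape(amplitude=60.0, rise_time=0.3, fall_time=_F_CA,
                      ahp_depth=_D_CA, ahp_recovery_tau=30.0)


def ahp_comparison_config(rng: np.random.Generator, seed: int,
                          noise_sd: float = 0.3) -> SynthSweepConfig:
    """One DI spike evoking an AP (Ca-AP) plus a later simple AP (s-AP),
    both at the same injection level, for AHP/repolarization comparison.

    The DI kernel uses a fast decay here so the spike is clearly
    separable from the AP it evokes.
    """
    t0 = 100.0 + float(rng.uniform(150.0, 350.0))
    di = default_kernel(EventClass.DI_spike, decay_time=2.0,
                        coupling="evokes_ap")
    peak = t0 + di.rise_duration
    t_s = t0 + float(rng.uniform(350.0, 500.0))
    sched = [
        (di, t0),
        (default_kernel(EventClass.bAP, coupling="ca_ap"), peak + 3.5),
        (default_kernel(EventClass.bAP, coupling="s_ap"), t_s),
    ]
    return _cfg(500.0, sched, seed, noise_sd,
                dend_ap_shapes={"ca_ap": CA_AP_SHAPE, "s_ap": S_AP_SHAPE})
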
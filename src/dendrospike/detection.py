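"""Detection and classification of regenerative dendritic events.

The classifier implements the decision sequence used to sort depolarizing
dendritic events into five classes:

1. **bAP** — event coincident with a somatic AP (within a small window)
   showing the sharp initiation kink, i.e. a low dV/dt ratio.
2. **Na+ spike** — abrupt-onset event at very short latency (< 7 ms) from
   step onset with no preceding somatic AP.
3. **fast / slow ADP** — event whose onset follows a bAP peak within a
   short coupling window, adding a distinct voltage peak; "slow" when the
   sustained depolarization outlasts the class boundary (default 50 ms).
4. **DI spike** — concave-onset event (high dV/dt ratio) with no
   initiating AP.
5. **unclassified** — anything else; never guessed.

The dV/dt ratio is ``dvdt_pre / dvdt_peak`` where ``dvdt_peak`` is the
maximum dV/dt during the event and ``dvdt_pre`` the maximum in the 1.5–9
ms window preceding the time of ``dvdt_peak``.  Abrupt onsets give ratios
near zero, gradually developing onsets give large ratios.

Detection runs in two passes on the charging-subtracted trace: a fast
pass for spike-like events (light smoothing) and a slow pass on an
AP-excised, smoothed trace for ADP envelopes, whose rise is too gradual
to pass the fast pass's dV/dt gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .recording import SweepRecording, binomial_smooth
from .synth.kernels import EventClass


# labels reuse EventClass values plus 'unclassified'
UNCLASSIFIED = "unclassified"


@dataclass
class SomaticAP:
    """A detected somatic action potential."""

    peak_index: int
    peak_time: float  # ms
    peak_vm: float  # mV


@dataclass
class RegenerativeEvent:
    """A detected depolarizing event with its anchors and features.

    Indices refer to samples of the sweep the event was detected on.
    ``amplitude`` is the baseline-subtracted peak height (prominence over
    the detected onset), used for classification only — quantitative
    amplitudes follow the measurement conventions in ``metrics``.
    """

    onset_index: int
    peak_index: int
    end_index: int
    onset_time: float
    peak_time: float
    end_time: float
    peak_vm: float
    amplitude: float
    dvdt_peak: float
    dvdt_pre: float
    dvdt_ratio: float
    latency_from_step: float
    label: str = UNCLASSIFIED
    initiating_ap: Optional[float] = None  # peak time (ms) of initiating AP
    evoked_ap: Optional[float] = None  # peak time (ms) of evoked AP
    sustained_ms: Optional[float] = None  # above-half duration, AP-excised
    secondary_peaks: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.onset_index < self.peak_index <= self.end_index):
            raise ValueError("require onset_index < peak_index <= end_index")


@dataclass
class DetectionParams:
    """Tunable parameters of detection and classification.

    The kink threshold on the dV/dt ratio (default 0.35) separates
    abrupt-onset events (bAPs, Na+ spikes; ratio near 0) from concave
    Ca2+-spike onsets (ratio well above 0.5); the boundary is a
    calibration choice and configurable.  Window defaults (bAP
    coincidence ±2 ms, ADP coupling 15 ms, fast/slow boundary 50 ms,
    Na+-spike latency 7 ms) follow the event taxonomy the classifier
    reproduces.
    """

    prominence: float = 2.0  # mV
    min_pre_dvdt: float = 1.0  # V/s gate within 10 ms before a fast peak
    pre_dvdt_window_ms: float = 10.0
    onset_fraction: float = 0.05
    onset_floor_fast: float = 0.3  # V/s
    onset_floor_slow: float = 0.08  # V/s
    refractory_ms: float = 2.0
    ap_dvdt_threshold: float = 20.0  # V/s, somatic AP detection
    ap_peak_min: float = -20.0  # mV
    kink_threshold: float = 0.35
    bap_coincidence_ms: float = 2.0
    adp_window_ms: float = 15.0
    slow_adp_boundary_ms: float = 50.0
    na_latency_ms: float = 7.0
    evoked_ap_window_ms: float = 4.0
    ap_like_amplitude: float = 35.0  # mV, dendritic AP-like events
    ap_like_width_ms: float = 6.0
    # smoothing scales
    fast_smooth_passes: int = 2  # binomial passes before fast peak finding
    slow_trace_sigma_ms: float = 0.2
    deriv_sigma_fast_ms: float = 0.2
    deriv_sigma_slow_ms: float = 1.5
    deriv_scale_switch: float = 20.0  # V/s: below, use the slow deriv scale
    pre_window_ms: tuple = (1.5, 9.0)
    max_lookback_ms: float = 150.0
    subtract_charging: bool = True
    restrict_to_step: bool = True  # only events peaking within the step


class UndefinedRatioError(ValueError):
    """dV/dt ratio undefined (non-positive peak derivative)."""


# ---------------------------------------------------------------------------
# charging model subtraction
# ---------------------------------------------------------------------------

def fit_step_charging(sweep: SweepRecording, trace: Optional[np.ndarray] = None,
                      exclude: Optional[np.ndarray] = None) -> np.ndarray:
    """Robustly fit the passive double-exponential step response.

    Returns the fitted passive trace (baseline + charging) over the full
    sweep.  Fast spikes are masked structurally (by their extreme dV/dt)
    before fitting; remaining positive deviations (event envelopes and
    their decay tails) are trimmed one-sidedly between fit iterations.
    ``exclude`` optionally marks known event spans (boolean, True =
    drop) from a previous detection round.
    """
    v = sweep.v_dend if trace is None else np.asarray(trace, float)
    t = sweep.time
    on, off = sweep.step_onset, sweep.step_offset
    dt = 1000.0 / sweep.sampling_rate
    pre = t < on - 1.0
    v0 = float(np.mean(v[pre])) if np.any(pre) else float(v[0])
    noise = float(np.std(v[pre] - v0)) if np.any(pre) else 0.3

    # structural spike mask: fast events have |dV/dt| far beyond any
    # passive charging; mask them (with margin) before any fitting
    d = gaussian_filter1d(v, sigma=max(0.2 / dt, 1.0), order=1) / dt
    spike = np.abs(d) >= 5.0
    spike[t < on] = False
    spike[(t >= on) & (t < on + 1.0)] = False  # charging kink is fast too
    spike[(t >= off) & (t < off + 1.0)] = False
    dil = int(round(8.0 / dt))
    if np.any(spike):
        idx = np.nonzero(spike)[0]
        grow = np.zeros(v.size, dtype=bool)
        for i in idx[:: max(dil // 4, 1)]:
            grow[max(i - dil, 0): i + dil] = True
        grow[idx] = True
        structural = ~grow
    else:
        structural = np.ones(v.size, dtype=bool)

    if exclude is not None:
        structural &= ~np.asarray(exclude, dtype=bool)
    stride = max(int(round(sweep.sampling_rate / 5000.0)), 1)
    tb, vb, kb = t[::stride], v[::stride], structural[::stride]

    # steady-state amplitude pinned robustly: regenerative events deflect
    # upward only, so a low percentile of the late-step spike-masked trace
    # tracks the passive plateau (corrected for the percentile's noise bias)
    late = (tb >= on + (off - on) / 2) & (tb < off) & kb
    if np.any(late):
        a_est = float(np.percentile(vb[late], 10) + 1.2816 * noise - v0)
    else:
        # fall back to the latest unmasked step samples (past the fast
        # charging), still with the low-percentile event guard
        step_kb = (tb >= on + 150.0) & (tb < off) & kb
        if not np.any(step_kb):
            step_kb = (tb >= on + 150.0) & (tb < off)
        a_est = float(np.percentile(vb[step_kb], 10) + 1.2816 * noise - v0)

    def model(p, tt):
        a, wf, tf, ts = p
        wf = np.clip(wf, 0.0, 1.0)
        out = np.full_like(tt, v0)
        onm = (tt >= on) & (tt < off)
        x = tt[onm] - on
        out[onm] += a * (1 - wf * np.exp(-x / tf)
                         - (1 - wf) * np.exp(-x / ts))
        after = tt >= off
        a_off = a * (1 - wf * np.exp(-(off - on) / tf)
                     - (1 - wf) * np.exp(-(off - on) / ts))
        xa = tt[after] - off
        out[after] += a_off * (wf * np.exp(-xa / tf) + (1 - wf) * np.exp(-xa / ts))
        return out

    p0 = np.array([a_est, 0.3, 2.0, 25.0])
    bounds = ([a_est - 10.0, 0.0, 0.05, 5.0], [a_est + 10.0, 1.0, 20.0, 500.0])
    p = p0
    thr = max(0.5, 3.0 * noise)
    try:
        keep = kb.copy()
        for _ in range(4):
            if keep.sum() < max(50, vb.size // 10):
                break
            res = least_squares(lambda q: model(q, tb[keep]) - vb[keep], p,
                                bounds=bounds, loss="soft_l1", f_scale=0.5,
                                max_nfev=200)
            p = res.x
            # one-sided trim: drop samples above the fit (event envelopes
            # and tails); never drop samples below it
            resid_b = vb - model(p, tb)
            keep = kb & (resid_b < thr)
    except Exception:  # fit failure: fall back to the last estimate
        pass
    return model(p, t)


# ---------------------------------------------------------------------------
# somatic AP detection
# ---------------------------------------------------------------------------

def detect_somatic_aps(v_soma: np.ndarray, sampling_rate: float,
                       params: Optional[DetectionParams] = None,
                       t0: float = 0.0) -> list[SomaticAP]:
    """Locate somatic action potentials.

    APs are voltage peaks exceeding ``ap_peak_min`` whose immediately
    preceding rise crosses the dV/dt threshold (default 20 V/s); peaks
    closer than the refractory merge window collapse to the larger one.
    """
    params = params or DetectionParams()
    v = np.asarray(v_soma, dtype=float)
    if v.size < 3:
        return []
    dt = 1000.0 / sampling_rate
    sm = binomial_smooth(v, 2)
    d = gaussian_filter1d(sm, sigma=max(params.deriv_sigma_fast_ms / dt, 1.0),
                          order=1) / dt
    dist = max(int(round(params.refractory_ms / dt)), 1)
    peaks, _ = find_peaks(sm, height=params.ap_peak_min, distance=dist,
                          prominence=10.0)
    out = []
    pre = int(round(1.5 / dt))
    for p in peaks:
        lo = max(p - pre, 0)
        if np.max(d[lo: p + 1]) >= params.ap_dvdt_threshold:
            out.append(SomaticAP(int(p), t0 + p * dt, float(v[p])))
    return out


# ---------------------------------------------------------------------------
# candidate event detection
# ---------------------------------------------------------------------------

def _backtrack_onset(d: np.ndarray, peak_d_idx: int, floor: float,
                     left_limit: int, sustain: int = 1) -> int:
    """Walk left from the dV/dt peak until the derivative stays below the
    floor for ``sustain`` consecutive samples; returns the onset index.

    The sustain requirement keeps single noise dips in the derivative
    from truncating the onset of gradually rising events.
    """
    i = peak_d_idx
    below = 0
    while i > left_limit:
        if d[i - 1] < floor:
            below += 1
            if below >= sustain:
                return i + below - 1
        else:
            below = 0
        i -= 1
    return max(i + below, left_limit)


def _event_from_peak(resid_sm: np.ndarray, d_fast: np.ndarray,
                     d_slow: np.ndarray, peak: int, left_base: int,
                     sweep: SweepRecording, params: DetectionParams,
                     next_peak: Optional[int],
                     prev_peak: Optional[int] = None,
                     ) -> Optional[RegenerativeEvent]:
    dt = sweep.dt
    lookback = int(round(params.max_lookback_ms / dt))
    lo = max(left_base, peak - lookback, 0)
    if prev_peak is not None and prev_peak >= lo:
        # never search past the preceding event: anchor at the valley
        valley = prev_peak + int(np.argmin(resid_sm[prev_peak: peak + 1]))
        lo = max(lo, valley)
    if peak - lo < 2:
        return None
    seg_fast = d_fast[lo: peak + 1]
    dvdt_peak_fast = float(np.max(seg_fast))
    use_fast = dvdt_peak_fast >= params.deriv_scale_switch
    d = d_fast if use_fast else d_slow
    seg = d[lo: peak + 1]
    pk_rel = int(np.argmax(seg))
    dvdt_peak = float(seg[pk_rel])
    if dvdt_peak <= 0:
        return None
    pk_d = lo + pk_rel
    floor = max(params.onset_fraction * dvdt_peak,
                params.onset_floor_fast if use_fast else params.onset_floor_slow)
    sustain = max(int(round((0.2 if use_fast else 2.0) / dt)), 1)
    onset = _backtrack_onset(d, pk_d, floor, lo, sustain=sustain)
    if onset >= peak:
        onset = max(peak - 1, 0)

    # pre-event window for the dV/dt ratio
    w0, w1 = params.pre_window_ms
    i0 = pk_d - int(round(w1 / dt))
    i1 = pk_d - int(round(w0 / dt))
    flags = []
    if i0 < 0:
        i0, flags = 0, ["pre_window_truncated"]
    dvdt_pre = float(np.max(d[i0:i1])) if i1 > i0 else 0.0
    ratio = dvdt_pre / dvdt_peak

    amp = float(resid_sm[peak] - resid_sm[onset])
    half = resid_sm[onset] + amp / 2.0
    stop = next_peak if next_peak is not None else resid_sm.size
    below = np.nonzero(resid_sm[peak:stop] < half)[0]
    end = peak + int(below[0]) if below.size else min(stop - 1, resid_sm.size - 1)
    end = max(end, peak)
    if end == peak:
        end = min(peak + 1, resid_sm.size - 1)

    ev = RegenerativeEvent(
        onset_index=int(onset), peak_index=int(peak), end_index=int(end),
        onset_time=float(sweep.time[onset]), peak_time=float(sweep.time[peak]),
        end_time=float(sweep.time[end]), peak_vm=float(sweep.v_dend[peak]),
        amplitude=amp, dvdt_peak=dvdt_peak, dvdt_pre=dvdt_pre,
        dvdt_ratio=ratio,
        latency_from_step=float(sweep.time[onset] - sweep.step_onset),
        flags=flags)
    return ev


def detect_candidate_events(sweep: SweepRecording,
                            params: Optional[DetectionParams] = None,
                            ) -> list[RegenerativeEvent]:
    """Detect candidate regenerative events on the dendritic trace.

    Two passes on the charging-subtracted trace: a fast pass (light
    binomial smoothing, prominence and preceding-dV/dt gates) for
    spike-like events, then a slow pass on an AP-excised,
    Gaussian-smoothed trace for gradual ADP envelopes.  When slow
    envelope events are found, the passive charging fit is repeated with
    the detected event spans excluded (their long decay tails otherwise
    bias the fit) and detection reruns on the refined residual.  Merged
    peaks closer than the refractory window surface as one event with
    secondary-peak annotations.
    """
    params = params or DetectionParams()
    dt = sweep.dt
    v = sweep.v_dend
    sig_f = max(params.deriv_sigma_fast_ms / dt, 0.5)
    sig_s = max(params.deriv_sigma_slow_ms / dt, 1.0)
    dist = max(int(round(params.refractory_ms / dt)), 1)
    refr = dist
    gate = int(round(params.pre_dvdt_window_ms / dt))
    i_on = int(round((sweep.step_onset - sweep.time[0]) / dt))
    i_off = int(round((sweep.step_offset - sweep.time[0]) / dt))

    def run_passes(resid):
        sm = binomial_smooth(resid, params.fast_smooth_passes)
        d_fast = gaussian_filter1d(resid, sigma=sig_f, order=1) / dt
        d_slow = gaussian_filter1d(resid, sigma=sig_s, order=1) / dt
        peaks, props = find_peaks(sm, prominence=params.prominence,
                                  distance=dist)
        # fast-pass gate: a dV/dt excursion must precede the peak
        keep, bases = [], []
        for p, lb in zip(peaks, props["left_bases"]):
            if params.restrict_to_step and not (i_on <= p <= i_off):
                continue
            lo = max(p - gate, 0)
            if np.max(d_fast[lo: p + 1]) >= params.min_pre_dvdt:
                keep.append(int(p))
                bases.append(int(lb))

        events: list[RegenerativeEvent] = []
        for i, (p, lb) in enumerate(zip(keep, bases)):
            nxt = keep[i + 1] if i + 1 < len(keep) else None
            prv = keep[i - 1] if i > 0 else None
            ev = _event_from_peak(sm, d_fast, d_slow, p, lb, sweep, params,
                                  nxt, prev_peak=prv)
            if ev is not None:
                events.append(ev)

        # slow pass: excise AP-like events, re-smooth, find envelopes
        ap_like = [e for e in events
                   if e.amplitude >= params.ap_like_amplitude
                   and (e.end_time - e.onset_time) <= params.ap_like_width_ms]
        excised = resid.copy()
        for e in ap_like:
            a = max(e.onset_index - int(round(0.2 / dt)), 0)
            b = min(e.peak_index + int(round(4.0 / dt)), resid.size - 1)
            excised[a: b + 1] = np.linspace(excised[a], excised[b], b - a + 1)
        sm_slow = gaussian_filter1d(
            excised, sigma=max(params.slow_trace_sigma_ms / dt, 1.0))
        d_slow_x = gaussian_filter1d(excised, sigma=sig_s, order=1) / dt
        d_fast_x = gaussian_filter1d(excised, sigma=sig_f, order=1) / dt

        peaks2, props2 = find_peaks(sm_slow, prominence=params.prominence,
                                    distance=dist)
        taken = np.zeros(resid.size, dtype=bool)
        for e in events:
            taken[e.onset_index: e.end_index + 1] = True
        for p, lb in zip(peaks2, props2["left_bases"]):
            if params.restrict_to_step and not (i_on <= p <= i_off):
                continue
            if taken[p] or any(abs(p - e.peak_index) <= refr for e in events):
                continue
            ev = _event_from_peak(sm_slow, d_fast_x, d_slow_x, int(p),
                                  int(lb), sweep, params, None)
            if ev is not None:
                ev.flags.append("slow_pass")
                events.append(ev)

        # drop fit-wiggle artifacts whose onset-to-peak height falls
        # below the prominence requirement
        events = [e for e in events if e.amplitude >= params.prominence]
        events.sort(key=lambda e: e.peak_index)

        # sustained depolarization duration on the AP-excised trace: time
        # the event stays above half amplitude, not clipped by riding
        # APs; this drives the fast/slow ADP boundary
        for e in events:
            if e in ap_like:
                continue
            base = sm_slow[e.onset_index]
            pk = sm_slow[e.onset_index + int(np.argmax(
                sm_slow[e.onset_index: max(e.end_index, e.peak_index) + 1]))]
            half = base + (pk - base) / 2.0
            below = np.nonzero(sm_slow[e.peak_index:] < half)[0]
            stop = (e.peak_index + int(below[0]) if below.size
                    else sm_slow.size - 1)
            e.sustained_ms = float((stop - e.onset_index) * dt)

        # secondary-peak annotation inside each event span
        for e in events:
            seg = sm[e.onset_index: e.end_index + 1]
            if seg.size >= 3:
                sub, _ = find_peaks(seg, prominence=params.prominence)
                extra = [int(s + e.onset_index) for s in sub
                         if s + e.onset_index != e.peak_index]
                e.secondary_peaks = extra
        return events

    if not params.subtract_charging:
        baseline = np.full_like(v, np.mean(v[sweep.time < sweep.step_onset]))
        return run_passes(v - baseline)

    charge = fit_step_charging(sweep)
    events = run_passes(v - charge)

    slow = [e for e in events if e.sustained_ms is not None
            and e.sustained_ms > params.slow_adp_boundary_ms]
    if slow:
        # long envelopes and their tails bias the passive fit; refit with
        # the slow spans excluded (fast events are already handled by the
        # structural spike mask) and run detection once more
        exclude = np.zeros(v.size, dtype=bool)
        for e in slow:
            exclude[max(e.onset_index - int(round(2.0 / dt)), 0):] = True
        charge = fit_step_charging(sweep, exclude=exclude)
        events = run_passes(v - charge)
    return events


# ---------------------------------------------------------------------------
# dV/dt ratio (standalone operation)
# ---------------------------------------------------------------------------

def dvdt_ratio(event: RegenerativeEvent, v_dend: np.ndarray,
               sampling_rate: float,
               pre_window_ms: tuple = (1.5, 9.0),
               deriv_sigma_ms: float = 0.2) -> float:
    """dV/dt ratio of an event computed on a given voltage trace.

    ``dvdt_peak`` is the maximum (smoothed) dV/dt between event onset and
    peak; ``dvdt_pre`` the maximum in the ``pre_window_ms`` window before
    the time of ``dvdt_peak``.  The window is truncated (and flagged on
    the event) if the event sits too close to the trace start.
    """
    v = np.asarray(v_dend, dtype=float)
    dt = 1000.0 / sampling_rate
    d = gaussian_filter1d(v, sigma=max(deriv_sigma_ms / dt, 0.5), order=1) / dt
    seg = d[event.onset_index: event.peak_index + 1]
    if seg.size == 0 or np.max(seg) <= 0:
        raise UndefinedRatioError("non-positive peak dV/dt")
    pk_d = event.onset_index + int(np.argmax(seg))
    dvdt_peak = float(d[pk_d])
    i0 = pk_d - int(round(pre_window_ms[1] / dt))
    i1 = pk_d - int(round(pre_window_ms[0] / dt))
    if i0 < 0:
        i0 = 0
        if "pre_window_truncated" not in event.flags:
            event.flags.append("pre_window_truncated")
    if i1 <= i0:
        return 0.0
    return float(np.max(d[i0:i1]) / dvdt_peak)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_events(events: Sequence[RegenerativeEvent],
                    somatic_aps: Optional[Sequence[SomaticAP]],
                    sweep: SweepRecording,
                    params: Optional[DetectionParams] = None,
                    ) -> list[RegenerativeEvent]:
    """Assign class labels to detected events (in place; returns the list).

    Applies the decision sequence documented at module level.  When no
    somatic trace is available, bAP identification falls back to the kink
    criterion plus an AP-like amplitude/width requirement; repetition
    stereotypy can be checked across sweeps with
    :func:`classify_sweep_set`.
    """
    params = params or DetectionParams()
    events = sorted(events, key=lambda e: e.peak_index)
    ap_times = [ap.peak_time for ap in somatic_aps] if somatic_aps else None

    # pass 1: bAPs
    for ev in events:
        if ap_times is not None:
            if any(abs(t - ev.peak_time) <= params.bap_coincidence_ms
                   for t in ap_times) \
                    and ev.dvdt_ratio < params.kink_threshold:
                ev.label = EventClass.bAP.value
        else:
            width = ev.end_time - ev.onset_time
            if (ev.dvdt_ratio < params.kink_threshold
                    and ev.amplitude >= params.ap_like_amplitude
                    and width <= params.ap_like_width_ms):
                ev.label = EventClass.bAP.value
                ev.flags.append("bap_fallback_no_soma")

    bap_peaks = [ev.peak_time for ev in events
                 if ev.label == EventClass.bAP.value]
    initiator_peaks = sorted(set((ap_times or []) + bap_peaks))

    for ev in events:
        if ev.label != UNCLASSIFIED:
            continue
        # pass 2: local Na+ spikes on the initial charging phase
        preceded = any(t < ev.peak_time - params.bap_coincidence_ms
                       for t in initiator_peaks)
        if (0 <= ev.latency_from_step < params.na_latency_ms
                and ev.dvdt_ratio < params.kink_threshold and not preceded):
            ev.label = EventClass.Na_spike.value
            continue
        # pass 3: ADPs — onset tightly follows an initiating AP.  A small
        # negative lower bound tolerates onsets backtracked into the
        # initiating AP's own span.
        init = [t for t in initiator_peaks
                if -2.5 <= ev.onset_time - t <= params.adp_window_ms]
        if init:
            sustained = (ev.sustained_ms if ev.sustained_ms is not None
                         else ev.end_time - ev.onset_time)
            ev.label = (EventClass.slow_ADP.value
                        if sustained > params.slow_adp_boundary_ms
                        else EventClass.fast_ADP.value)
            ev.initiating_ap = init[-1]
            continue
        # pass 4: DI spikes — concave onset, no initiating AP
        if ev.dvdt_ratio >= params.kink_threshold:
            ev.label = EventClass.DI_spike.value

    # evoked-AP annotation for DI spikes
    for ev in events:
        if ev.label == EventClass.DI_spike.value:
            evoked = [t for t in initiator_peaks
                      if 0.0 < t - ev.peak_time <= params.evoked_ap_window_ms]
            if evoked:
                ev.evoked_ap = evoked[0]
    return events


def detect_and_classify(sweep: SweepRecording,
                        params: Optional[DetectionParams] = None,
                        ) -> tuple[list[RegenerativeEvent], list[SomaticAP]]:
    """Full per-sweep pipeline: somatic APs, candidates, classification."""
    params = params or DetectionParams()
    aps = detect_somatic_aps(sweep.v_soma, sweep.sampling_rate, params,
                             t0=float(sweep.time[0])) \
        if sweep.v_soma is not None else None
    events = detect_candidate_events(sweep, params)
    classify_events(events, aps, sweep, params)
    return events, (aps or [])


def classify_sweep_set(sweeps: Sequence[SweepRecording],
                       params: Optional[DetectionParams] = None,
                       ) -> list[list[RegenerativeEvent]]:
    """Classify repetitions of one protocol; applies the amplitude
    stereotypy check to fallback bAP labels in soma-less recordings.

    Fallback-labeled bAPs whose amplitudes vary too much across
    repetitions (CV > 0.25) are demoted to unclassified, since bAP
    amplitude at a fixed dendritic site is stereotyped.
    """
    params = params or DetectionParams()
    per_sweep = [detect_and_classify(s, params)[0] for s in sweeps]
    fallback = [ev for evs in per_sweep for ev in evs
                if "bap_fallback_no_soma" in ev.flags]
    if len(fallback) >= 3:
        amps = np.array([ev.amplitude for ev in fallback])
        cv = float(np.std(amps) / np.mean(amps)) if np.mean(amps) > 0 else np.inf
        if cv > 0.25:
            for ev in fallback:
                ev.label = UNCLASSIFIED
                ev.flags.append("stereotypy_failed")
    return per_sweep


CA_SPIKE_LABELS = {EventClass.fast_ADP.value, EventClass.slow_ADP.value,
                   EventClass.DI_spike.value}


def ca_spike_first_probability(
        classified_sweeps: Sequence[Sequence[RegenerativeEvent]]) -> float:
    """Probability that a Ca2+ spike is the first regenerative event.

    Over a set of suprathreshold sweeps at one injection level: the
    fraction whose earliest classified event is an ADP or DI spike rather
    than a bAP or Na+ spike.  Sweeps with no classified events do not
    count as suprathreshold.
    """
    n_supra = 0
    n_ca_first = 0
    for events in classified_sweeps:
        labeled = [e for e in sorted(events, key=lambda e: e.peak_time)
                   if e.label != UNCLASSIFIED]
        if not labeled:
            continue
        n_supra += 1
        if labeled[0].label in CA_SPIKE_LABELS:
            n_ca_first += 1
    if n_supra == 0:
        raise ValueError("no suprathreshold sweeps")
    return n_ca_first / n_supra


# ---------------------------------------------------------------------------
# ground-truth matching (evaluation helper)
# ---------------------------------------------------------------------------

def match_ground_truth(truth, events: Sequence[RegenerativeEvent],
                       tol_ms: float = 1.0) -> list[tuple]:
    """Greedily match ground-truth events to detections by peak time.

    Returns a list of (truth_event, detected_event_or_None) pairs; each
    detection is used at most once.
    """
    used = set()
    out = []
    for gt in sorted(truth, key=lambda g: g.peak_ms):
        best, best_d = None, tol_ms
        for i, ev in enumerate(events):
            if i in used:
                continue
            dtm = abs(ev.peak_time - gt.peak_ms)
            if dtm <= best_d:
                best, best_d = i, dtm
        if best is not None:
            used.add(best)
            out.append((gt, events[best]))
        else:
            out.append((gt, None))
    return out
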
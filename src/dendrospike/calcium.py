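"""ΔF/F computation, spike-aligned Ca2+ amplitudes, and propagation
classification across dendritic ROIs.

Analysis stays in ΔF/F units throughout; indicator saturation is not
inverted to [Ca2+].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .recording import CaLinescan, Dye, RoiCompartment

#: post-alignment averaging window length (consecutive samples) per dye;
#: the high-affinity indicator uses a longer window.
POINTS_PER_DYE = {Dye.OGB1: 10, Dye.OGB6F: 3}

#: dV/dt level (V/s) on the spike's initial rise used for alignment
ALIGN_DVDT = 0.35  # mid 0.3-0.4 V/s band


class PropagationClass(str, Enum):
    global_ = "global"
    subtree_restricted = "subtree_restricted"
    indeterminate = "indeterminate"


class KineticClass(str, Enum):
    fast = "fast"  # width < 20 ms
    slow = "slow"  # width > 60 ms
    intermediate = "intermediate"


def kinetic_class(spike_width_ms: float) -> KineticClass:
    if spike_width_ms < 20.0:
        return KineticClass.fast
    if spike_width_ms > 60.0:
        return KineticClass.slow
    return KineticClass.intermediate


@dataclass
class CaTransient:
    """ΔF/F trace with a spike-aligned amplitude for one ROI."""

    time: np.ndarray
    dff: np.ndarray
    roi_distance_from_pipette: float
    roi_compartment: RoiCompartment
    dye: Dye
    dff_amplitude: float = float("nan")
    alignment_time: float = float("nan")


def dff(linescan: CaLinescan, step_onset: float,
        baseline_ms: float = 50.0) -> np.ndarray:
    """ΔF/F₀ with F₀ the mean fluorescence over the ``baseline_ms``
    window immediately preceding the depolarizing current step."""
    t = linescan.time
    sel = (t >= step_onset - baseline_ms) & (t < step_onset)
    if not np.any(sel):
        raise ValueError(f"need {baseline_ms} ms of pre-step data")
    f0 = float(np.mean(linescan.fluorescence[sel]))
    if f0 <= 0:
        raise ValueError("invalid baseline: F0 <= 0")
    return (linescan.fluorescence - f0) / f0


def spike_aligned_ca_amplitude(transient_dff: np.ndarray,
                               time: np.ndarray,
                               alignment_time: float,
                               dye: Dye,
                               search_end: Optional[float] = None) -> float:
    """Spike-aligned ΔF/F amplitude.

    The trace is aligned to the spike's initial rise (the time the
    dendritic dV/dt crosses the 0.3–0.4 V/s band; for slow events
    lacking such a crossing, the dV/dt peak time).  The amplitude is the
    maximum over post-alignment sliding windows of k consecutive samples
    (k = 10 for OGB-1, 3 for OGB-6F) of the window mean, minus the mean
    of the 20–50 ms period preceding the spike.  On noisy flat traces
    the max-of-window-means construction has a known positive bias.
    """
    dye = Dye(dye)
    k = POINTS_PER_DYE[dye]
    t = np.asarray(time, dtype=float)
    y = np.asarray(transient_dff, dtype=float)
    pre = (t >= alignment_time - 50.0) & (t <= alignment_time - 20.0)
    if not np.any(pre):
        raise ValueError("insufficient pre-spike data (need 20-50 ms window)")
    base = float(np.mean(y[pre]))
    post = t >= alignment_time
    if search_end is not None:
        post &= t <= search_end
    yy = y[post]
    if yy.size < k:
        raise ValueError("insufficient post-alignment samples")
    means = np.convolve(yy, np.ones(k) / k, mode="valid")
    return float(np.max(means) - base)


def alignment_time_from_voltage(v_dend: np.ndarray, time: np.ndarray,
                                sampling_rate: float,
                                onset_index: int, peak_index: int,
                                align_dvdt: float = ALIGN_DVDT) -> float:
    """Alignment time for a spike: first crossing of ``align_dvdt`` on
    the rising phase, or the dV/dt peak time if never reached."""
    from scipy.ndimage import gaussian_filter1d
    dt = 1000.0 / sampling_rate
    d = gaussian_filter1d(np.asarray(v_dend, float),
                          sigma=max(0.5 / dt, 1.0), order=1) / dt
    seg = d[onset_index: peak_index + 1]
    above = np.nonzero(seg >= align_dvdt)[0]
    if above.size:
        return float(time[onset_index + above[0]])
    return float(time[onset_index + int(np.argmax(seg))])


def classify_propagation(transients: Sequence[CaTransient],
                         spike_width_ms: float,
                         global_band: float = 0.5,
                         restricted_band: float = 0.2,
                         ) -> tuple[PropagationClass, KineticClass, float]:
    """Classify spike propagation from cross-subtree Ca2+ amplitude ratios.

    ``r = amplitude(other subtree) / amplitude(same subtree)``; r at or
    above ``global_band`` means the spike invades the whole arbor
    (global), r at or below ``restricted_band`` means it stays within
    the stimulated dendritic family.  The spike's kinetic class (fast
    < 20 ms, slow > 60 ms) is reported alongside.
    """
    d1 = [tr.dff_amplitude for tr in transients
          if tr.roi_compartment == RoiCompartment.same_subtree]
    d2 = [tr.dff_amplitude for tr in transients
          if tr.roi_compartment in (RoiCompartment.other_subtree,
                                    RoiCompartment.basal)]
    if not d1 or not d2:
        raise ValueError("need at least one same-subtree and one "
                         "other-subtree transient")
    kin = kinetic_class(spike_width_ms)
    a1 = float(np.mean(d1))
    a2 = float(np.mean(d2))
    if a1 <= 0:
        return PropagationClass.indeterminate, kin, float("nan")
    r = a2 / a1
    if r >= global_band:
        return PropagationClass.global_, kin, r
    if r <= restricted_band:
        return PropagationClass.subtree_restricted, kin, r
    return PropagationClass.indeterminate, kin, r


def proximal_profile(distances_um: Sequence[float],
                     amplitudes: Sequence[float]) -> Optional[float]:
    """Soma-ward drop distance of a spike's Ca2+ signal.

    Given amplitudes at increasing proximal distances from the pipette,
    returns the (monotone-interpolated) distance at which the amplitude
    falls below 50% of the at-pipette amplitude, or None when the
    profile never crosses 50% (reported as no-drop).
    """
    d = np.asarray(distances_um, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 ROIs along the soma-ward path")
    order = np.argsort(d)
    d, a = d[order], a[order]
    if d[0] != 0.0:
        d = np.insert(d, 0, 0.0)
        a = np.insert(a, 0, a[0])
    a0 = a[0]
    if a0 <= 0:
        raise ValueError("non-positive at-pipette amplitude")
    rel = a / a0
    below = np.nonzero(rel < 0.5)[0]
    if below.size == 0:
        return None
    j = below[0]
    if j == 0:
        return 0.0
    f = (rel[j - 1] - 0.5) / (rel[j - 1] - rel[j])
    return float(d[j - 1] + f * (d[j] - d[j - 1]))
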
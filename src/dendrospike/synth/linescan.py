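"""Synthetic two-photon linescan fluorescence traces.

Each Ca2+-mediated event (ADPs, DI spikes) contributes an underlying
calcium transient (step rise, slow exponential decay) that is passed
through a saturating indicator curve — the high-affinity dye (OGB-1)
has a far lower half-saturation constant than the low-affinity dye
(OGB-6F) — and then scaled by a spatial weight encoding the spike's
compartmentalization:

* slow spikes invade the entire arbor: weight 1 at every ROI;
* fast spikes are full-size distal to the stimulation site within the
  same subtree, collapse to a small residual in other subtrees and
  basal dendrites, and fall off linearly along the soma-ward path,
  reaching 50% at the configured proximal drop length.

bAPs add only a small transient; local Na+ spikes add none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..recording import CaLinescan, Dye, RoiCompartment
from .kernels import EventClass
from .sweeps import GroundTruthEvent

#: half-saturation constants (in units of the underlying transient) and
#: maximal ΔF/F per dye
DYE_HALF_SAT = {Dye.OGB1: 0.15, Dye.OGB6F: 3.0}
DYE_DFF_MAX = {Dye.OGB1: 1.5, Dye.OGB6F: 3.0}

#: underlying transient size per event class (a.u.)
CA_DRIVE = {
    EventClass.DI_spike: 2.0,
    EventClass.fast_ADP: 2.0,
    EventClass.slow_ADP: 2.0,
    EventClass.bAP: 0.08,
    EventClass.Na_spike: 0.0,
}

FAST_CLASSES = {EventClass.DI_spike, EventClass.fast_ADP}
OTHER_SUBTREE_RESIDUAL = 0.1


@dataclass
class LinescanConfig:
    """Geometry and acquisition parameters of one synthetic linescan."""

    roi_distance: float  # um from pipette (path distance)
    roi_compartment: RoiCompartment = RoiCompartment.same_subtree
    dye: Dye = Dye.OGB1
    noise_sd: float = 0.0  # a.u. fluorescence noise
    seed: int = 0
    sampling_rate: float = 300.0  # Hz
    duration_ms: float = 1200.0
    step_onset: float = 100.0
    f0: float = 100.0  # baseline fluorescence, a.u.
    ca_decay_ms: float = 250.0
    ca_rise_ms: float = 8.0
    proximal_drop_um: float = 160.0  # 50% fall-off distance soma-ward


def _spatial_weight(event_class: EventClass, cfg: LinescanConfig) -> float:
    if event_class not in FAST_CLASSES:
        return 1.0
    comp = cfg.roi_compartment
    if comp == RoiCompartment.same_subtree:
        return 1.0
    if comp in (RoiCompartment.other_subtree, RoiCompartment.basal):
        return OTHER_SUBTREE_RESIDUAL
    # proximal path: linear fall-off, 50% at the drop length
    return float(np.clip(1.0 - cfg.roi_distance / (2.0 * cfg.proximal_drop_um),
                         0.0, 1.0))


def generate_ca_linescan(events: Sequence[GroundTruthEvent],
                         config: LinescanConfig) -> CaLinescan:
    """Render the fluorescence trace seen by one ROI for a sweep's events.

    Deterministic given config (incl. seed).  Raises on unknown dye or
    negative ROI distance.
    """
    if config.roi_distance < 0:
        raise ValueError("roi_distance must be >= 0")
    dye = Dye(config.dye)
    rng = np.random.default_rng(config.seed)
    dt = 1000.0 / config.sampling_rate
    n = int(round(config.duration_ms / dt)) + 1
    t = np.arange(n) * dt

    dff = np.zeros(n)
    k = DYE_HALF_SAT[dye]
    for ev in events:
        drive = CA_DRIVE.get(EventClass(ev.event_class), 0.0)
        if drive <= 0.0:
            continue
        w = _spatial_weight(EventClass(ev.event_class), config)
        x = t - ev.onset_ms
        c = np.where(x >= 0,
                     drive * (1.0 - np.exp(-np.maximum(x, 0) / config.ca_rise_ms))
                     * np.exp(-np.maximum(x, 0) / config.ca_decay_ms),
                     0.0)
        dff += w * DYE_DFF_MAX[dye] * c / (c + k)

    f = config.f0 * (1.0 + dff)
    if config.noise_sd > 0:
        f = f + rng.normal(0.0, config.noise_sd, n)
    f = np.clip(f, 0.0, None)
    return CaLinescan(time=t, fluorescence=f,
                      roi_distance_from_pipette=config.roi_distance,
                      roi_compartment=config.roi_compartment, dye=dye)
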
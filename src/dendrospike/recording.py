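"""Core data model and preprocessing primitives for current-clamp sweeps.

Units follow electrophysiology convention throughout the package: time in
milliseconds, voltage in millivolts, injected current in picoamperes,
voltage slope (dV/dt) in volts per second.  With these units mV/ms equals
V/s, so no conversion factors appear in derivative code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class Condition(str, Enum):
    """Recording bath condition; pharmacology is emulated, never modeled."""

    control = "control"
    TTX = "TTX"
    Ni = "Ni"
    NMDG = "NMDG"
    APV_NBQX = "APV_NBQX"


class Phenotype(str, Enum):
    """Per-cell Ca2+ spike expression phenotype."""

    ADP_only = "ADP_only"
    DI = "DI"
    both = "both"
    none = "none"


class RoiCompartment(str, Enum):
    same_subtree = "same_subtree"
    other_subtree = "other_subtree"
    basal = "basal"
    proximal_path = "proximal_path"


class Dye(str, Enum):
    """Ca2+ indicator identity; OGB1 is high affinity (saturates readily),
    OGB6F low affinity (more linear)."""

    OGB1 = "OGB1"
    OGB6F = "OGB6F"


@dataclass
class SweepRecording:
    """One stimulus repetition: dendritic voltage, optional somatic voltage,
    injected current and metadata.

    ``step_onset``/``step_offset`` delimit the depolarizing (or
    hyperpolarizing) current step in ms on the sweep time base.
    """

    time: np.ndarray
    v_dend: np.ndarray
    i_inj: np.ndarray
    sampling_rate: float
    step_onset: float
    step_offset: float
    v_soma: Optional[np.ndarray] = None
    pipette_distance: float = float("nan")
    cell_id: str = ""
    sweep_id: str = ""
    condition: Condition = Condition.control

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.v_dend = np.asarray(self.v_dend, dtype=float)
        self.i_inj = np.asarray(self.i_inj, dtype=float)
        if self.v_soma is not None:
            self.v_soma = np.asarray(self.v_soma, dtype=float)
            if self.v_soma.shape != self.time.shape:
                raise ValueError("v_soma length differs from time base")
        if not (self.time.shape == self.v_dend.shape == self.i_inj.shape):
            raise ValueError("time, v_dend and i_inj must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.time) > 1:
            dt = np.median(np.diff(self.time))
            if not np.isclose(dt, 1000.0 / self.sampling_rate, rtol=1e-6):
                raise ValueError("time spacing inconsistent with sampling_rate")
        if not self.step_onset < self.step_offset <= self.time[-1] + 1e-9:
            raise ValueError("require step_onset < step_offset <= trace end")

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1000.0 / self.sampling_rate

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms."""
        return int(round((t_ms - self.time[0]) / self.dt))


@dataclass
class CaLinescan:
    """Fluorescence linescan from one ROI, linked to a voltage sweep.

    ``roi_distance_from_pipette`` is the dendritic path distance (um) from
    the patch pipette; for soma-ward ROIs (``proximal_path``) it measures
    the proximal distance.
    """

    time: np.ndarray
    fluorescence: np.ndarray
    roi_distance_from_pipette: float
    roi_compartment: RoiCompartment
    dye: Dye
    sweep_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must have equal length")
        if np.any(self.fluorescence < 0):
            raise ValueError("fluorescence must be non-negative")


@dataclass
class CellRecord:
    """Per-cell aggregate: phenotype, morphology and event inventory.

    Morphology fields mirror what is measured on collapsed 2P stacks:
    summed thorny-excrescence coverage (um), mean first-order apical trunk
    length (um), number of primary trunks, branch points between pipette
    and soma.
    """

    cell_id: str
    phenotype: Phenotype
    te_coverage: float
    trunk_length: float
    n_primary_trunks: int
    branch_points_to_soma: int
    pipette_distance: float
    events: list = field(default_factory=list)
    sweeps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_primary_trunks < 0 or self.branch_points_to_soma < 0:
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# preprocessing primitives
# ---------------------------------------------------------------------------

_BINOMIAL_KERNEL = np.array([0.25, 0.5, 0.25])


def binomial_smooth(trace: np.ndarray, n: int) -> np.ndarray:
    """Apply ``n`` passes of the 3-point binomial filter (1/4, 1/2, 1/4).

    Edges are handled by edge-value replication, which preserves flat
    baselines.  ``n = 0`` returns a copy.
    """
    if n < 0:
        raise ValueError("pass count must be >= 0")
    out = np.asarray(trace, dtype=float).copy()
    if out.size < 3:
        return out
    for _ in range(int(n)):
        padded = np.pad(out, 1, mode="edge")
        out = np.convolve(padded, _BINOMIAL_KERNEL, mode="valid")
    return out


def dvdt(trace: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Time derivative of a voltage trace in V/s.

    Central differences in the interior, one-sided at the ends.  ``trace``
    is in mV, sampled at ``sampling_rate`` Hz.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt_ms = 1000.0 / sampling_rate
    return np.gradient(trace, dt_ms)  # mV/ms == V/s


def _step_deflection(trace: np.ndarray, time: np.ndarray,
                     step_onset: float, step_offset: float) -> float:
    """Steady-state voltage deflection of a step response (mV): mean over
    the final third of the step minus the pre-step baseline mean."""
    pre = trace[time < step_onset]
    if pre.size == 0:
        raise ValueError("no pre-step baseline samples")
    t_last_third = step_offset - (step_offset - step_onset) / 3.0
    sel = (time >= t_last_third) & (time < step_offset)
    if not np.any(sel):
        raise ValueError("no samples in final third of step")
    return float(np.mean(trace[sel]) - np.mean(pre))


def steady_state_transfer(local_sweep: SweepRecording,
                          remote_trace: np.ndarray) -> float:
    """Steady-state voltage transfer ratio between recording sites.

    Measured on a hyperpolarizing step injected at the *local* site: the
    ratio of the remote steady-state deflection to the local one, each
    averaged over the final third of the step.  Passive transfer gives a
    ratio in (0, 1]; dendrite-to-soma transfer is typically much smaller
    than soma-to-dendrite.
    """
    if remote_trace is None:
        raise ValueError("remote trace missing")
    step_sel = (local_sweep.time >= local_sweep.step_onset) & \
               (local_sweep.time < local_sweep.step_offset)
    if np.mean(local_sweep.i_inj[step_sel]) >= 0:
        raise ValueError("transfer is measured on a hyperpolarizing step")
    local = _step_deflection(local_sweep.v_dend, local_sweep.time,
                             local_sweep.step_onset, local_sweep.step_offset)
    remote = _step_deflection(np.asarray(remote_trace, float), local_sweep.time,
                              local_sweep.step_onset, local_sweep.step_offset)
    if local == 0:
        raise ValueError("zero local deflection")
    return float(remote / local)


def input_resistance(sweep: SweepRecording) -> float:
    """Input resistance in MOhm from a hyperpolarizing current step.

    R = steady-state deflection / step amplitude.  The conventional
    protocol is a 50 pA, 300 ms hyperpolarizing step; the actual step
    amplitude in ``i_inj`` is used.
    """
    step_sel = (sweep.time >= sweep.step_onset) & (sweep.time < sweep.step_offset)
    i_step = float(np.mean(sweep.i_inj[step_sel]))  # pA
    if i_step == 0:
        raise ValueError("zero step amplitude")
    if i_step >= 0:
        raise ValueError("input resistance is measured on a hyperpolarizing step")
    deflection = _step_deflection(sweep.v_dend, sweep.time,
                                  sweep.step_onset, sweep.step_offset)
    return float(deflection / i_step * 1000.0)  # mV/pA -> MOhm
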
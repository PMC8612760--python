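"""Population-level analyses: phenotype assignment, amplitude-decay
fitting, spike-probability summaries, morphology statistics, and output
mode (burst versus single-AP) characterization.

Statistical tests are the field's standard nonparametric choices:
Spearman rank correlation (average ranks for ties) and two-sided
Mann-Whitney U tests, exact for small samples and normal-approximated
with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .detection import CA_SPIKE_LABELS
from .recording import CellRecord, Phenotype
from .synth.kernels import EventClass

PHENOTYPING_I_RANGE = (300.0, 600.0)  # pA window for phenotype assignment
ADP_LABELS = {EventClass.fast_ADP.value, EventClass.slow_ADP.value}


class DegenerateDataError(ValueError):
    """All-tied input: the requested statistic is undefined."""


# ---------------------------------------------------------------------------
# phenotype assignment
# ---------------------------------------------------------------------------

def assign_phenotype(labels_by_sweep: Sequence[Sequence[str]],
                     i_inj_by_sweep: Sequence[float],
                     mode: str = "grouping") -> Optional[Phenotype]:
    """Assign a cell's Ca2+-spike phenotype from its classified events.

    Only sweeps with injection in the 300-600 pA phenotyping window are
    eligible.  ``mode='grouping'`` follows the morphology-comparison
    grouping (any DI spike puts the cell in the DI group, with or
    without ADPs); ``mode='tally'`` keeps co-expression as a separate
    'both' category for propensity tallies.  Returns None when no
    eligible sweep exists.
    """
    lo, hi = PHENOTYPING_I_RANGE
    labels: set = set()
    eligible = False
    for lab, i_inj in zip(labels_by_sweep, i_inj_by_sweep):
        if lo <= i_inj <= hi:
            eligible = True
            labels.update(lab)
    if not eligible:
        return None
    has_di = EventClass.DI_spike.value in labels
    has_adp = bool(labels & ADP_LABELS)
    if has_di and has_adp:
        return Phenotype.DI if mode == "grouping" else Phenotype.both
    if has_di:
        return Phenotype.DI
    if has_adp:
        return Phenotype.ADP_only
    return Phenotype.none


def phenotype_tally(cells_labels: Sequence[tuple]) -> dict:
    """Fraction of cells expressing ADPs, DI spikes, and both.

    ``cells_labels`` is a sequence of (labels_by_sweep, i_inj_by_sweep)
    pairs, one per cell.  Returns fractions over assignable cells.
    """
    counts = {"ADP": 0, "DI": 0, "both": 0, "none": 0, "n": 0}
    for labels_by_sweep, i_by_sweep in cells_labels:
        ph = assign_phenotype(labels_by_sweep, i_by_sweep, mode="tally")
        if ph is None:
            continue
        counts["n"] += 1
        if ph in (Phenotype.ADP_only, Phenotype.both):
            counts["ADP"] += 1
        if ph in (Phenotype.DI, Phenotype.both):
            counts["DI"] += 1
        if ph is Phenotype.both:
            counts["both"] += 1
        if ph is Phenotype.none:
            counts["none"] += 1
    n = max(counts["n"], 1)
    return {k: (v / n if k != "n" else v) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# amplitude vs drive
# ---------------------------------------------------------------------------

@dataclass
class AmplitudeCurve:
    """Normalized DI-spike amplitude versus injected current.

    Normalization: x = (I - I_threshold)/I_threshold, y = amplitude /
    amplitude at threshold, so y(x=0) = 1 by construction.
    """

    i_inj_levels: np.ndarray
    mean_amplitudes: np.ndarray
    i_threshold: float

    def __post_init__(self) -> None:
        self.i_inj_levels = np.asarray(self.i_inj_levels, dtype=float)
        self.mean_amplitudes = np.asarray(self.mean_amplitudes, dtype=float)
        if np.any(np.diff(self.i_inj_levels) <= 0):
            raise ValueError("injection levels must be strictly increasing")

    @property
    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        x = (self.i_inj_levels - self.i_threshold) / self.i_threshold
        a0 = self.mean_amplitudes[np.argmin(np.abs(x))]
        return x, self.mean_amplitudes / a0


def fit_amplitude_decay(x: Sequence[float], y: Sequence[float],
                        ) -> tuple[float, float]:
    """Least-squares fit of y = exp(-x/tau) to normalized amplitude data.

    Non-positive y values are excluded (with a warning flag through the
    residual count); returns (tau, rms residual).  All-flat data (y == 1)
    yields tau = inf, reported as no-decay.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = y > 0
    x, y = x[pos], y[pos]
    if x.size < 3:
        raise ValueError("need at least 3 positive (x, y) points")
    if np.allclose(y, 1.0, atol=1e-12):
        return float("inf"), 0.0
    # log-linear initial guess
    slope = np.polyfit(x, np.log(y), 1)[0]
    tau0 = -1.0 / slope if slope < 0 else 1.0
    tau0 = float(np.clip(tau0, 1e-3, 1e3))
    popt, _ = optimize.curve_fit(lambda xx, tau: np.exp(-xx / tau),
                                 x, y, p0=[tau0], maxfev=10000)
    tau = float(popt[0])
    resid = float(np.sqrt(np.mean((np.exp(-x / tau) - y) ** 2)))
    return tau, resid


def di_ap_window(ap_probabilities: Sequence[float],
                 min_events_ok: bool = True) -> str:
    """Detect an AP-coupling window in DI-spike responses.

    Over increasing injection levels, a window is present when the
    probability that the DI spike triggers an AP rises above 0.5 and
    subsequently falls below 0.5 (larger drive evoking spikes with
    progressively lower AP probability).
    """
    if not min_events_ok:
        return "indeterminate"
    p = np.asarray(ap_probabilities, dtype=float)
    if p.size < 2:
        return "indeterminate"
    rose = False
    for v in p:
        if v > 0.5:
            rose = True
        elif rose and v < 0.5:
            return "window_present"
    return "absent"


# ---------------------------------------------------------------------------
# uncaging spike probability
# ---------------------------------------------------------------------------

def gu_spike_probability(trace_labels: Sequence[Sequence[str]],
                         min_traces: int = 3) -> dict:
    """Per-class d-spike probability from suprathreshold uncaging traces.

    ``trace_labels`` holds, per suprathreshold trace, the classified
    d-spike labels present.  Fewer than ``min_traces`` traces skips the
    measurement (raises ValueError).
    """
    n = len(trace_labels)
    if n < min_traces:
        raise ValueError(f"need at least {min_traces} suprathreshold traces")
    out = {}
    for cls in (EventClass.fast_ADP, EventClass.slow_ADP, EventClass.DI_spike):
        out[cls.value] = sum(cls.value in set(lab) for lab in trace_labels) / n
    out["ADP"] = sum(bool(set(lab) & ADP_LABELS) for lab in trace_labels) / n
    return out


# ---------------------------------------------------------------------------
# morphology statistics
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("all-tied input, correlation undefined")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small samples (both n <= ``exact_max_n``,
    no ties), normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = ("exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n
                          and not ties) else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def morphology_associations(cohort: Sequence[CellRecord],
                            min_group: int = 5) -> pd.DataFrame:
    """Morphology-phenotype statistics table.

    Spearman correlation of first-order trunk length against total
    TE coverage over all cells, and Mann-Whitney comparisons of the four
    morphology fields between the ADP-only and DI (incl. co-expressing)
    groups.
    """
    rows = []
    te = [c.te_coverage for c in cohort]
    trunk = [c.trunk_length for c in cohort]
    try:
        r, p = spearman(trunk, te)
        rows.append(dict(statistic="spearman_trunk_vs_te", value=r,
                         p_value=p, n=len(cohort)))
    except DegenerateDataError:
        rows.append(dict(statistic="spearman_trunk_vs_te", value=np.nan,
                         p_value=np.nan, n=len(cohort)))

    adp = [c for c in cohort if c.phenotype is Phenotype.ADP_only]
    di = [c for c in cohort if c.phenotype in (Phenotype.DI, Phenotype.both)]
    fields = {
        "te_coverage": lambda c: c.te_coverage,
        "trunk_length": lambda c: c.trunk_length,
        "n_primary_trunks": lambda c: c.n_primary_trunks,
        "branch_points": lambda c: c.branch_points_to_soma,
    }
    for name, get in fields.items():
        if len(adp) >= min_group and len(di) >= min_group:
            u, p = mann_whitney([get(c) for c in adp], [get(c) for c in di])
            rows.append(dict(statistic=f"mannwhitney_{name}", value=u,
                             p_value=p, n=len(adp) + len(di)))
        else:
            rows.append(dict(statistic=f"mannwhitney_{name}", value=np.nan,
                             p_value=np.nan, n=len(adp) + len(di)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output mode
# ---------------------------------------------------------------------------

def burst_vs_single_output(cell_events: dict,
                           min_events: int = 3) -> pd.DataFrame:
    """Per-cell median evoked-AP counts by Ca2+ spike class.

    ``cell_events`` maps cell_id to a list of (spike label, evoked-AP
    count) pairs for qualifying Ca2+ spike events that evoked at least
    one AP analysis-wise.  Cells with fewer than ``min_events``
    AP-evoking Ca2+ spike events are excluded and reported as such.
    """
    rows = []
    for cell_id, events in cell_events.items():
        ca = [(lab, n) for lab, n in events if lab in CA_SPIKE_LABELS]
        evoking = [(lab, n) for lab, n in ca if n >= 1]
        if len(evoking) < min_events:
            rows.append(dict(cell_id=cell_id, spike_class="",
                             median_evoked_aps=np.nan, n_events=len(evoking),
                             included=False))
            continue
        for cls in sorted({lab for lab, _ in evoking}):
            counts = [n for lab, n in evoking if lab == cls]
            rows.append(dict(cell_id=cell_id, spike_class=cls,
                             median_evoked_aps=float(np.median(counts)),
                             n_events=len(counts), included=True))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# propagation readout comparison
# ---------------------------------------------------------------------------

def propagation_comparison(df: pd.DataFrame) -> dict:
    """Within/between comparison of Ca2+ signal amplitudes by location.

    ``df`` columns: cell_id, kinetic_group ('fast'/'slow'), d1, d2
    (same- and other-subtree amplitudes).  Returns paired within-group
    (Wilcoxon d1 vs d2) and between-group (Mann-Whitney on d2/d1 ratio)
    two-sided p-values — the paired-contrast reading of the mixed-design
    location x kinetic-group comparison.
    """
    out = {}
    for grp, sub in df.groupby("kinetic_group"):
        if len(sub) >= 5:
            res = stats.wilcoxon(sub["d1"], sub["d2"], alternative="two-sided")
            out[f"wilcoxon_d1_vs_d2_{grp}"] = float(res.pvalue)
        ratio = sub["d2"] / sub["d1"]
        out[f"median_ratio_{grp}"] = float(np.median(ratio))
    fast = df[df.kinetic_group == "fast"]
    slow = df[df.kinetic_group == "slow"]
    if len(fast) >= 3 and len(slow) >= 3:
        _, p = mann_whitney(fast["d2"] / fast["d1"], slow["d2"] / slow["d1"])
        out["mannwhitney_ratio_fast_vs_slow"] = p
    return out
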
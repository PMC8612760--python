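"""Synthetic cell cohorts with phenotype-conditional morphology.

Morphology fields are drawn from per-phenotype normal distributions
whose means come from the reported population summaries (DI-spiking
cells have roughly twice the thorny-excrescence coverage, shorter and
more numerous primary trunks, and more branch points to the soma than
ADP-only cells); SDs are reconstructed from the reported SEMs and group
sizes.  Event content always matches the phenotype: ADP-only cells
never contain DI events.

Random streams are per-cell substreams spawned from the master seed, so
changing the cohort size never perturbs earlier cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..recording import CellRecord, Phenotype
from .scenarios import (
    bap_train_config,
    di_config,
    fast_adp_config,
    slow_adp_config,
)
from .sweeps import generate_sweep

#: per-phenotype (mean, sd) of morphology fields.  SDs are SEM*sqrt(n)
#: from the reported group summaries.
DEFAULT_MORPHOLOGY = {
    Phenotype.ADP_only: {
        "te_coverage": (40.0, 21.8),
        "trunk_length": (128.0, 49.2),
        "n_primary_trunks": (1.0, 0.0),
        "branch_points": (4.15, 1.61),
        "pipette_distance": (276.0, 67.1),
    },
    Phenotype.DI: {
        "te_coverage": (84.0, 47.3),
        "trunk_length": (57.0, 32.0),
        "n_primary_trunks": (1.49, 0.70),
        "branch_points": (5.97, 2.19),
        "pipette_distance": (260.0, 64.0),
    },
}
# co-expressing cells follow the DI-group morphology (the grouping used
# for morphology comparisons pools DI with/without ADPs); spike-less
# cells follow the ADP-only morphology.
DEFAULT_MORPHOLOGY[Phenotype.both] = DEFAULT_MORPHOLOGY[Phenotype.DI]
DEFAULT_MORPHOLOGY[Phenotype.none] = DEFAULT_MORPHOLOGY[Phenotype.ADP_only]

#: step current (pA) per phenotype's sweep protocol, within the
#: 300-600 pA phenotyping range
PHENOTYPE_STEP_PA = {
    Phenotype.ADP_only: 300.0,
    Phenotype.DI: 500.0,
    Phenotype.both: 500.0,
    Phenotype.none: 300.0,
}


@dataclass
class SynthCohortConfig:
    """Cohort composition and morphology distributions.

    ``n_cells`` maps phenotype name to group size.  ``with_sweeps``
    attaches per-cell synthetic sweep sets whose event content matches
    the phenotype (slow burst-driving ADPs for ADP-only cells, DI spikes
    with evoked APs for DI cells); morphology-only cohorts are much
    cheaper and serve the population-statistics analyses.
    """

    n_cells: dict = field(default_factory=lambda: {"ADP_only": 20, "DI": 20})
    morphology: dict = field(default_factory=lambda: {
        k.value: dict(v) for k, v in DEFAULT_MORPHOLOGY.items()})
    seed: int = 0
    with_sweeps: bool = False
    sweeps_per_cell: int = 4
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for ph, n in self.n_cells.items():
            Phenotype(ph)
            if n < 1:
                raise ValueError(f"n_cells[{ph!r}] must be >= 1")
        for ph, fields_ in self.morphology.items():
            for name, (mean, sd) in fields_.items():
                if mean < 0 or sd < 0:
                    raise ValueError(
                        f"morphology {ph}/{name}: mean and sd must be >= 0")


def _draw_morphology(rng: np.random.Generator, dists: dict) -> dict:
    def normal(key):
        mean, sd = dists[key]
        return mean if sd == 0 else float(rng.normal(mean, sd))

    return dict(
        te_coverage=max(normal("te_coverage"), 0.0),
        trunk_length=max(normal("trunk_length"), 0.0),
        n_primary_trunks=max(int(round(normal("n_primary_trunks"))), 1),
        branch_points_to_soma=max(int(round(normal("branch_points"))), 0),
        pipette_distance=max(normal("pipette_distance"), 0.0),
    )


def _cell_sweeps(phenotype: Phenotype, rng: np.random.Generator,
                 seeds: list[int], noise_sd: float, cell_id: str) -> list:
    out = []
    for j, s in enumerate(seeds):
        if phenotype is Phenotype.ADP_only:
            cfg = slow_adp_config(rng, s, noise_sd)
        elif phenotype is Phenotype.DI:
            cfg = di_config(rng, s, noise_sd, evoke_ap=True)
        elif phenotype is Phenotype.both:
            cfg = (di_config(rng, s, noise_sd, evoke_ap=True) if j % 2 == 0
                   else slow_adp_config(rng, s, noise_sd))
        else:
            cfg = bap_train_config(rng, s, noise_sd)
        cfg.step_amplitude = PHENOTYPE_STEP_PA[phenotype]
        sweep, truth = generate_sweep(cfg, cell_id=cell_id,
                                      sweep_id=f"{cell_id}_s{j}")
        out.append((sweep, truth))
    return out


def generate_cohort(config: SynthCohortConfig) -> list[CellRecord]:
    """Generate a labeled cohort of synthetic cells.

    Deterministic in (config, seed).  Each cell carries its morphology
    record, its ground-truth event inventory, and (optionally) its sweep
    set.
    """
    total = sum(config.n_cells.values())
    children = np.random.SeedSequence(config.seed).spawn(total)
    cells: list[CellRecord] = []
    i = 0
    for ph_name in sorted(config.n_cells):
        phenotype = Phenotype(ph_name)
        dists = config.morphology.get(ph_name,
                                      {k: v for k, v in
                                       DEFAULT_MORPHOLOGY[phenotype].items()})
        for _ in range(config.n_cells[ph_name]):
            rng = np.random.default_rng(children[i])
            morph = _draw_morphology(rng, dists)
            cell_id = f"{ph_name}_{i:04d}"
            sweeps, events = [], []
            if config.with_sweeps:
                seeds = [int(x) for x in
                         rng.integers(2 ** 31, size=config.sweeps_per_cell)]
                sweeps = _cell_sweeps(phenotype, rng, seeds,
                                      config.noise_sd, cell_id)
                events = [gt for _, truth in sweeps for gt in truth]
            cells.append(CellRecord(cell_id=cell_id, phenotype=phenotype,
                                    events=events, sweeps=sweeps, **morph))
            i += 1
    return cells
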
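"""Pipeline orchestration: simulate -> detect -> quantify -> cohort.

Each stage is a pure function of (inputs, config, seed); a run manifest
records the config hash, seeds and every artifact path so a rerun with
the same manifest reproduces identical outputs for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import burst_vs_single_output, morphology_associations, phenotype_tally
from .detection import DetectionParams, detect_and_classify
from .io import (
    cohort_to_frame,
    events_to_frame,
    load_config,
    read_sweeps,
    read_truth,
    validate_config,
    write_sweeps,
)
from .metrics import metrics_table
from .recording import Phenotype
from .synth.cohorts import SynthCohortConfig, generate_cohort

CONFIG_SCHEMA = {
    "simulate": {"n_cells": None, "sweeps_per_cell": None, "noise_sd": None,
                 "seed": None},
    "detect": {"kink_threshold": None, "prominence": None,
               "bap_coincidence_ms": None, "adp_window_ms": None,
               "slow_adp_boundary_ms": None},
    "quantify": {},
    "cohort": {"min_group": None},
    "out_dir": None,
    "log_level": None,
}


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def _config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_simulate(cfg: dict, seed: int, out_dir: Path) -> dict:
    scfg = SynthCohortConfig(
        n_cells=cfg.get("n_cells", {"ADP_only": 4, "DI": 4}),
        sweeps_per_cell=int(cfg.get("sweeps_per_cell", 2)),
        noise_sd=float(cfg.get("noise_sd", 0.3)),
        seed=int(cfg.get("seed", seed)), with_sweeps=True)
    cells = generate_cohort(scfg)
    h5 = out_dir / "sweeps.h5"
    sweeps = [s for c in cells for s, _ in c.sweeps]
    truth = {s.sweep_id: t for c in cells for s, t in c.sweeps}
    write_sweeps(h5, sweeps, truth)
    cohort_csv = out_dir / "cohort.csv"
    cohort_to_frame(cells).to_csv(cohort_csv, index=False)
    return {"sweeps": str(h5), "truth": str(h5) + ".truth.json",
            "cohort": str(cohort_csv)}


def stage_detect(cfg: dict, seed: int, out_dir: Path, sweeps_path) -> dict:
    del seed
    params = DetectionParams(**{k: v for k, v in cfg.items()
                                if k in DetectionParams.__dataclass_fields__})
    sweeps = read_sweeps(sweeps_path)
    events_by_sweep = {}
    for s in sweeps:
        events, _ = detect_and_classify(s, params)
        events_by_sweep[s.sweep_id] = events
    out = out_dir / "events.csv"
    events_to_frame(events_by_sweep).to_csv(out, index=False)
    return {"events": str(out)}


def stage_quantify(cfg: dict, seed: int, out_dir: Path, sweeps_path) -> dict:
    del cfg, seed
    sweeps = read_sweeps(sweeps_path)
    tables = []
    for s in sweeps:
        events, aps = detect_and_classify(s)
        tables.append(metrics_table(s, events, aps))
    df = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    out = out_dir / "metrics.csv"
    df.to_csv(out, index=False)
    # per-cell summary
    summary = {}
    if not df.empty:
        df["cell_id"] = df.sweep_id.str.rsplit("_s", n=1).str[0]
        for cid, sub in df.groupby("cell_id"):
            summary[cid] = {
                "n_events": int(len(sub)),
                "labels": sub.label.value_counts().to_dict(),
            }
    summary_path = out_dir / "cells.json"
    summary_path.write_text(json.dumps(summary, indent=1))
    return {"metrics": str(out), "cells": str(summary_path)}


def stage_cohort(cfg: dict, seed: int, out_dir: Path,
                 cohort_csv, metrics_csv) -> dict:
    del seed
    from .recording import CellRecord
    cdf = pd.read_csv(cohort_csv)
    cells = [CellRecord(cell_id=r.cell_id, phenotype=Phenotype(r.phenotype),
                        te_coverage=r.te_coverage, trunk_length=r.trunk_length,
                        n_primary_trunks=int(r.n_primary_trunks),
                        branch_points_to_soma=int(r.branch_points_to_soma),
                        pipette_distance=r.pipette_distance)
             for r in cdf.itertuples()]
    stats = morphology_associations(cells,
                                    min_group=int(cfg.get("min_group", 5)))
    stats_csv = out_dir / "morphology_stats.csv"
    stats.to_csv(stats_csv, index=False)

    mdf = pd.read_csv(metrics_csv) if Path(metrics_csv).exists() else pd.DataFrame()
    report = {"n_cells": len(cells)}
    if not mdf.empty:
        mdf["cell_id"] = mdf.sweep_id.str.rsplit("_s", n=1).str[0]
        cell_events = {
            cid: list(zip(sub.label, sub.n_evoked_aps.fillna(0).astype(int)))
            for cid, sub in mdf.groupby("cell_id")}
        out_modes = burst_vs_single_output(cell_events)
        report["output_mode"] = out_modes.to_dict(orient="records")
    report_path = out_dir / "cohort_report.json"
    report_path.write_text(json.dumps(report, indent=1))
    return {"morphology_stats": str(stats_csv), "report": str(report_path)}


def run_pipeline(config, seed: int = 0,
                 out_dir: Optional[str] = None) -> RunManifest:
    """Run all stages in order and return the manifest.

    ``config`` is a YAML path or a dict following :data:`CONFIG_SCHEMA`.
    A stage failure raises after writing the partial manifest.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    validate_config(cfg, CONFIG_SCHEMA)
    out = Path(out_dir or cfg.get("out_dir", "dendrospike_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(cfg), seed=seed,
                           version=__version__, started=_time.time())
    mpath = out / "manifest.json"
    try:
        sim = stage_simulate(cfg.get("simulate", {}), seed, out)
        manifest.stages["simulate"] = sim
        det = stage_detect(cfg.get("detect", {}), seed, out, sim["sweeps"])
        manifest.stages["detect"] = det
        qua = stage_quantify(cfg.get("quantify", {}), seed, out, sim["sweeps"])
        manifest.stages["quantify"] = qua
        coh = stage_cohort(cfg.get("cohort", {}), seed, out,
                           sim["cohort"], qua["metrics"])
        manifest.stages["cohort"] = coh
    finally:
        manifest.finished = _time.time()
        mpath.write_text(manifest.to_json())
    return manifest
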
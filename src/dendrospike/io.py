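"""On-disk formats: the HDF5 sweep dialect, ground-truth JSON sidecars,
cohort CSV tables and YAML configs.

Sweep dialect: one HDF5 group per sweep under ``/sweeps/<sweep_id>``
with datasets ``time``, ``v_dend``, ``i_inj`` (and ``v_soma`` when
present) plus scalar attributes for the metadata fields.  Round-trips
are bit-exact for arrays and lossless for metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .recording import CellRecord, Condition, SweepRecording
from .synth.sweeps import GroundTruthEvent
from .synth.kernels import EventClass


def write_sweeps(path, sweeps: Sequence[SweepRecording],
                 truth: Optional[dict] = None) -> None:
    """Write sweeps to the HDF5 dialect; optionally a ground-truth JSON
    sidecar (``<path>.truth.json``) keyed by sweep_id."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        root = f.create_group("sweeps")
        for s in sweeps:
            g = root.create_group(s.sweep_id or f"sweep{len(root)}")
            g.create_dataset("time", data=s.time)
            g.create_dataset("v_dend", data=s.v_dend)
            g.create_dataset("i_inj", data=s.i_inj)
            if s.v_soma is not None:
                g.create_dataset("v_soma", data=s.v_soma)
            g.attrs["sampling_rate"] = s.sampling_rate
            g.attrs["step_onset"] = s.step_onset
            g.attrs["step_offset"] = s.step_offset
            g.attrs["pipette_distance"] = s.pipette_distance
            g.attrs["cell_id"] = s.cell_id
            g.attrs["sweep_id"] = s.sweep_id
            g.attrs["condition"] = s.condition.value
    if truth is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        payload = {sid: [dataclasses.asdict(gt) | {"event_class": gt.event_class.value}
                         for gt in events]
                   for sid, events in truth.items()}
        sidecar.write_text(json.dumps(payload, indent=1))


def read_sweeps(path) -> list[SweepRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for name in f["sweeps"]:
            g = f["sweeps"][name]
            out.append(SweepRecording(
                time=g["time"][()], v_dend=g["v_dend"][()],
                i_inj=g["i_inj"][()],
                v_soma=g["v_soma"][()] if "v_soma" in g else None,
                sampling_rate=float(g.attrs["sampling_rate"]),
                step_onset=float(g.attrs["step_onset"]),
                step_offset=float(g.attrs["step_offset"]),
                pipette_distance=float(g.attrs["pipette_distance"]),
                cell_id=str(g.attrs["cell_id"]),
                sweep_id=str(g.attrs["sweep_id"]),
                condition=Condition(str(g.attrs["condition"]))))
    out.sort(key=lambda s: s.sweep_id)
    return out


def read_truth(path) -> dict:
    path = Path(path)
    payload = json.loads(path.read_text())
    out = {}
    for sid, events in payload.items():
        out[sid] = [GroundTruthEvent(
            event_class=EventClass(e["event_class"]), onset_ms=e["onset_ms"],
            peak_ms=e["peak_ms"], amplitude=e["amplitude"],
            soma_amplitude=e.get("soma_amplitude", 0.0),
            evokes_ap=e.get("evokes_ap", False),
            initiated_by_ap=e.get("initiated_by_ap", False))
            for e in events]
    return out


def cohort_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([dict(
        cell_id=c.cell_id, phenotype=c.phenotype.value,
        te_coverage=c.te_coverage, trunk_length=c.trunk_length,
        n_primary_trunks=c.n_primary_trunks,
        branch_points_to_soma=c.branch_points_to_soma,
        pipette_distance=c.pipette_distance) for c in cells])


def events_to_frame(events_by_sweep: dict) -> pd.DataFrame:
    rows = []
    for sid, events in events_by_sweep.items():
        for k, ev in enumerate(events):
            rows.append(dict(sweep_id=sid, event_index=k, label=ev.label,
                             onset_ms=ev.onset_time, peak_ms=ev.peak_time,
                             end_ms=ev.end_time, peak_vm=ev.peak_vm,
                             amplitude=ev.amplitude, dvdt_peak=ev.dvdt_peak,
                             dvdt_pre=ev.dvdt_pre, dvdt_ratio=ev.dvdt_ratio,
                             latency_ms=ev.latency_from_step,
                             initiating_ap=ev.initiating_ap,
                             evoked_ap=ev.evoked_ap,
                             flags=";".join(ev.flags)))
    return pd.DataFrame(rows)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def validate_config(cfg: dict, schema: dict, context: str = "config") -> None:
    """Recursively reject unknown keys, naming the offender."""
    for key, val in cfg.items():
        if key not in schema:
            raise ValueError(f"unknown key {context}.{key}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(val, dict):
            validate_config(val, sub, f"{context}.{key}")
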
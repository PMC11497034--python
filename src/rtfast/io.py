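"""Plain-text readers and writers for the pipeline's trace and table formats.

Current traces are two-column tab-delimited text (time_s, current_pA) with a
JSON sidecar carrying the acquisition metadata (sampling rate, voltage,
incubation time, pipette geometry).  Photon traces are one-column integer
counts with a JSON sidecar (bin width, incubation time).  Event, burst and
kinetics tables are CSV with fixed column names that embed their units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .burst_analysis import BurstSummary, PhotonTrace
from .event_detection import CurrentTrace, VolumeMapResult
from .kinetics import KineticTrace
from .pore_model import PipetteGeometry

__all__ = [
    "write_current_trace",
    "read_current_trace",
    "write_photon_trace",
    "read_photon_trace",
    "write_volume_map",
    "read_kinetics_table",
    "write_kinetics_table",
    "write_burst_summary",
]

EVENT_COLUMNS = ["start_s", "dwell_s", "dI_pA", "rel_blockade", "volume_nm3", "size_nm"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_current_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """Write a trace as (time_s, current_pA) TSV plus a JSON metadata sidecar."""
    path = Path(path)
    data = np.column_stack([trace.time_s, trace.current_pA])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t", header="time_s\tcurrent_pA")
    meta = {
        "sampling_rate_Hz": trace.sampling_rate_Hz,
        "applied_voltage_mV": trace.applied_voltage_mV,
        "incubation_time_min": trace.incubation_time_min,
        "geometry": trace.geometry.to_dict() if trace.geometry else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_current_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = np.loadtxt(path, delimiter="\t")
    geometry = (
        PipetteGeometry.from_dict(meta["geometry"]) if meta.get("geometry") else None
    )
    return CurrentTrace(
        current_pA=data[:, 1],
        sampling_rate_Hz=float(meta["sampling_rate_Hz"]),
        applied_voltage_mV=float(meta.get("applied_voltage_mV", -500.0)),
        incubation_time_min=float(meta.get("incubation_time_min", 0.0)),
        geometry=geometry,
    )


def write_photon_trace(trace: PhotonTrace, path: str | Path) -> Path:
    """Write photon counts as one integer per line plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(trace.counts, dtype=int), fmt="%d", header="counts")
    meta = {
        "bin_width_s": trace.bin_width_s,
        "incubation_time_min": trace.incubation_time_min,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_photon_trace(path: str | Path) -> PhotonTrace:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    counts = np.loadtxt(path, dtype=int)
    return PhotonTrace(
        counts=np.atleast_1d(counts),
        bin_width_s=float(meta["bin_width_s"]),
        incubation_time_min=float(meta.get("incubation_time_min", 0.0)),
    )


def write_volume_map(result: VolumeMapResult, path: str | Path) -> Path:
    """Write the event->volume table (CSV); non-invertible events go to a
    ``*.non_invertible.csv`` companion when present."""
    path = Path(path)
    result.table.to_csv(path, index=False)
    if result.n_non_invertible:
        result.non_invertible.to_csv(
            path.with_suffix(".non_invertible.csv"), index=False
        )
    return path


def read_kinetics_table(path: str | Path) -> list[KineticTrace]:
    """Read a kinetics CSV (time_min, intensity, condition, replicate) into
    one KineticTrace per (condition, replicate) group."""
    df = pd.read_csv(path)
    required = {"time_min", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"kinetics table must contain columns {sorted(required)}")
    if "condition" not in df.columns:
        df["condition"] = "control"
    if "replicate" not in df.columns:
        df["replicate"] = 0
    traces = []
    for (condition, replicate), g in df.groupby(["condition", "replicate"], sort=True):
        g = g.sort_values("time_min")
        traces.append(
            KineticTrace(
                time_min=g["time_min"].to_numpy(),
                intensity=g["intensity"].to_numpy(),
                condition=str(condition),
                replicate=int(replicate),
            )
        )
    return traces


def write_kinetics_table(traces: list[KineticTrace], path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                "time_min": tr.time_min,
                "intensity": tr.intensity,
                "condition": tr.condition,
                "replicate": tr.replicate,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_burst_summary(summary: BurstSummary, path: str | Path) -> Path:
    """Write per-burst CSV to ``path`` and a summary JSON sidecar."""
    path = Path(path)
    summary.table.to_csv(path, index=False)
    meta = {
        "frequency_per_s": summary.frequency_per_s,
        "n_bursts": summary.n_bursts,
        "dwell_hist_counts": summary.dwell_hist_counts.tolist(),
        "dwell_hist_edges": summary.dwell_hist_edges.tolist(),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path
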
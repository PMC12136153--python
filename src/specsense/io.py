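"""On-disk formats: trace TSVs, a manifest CSV, and truth tables.

One presentation is one two-column TSV (time_ms, voltage_mV); a manifest
CSV ties every trace file to its cell, individual, group and stimulus
metadata.  A ``schema.json`` sidecar declares the format version.  This
layout favors desk-scale inspectability; at larger scales a single binary
container would be substituted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import CellRecording, Trace

__all__ = ["write_recordings", "read_recordings", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"

MANIFEST_COLUMNS = [
    "cell_id", "individual_id", "group", "path", "wavelength_nm", "intensity",
    "led", "repeat", "kind", "stimulus_onset_ms", "sample_rate_hz",
]


def write_recordings(out_dir, recordings, truth: pd.DataFrame | None = None,
                     write_traces: bool = True) -> Path:
    """Write recordings as trace TSVs plus manifest (and optional truth) CSVs."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        for i, tr in enumerate(rec.traces):
            rel = f"traces/{rec.cell_id}_{i:04d}.tsv"
            if write_traces:
                _write_trace_tsv(out / rel, tr)
            rows.append(
                dict(
                    cell_id=rec.cell_id, individual_id=rec.individual_id,
                    group=rec.group, path=rel, wavelength_nm=tr.wavelength,
                    intensity=tr.intensity, led=tr.led, repeat=tr.repeat,
                    kind=tr.kind, stimulus_onset_ms=tr.stimulus_onset,
                    sample_rate_hz=tr.sample_rate,
                )
            )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(out / "manifest.csv", index=False)
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
    (out / "schema.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION,
                    "trace_format": "tsv:time_ms,voltage_mV"}, sort_keys=True)
    )
    return out


def _write_trace_tsv(path: Path, tr: Trace) -> None:
    t = tr.time
    with open(path, "w") as fh:
        fh.write("time_ms\tvoltage_mV\n")
        np.savetxt(fh, np.column_stack([t, tr.voltage]), fmt="%.4f", delimiter="\t")


def read_recordings(in_dir) -> list:
    """Reconstruct CellRecording objects from a manifest directory."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {in_dir}")
    manifest = pd.read_csv(manifest_path)
    recs = {}
    for _, row in manifest.iterrows():
        key = row["cell_id"]
        if key not in recs:
            recs[key] = CellRecording(
                cell_id=row["cell_id"],
                individual_id=row["individual_id"],
                group=row["group"],
            )
        data = np.loadtxt(in_dir / row["path"], delimiter="\t", skiprows=1, ndmin=2)
        recs[key].traces.append(
            Trace(
                voltage=data[:, 1],
                sample_rate=float(row["sample_rate_hz"]),
                stimulus_onset=float(row["stimulus_onset_ms"]),
                wavelength=float(row["wavelength_nm"]),
                intensity=float(row["intensity"]),
                led=str(row["led"]),
                repeat=int(row["repeat"]),
                kind=str(row["kind"]),
            )
        )
    return list(recs.values())
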
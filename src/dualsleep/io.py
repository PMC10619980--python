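"""Readers and writers for the pipeline's on-disk formats.

Movies travel as multi-page TIFF with a JSON metadata sidecar; traces,
behavior logs, bout tables, DE tables and summaries as headered CSV/TSV;
ground truths as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from dualsleep.containers import ROILabels, TraceMatrix


def write_movie(path: str | Path, movie: np.ndarray, meta: dict | None = None) -> None:
    """Write a (t, y, x) movie as multi-page float32 TIFF (+ JSON sidecar)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    movie = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return movie, meta


def write_labels(path: str | Path, labels: ROILabels) -> None:
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint16))


def read_labels(path: str | Path, slice_index: int = 0) -> ROILabels:
    return ROILabels(labels=tifffile.imread(Path(path)).astype(np.int32), slice_index=slice_index)


def write_traces(path: str | Path, traces: TraceMatrix) -> None:
    """Traces as CSV: neuron_id, slice, then one column per frame (t0..tN)."""
    df = pd.DataFrame(traces.values, columns=[f"t{i}" for i in range(traces.n_frames)])
    df.insert(0, "slice", traces.slice_index)
    df.insert(0, "neuron_id", traces.neuron_ids)
    df.attrs["fs"] = traces.fs
    df.to_csv(path, index=False)
    Path(path).with_suffix(".meta.json").write_text(json.dumps({"fs": traces.fs}))


def read_traces(path: str | Path) -> TraceMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".meta.json")
    fs = json.loads(sidecar.read_text())["fs"] if sidecar.exists() else 1.0
    frame_cols = [c for c in df.columns if c.startswith("t")]
    return TraceMatrix(
        values=df[frame_cols].to_numpy(dtype=float),
        fs=fs,
        neuron_ids=df["neuron_id"].to_numpy(),
        slice_index=df["slice"].to_numpy(dtype=int),
    )


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.to_csv(path, index=False, sep=sep)


def read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
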
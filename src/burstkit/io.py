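"""Readers and writers for the package's plain-text interchange formats.

Counts: CSV with columns cell_id, dose_uM, clone, mrna_count.
Traces: long CSV with columns trace_id, time_min, intensity[, true_state].
Images: single-plane grayscale TIFF plus a JSON truth sidecar.
Config: YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .hmm import IntensityTrace

COUNT_COLUMNS = ["cell_id", "dose_uM", "clone", "mrna_count"]


def write_counts_csv(table: pd.DataFrame, path) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"counts table missing columns {missing}")
    table[COUNT_COLUMNS].to_csv(path, index=False)


def read_counts_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"counts CSV missing columns {missing}")
    if (table.mrna_count < 0).any():
        raise ValueError("mrna_count must be non-negative")
    return table


def write_traces_csv(traces: list[IntensityTrace], path, true_states=None) -> None:
    frames = []
    for i, tr in enumerate(traces):
        df = pd.DataFrame(
            {"trace_id": tr.trace_id, "time_min": tr.times, "intensity": tr.intensity}
        )
        if true_states is not None:
            df["true_state"] = np.asarray(true_states[i], dtype=int)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    for col in ("trace_id", "time_min", "intensity"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col}")
    return [
        IntensityTrace(
            trace_id=tid,
            times=sub.time_min.to_numpy(float),
            intensity=sub.intensity.to_numpy(float),
        )
        for tid, sub in df.groupby("trace_id", sort=False)
    ]


def write_image_tiff(field, path, sidecar_path=None) -> None:
    tifffile.imwrite(path, field.image.astype(np.float32))
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(field.truth_sidecar(), indent=1))


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default, sort_keys=True))
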
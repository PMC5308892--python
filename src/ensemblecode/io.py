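"""Readers and writers for the pipeline's on-disk formats.

Trial tables, unit manifests and per-unit spike lists travel as headered CSV;
EMG traces as raw little-endian float32 with a JSON sidecar (sample rate and
start time) or as CSV; run configurations as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import EmgTrace, SpikeTrain, SpikeTrainSet

__all__ = [
    "write_trial_table", "read_trial_table",
    "write_spike_set", "read_spike_set",
    "write_emg", "read_emg",
    "write_yaml", "read_yaml",
]

TRIAL_COLUMNS = ["session_id", "epoch", "trial_index", "condition",
                 "cs_onset_s", "box_id"]


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["paired"] = table["condition"].str.endswith("_US")
    return table


def write_spike_set(spike_set: SpikeTrainSet, directory: str | Path) -> None:
    """One timestamp CSV per unit plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spike_set.manifest().to_csv(directory / "units.csv", index=False)
    for unit in spike_set:
        pd.DataFrame({"timestamp_s": unit.timestamps}).to_csv(
            directory / f"{unit.unit_id}.csv", index=False)


def read_spike_set(directory: str | Path) -> SpikeTrainSet:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "units.csv")
    units = []
    for row in manifest.itertuples():
        ts = pd.read_csv(directory / f"{row.unit_id}.csv")["timestamp_s"].to_numpy()
        units.append(SpikeTrain(
            unit_id=row.unit_id, timestamps=ts, session_id=int(row.session_id),
            rat=str(row.rat), tetrode=int(row.tetrode),
            neuron_class=getattr(row, "neuron_class", None)))
    return SpikeTrainSet(units)


def write_emg(trace: EmgTrace, path: str | Path, fmt: str = "float32") -> None:
    """Write a trace as raw float32 + JSON sidecar, or as a two-column CSV."""
    path = Path(path)
    if fmt == "float32":
        trace.samples.astype("<f4").tofile(path)
        sidecar = {"session_id": trace.session_id,
                   "sample_rate": trace.sample_rate, "t0": trace.t0,
                   "dtype": "<f4"}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    elif fmt == "csv":
        t = trace.t0 + np.arange(len(trace.samples)) / trace.sample_rate
        pd.DataFrame({"time_s": t, "amplitude": trace.samples}).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown EMG format {fmt!r}")


def read_emg(path: str | Path, session_id: int | None = None) -> EmgTrace:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        samples = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
        return EmgTrace(session_id=meta.get("session_id", session_id or 0),
                        sample_rate=meta["sample_rate"], t0=meta["t0"],
                        samples=samples)
    df = pd.read_csv(path)
    dt = float(np.median(np.diff(df["time_s"])))
    return EmgTrace(session_id=session_id or 0, sample_rate=1.0 / dt,
                    t0=float(df["time_s"].iloc[0]),
                    samples=df["amplitude"].to_numpy())


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
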
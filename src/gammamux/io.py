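"""Serialisation: spike records as TSV/HDF5, metrics as CSV, manifests as YAML."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SlowOscConfig, SpikeRecord

__all__ = [
    "spikes_to_frame",
    "write_spikes_tsv",
    "read_spikes_tsv",
    "write_spikes_hdf5",
    "read_spikes_hdf5",
    "write_manifest",
    "read_manifest",
    "write_results",
]


def spikes_to_frame(record: SpikeRecord) -> pd.DataFrame:
    """Tidy (repeat, population, cell, time_ms) frame, sorted within repeat."""
    frames = []
    for pop, ev in record.events.items():
        frames.append(pd.DataFrame({
            "repeat": ev["repeat"], "population": pop,
            "cell": ev["cell"], "time_ms": ev["time"],
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["repeat", "population", "cell", "time_ms"])
    return df.sort_values(["repeat", "time_ms", "population", "cell"],
                          kind="stable").reset_index(drop=True)


def write_spikes_tsv(record: SpikeRecord, path) -> None:
    spikes_to_frame(record).to_csv(path, sep="\t", index=False)


def read_spikes_tsv(path, duration: float, dt: float = 1.0,
                    repeats: int | None = None, seed: int = 0,
                    slow: SlowOscConfig | None = None) -> SpikeRecord:
    df = pd.read_csv(path, sep="\t")
    events = {}
    for pop, sub in df.groupby("population"):
        events[pop] = {
            "repeat": sub["repeat"].to_numpy(np.int32),
            "cell": sub["cell"].to_numpy(np.int32),
            "time": sub["time_ms"].to_numpy(float),
        }
    n_rep = repeats if repeats is not None else (int(df["repeat"].max()) + 1 if len(df) else 0)
    return SpikeRecord(events=events, duration=duration, dt=dt, repeats=n_rep,
                       seed=seed, slow=slow)


def write_spikes_hdf5(record: SpikeRecord, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["duration"] = record.duration
        fh.attrs["dt"] = record.dt
        fh.attrs["repeats"] = record.repeats
        fh.attrs["seed"] = record.seed
        for pop, ev in record.events.items():
            grp = fh.create_group(pop)
            for key in ("repeat", "cell", "time"):
                grp.create_dataset(key, data=ev[key])


def read_spikes_hdf5(path) -> SpikeRecord:
    import h5py

    with h5py.File(path, "r") as fh:
        events = {
            pop: {key: fh[pop][key][()] for key in ("repeat", "cell", "time")}
            for pop in fh
        }
        return SpikeRecord(events=events, duration=float(fh.attrs["duration"]),
                           dt=float(fh.attrs["dt"]), repeats=int(fh.attrs["repeats"]),
                           seed=int(fh.attrs["seed"]))


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_results(result: dict, out_dir) -> list[Path]:
    """Write a runner's result dict: spike TSV, metric tables as CSV, and the
    manifest as YAML.  Returns the list of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "record" in result:
        p = out / "spikes.tsv"
        write_spikes_tsv(result["record"], p)
        written.append(p)
    for key, val in result.items():
        if isinstance(val, pd.DataFrame):
            p = out / f"{key}.csv"
            val.to_csv(p, index=False)
            written.append(p)
    scalars = {k: float(v) for k, v in result.items()
               if isinstance(v, (int, float, np.floating))}
    if scalars:
        p = out / "metrics.csv"
        pd.DataFrame([scalars]).to_csv(p, index=False)
        written.append(p)
    if "manifest" in result:
        p = out / "manifest.yaml"
        write_manifest(result["manifest"], p)
        written.append(p)
    return written
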
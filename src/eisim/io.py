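"""File formats: raster CSV, trace HDF5/CSV, JSON configs, result tables.

Rasters are CSV with header ``unit_id,population,spike_time_s`` (times in
seconds, 6 decimal places, epoch half-open [0, duration)). Traces are HDF5
with datasets ``lfp``/``time`` (single trace) or ``data`` (channels x
samples) and a ``sampling_rate_hz`` attribute; a CSV fallback is provided.
Configs are JSON files mirroring the configuration dataclasses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ParameterError
from .network import (
    ExternalInputConfig,
    LFPProxyTrace,
    NetworkConfig,
    NoiseConfig,
    PopulationParams,
    RampProtocol,
    SpikeRaster,
    SynapseConfig,
)
from .spectral import RawTraceSet

__all__ = [
    "write_raster",
    "read_raster",
    "write_trace",
    "read_trace",
    "write_traceset",
    "read_traceset",
    "read_config",
    "write_config",
    "read_protocol",
    "write_manifest",
]

RASTER_COLUMNS = ["unit_id", "population", "spike_time_s"]


def write_raster(raster: SpikeRaster, path: Union[str, Path]) -> None:
    order = np.argsort(raster.spike_times, kind="stable")
    df = pd.DataFrame(
        {
            "unit_id": raster.unit_ids[order],
            "population": raster.populations[raster.unit_ids[order]],
            "spike_time_s": raster.spike_times[order],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_raster(path: Union[str, Path], duration: Optional[float] = None) -> SpikeRaster:
    df = pd.read_csv(path)
    missing = set(RASTER_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"raster file missing column(s): {sorted(missing)}")
    times = df["spike_time_s"].to_numpy(dtype=float)
    units = df["unit_id"].to_numpy(dtype=int)
    if duration is None:
        duration = float(times.max()) + 1e-6 if times.size else 1.0
    if times.size and (times.min() < 0 or times.max() >= duration):
        raise ParameterError("spike time outside the [0, duration) epoch")
    n_units = int(units.max()) + 1 if units.size else 0
    populations = np.array(["exc"] * n_units, dtype=object)
    for uid, pop in zip(units, df["population"]):
        populations[uid] = pop
    return SpikeRaster(times, units, populations, duration)


def write_trace(trace: LFPProxyTrace, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        t = np.arange(trace.samples.size) / trace.sampling_rate
        pd.DataFrame({"time_s": t, "lfp": trace.samples}).to_csv(path, index=False)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=trace.samples.astype(np.float32))
        f.create_dataset(
            "time", data=(np.arange(trace.samples.size) / trace.sampling_rate)
        )
        f.attrs["sampling_rate_hz"] = trace.sampling_rate


def read_trace(path: Union[str, Path]) -> LFPProxyTrace:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        if "lfp" not in df.columns or "time_s" not in df.columns:
            raise ParameterError("trace CSV needs 'time_s' and 'lfp' columns")
        dt = np.diff(df["time_s"].to_numpy()[:2])[0]
        return LFPProxyTrace(df["lfp"].to_numpy(dtype=float), 1.0 / dt)
    with h5py.File(path, "r") as f:
        return LFPProxyTrace(f["lfp"][...].astype(float), float(f.attrs["sampling_rate_hz"]))


def write_traceset(traces: RawTraceSet, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.DataFrame(traces.data.T)
        df.columns = traces.channel_labels or [f"ch{i}" for i in range(traces.n_channels)]
        df.insert(0, "time_s", np.arange(traces.data.shape[1]) / traces.sampling_rate)
        df.to_csv(path, index=False)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=traces.data.astype(np.float32))
        f.attrs["sampling_rate_hz"] = traces.sampling_rate
        if traces.channel_labels:
            f.attrs["channel_labels"] = [str(c) for c in traces.channel_labels]


def read_traceset(path: Union[str, Path]) -> RawTraceSet:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        if "time_s" not in df.columns or df.shape[1] < 2:
            raise ParameterError("trace CSV needs 'time_s' plus channel columns")
        t = df.pop("time_s").to_numpy()
        fs = 1.0 / (t[1] - t[0])
        return RawTraceSet(df.to_numpy(dtype=float).T, fs, list(df.columns))
    with h5py.File(path, "r") as f:
        labels = [str(c) for c in f.attrs.get("channel_labels", [])] or None
        return RawTraceSet(
            f["data"][...].astype(float), float(f.attrs["sampling_rate_hz"]), labels
        )


def _dataclass_from(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} field(s): {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        sub = {
            "exc": PopulationParams,
            "inh": PopulationParams,
            "synapses": SynapseConfig,
            "noise": NoiseConfig,
            "ext_input": ExternalInputConfig,
        }.get(name)
        kwargs[name] = _dataclass_from(sub, value) if sub and isinstance(value, dict) else value
    return cls(**kwargs)


def read_config(path: Union[str, Path]) -> NetworkConfig:
    with open(path) as f:
        return _dataclass_from(NetworkConfig, json.load(f))


def write_config(config: NetworkConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as f:
        json.dump(dataclasses.asdict(config), f, indent=2)


def read_protocol(path: Union[str, Path]) -> RampProtocol:
    with open(path) as f:
        return _dataclass_from(RampProtocol, json.load(f))


def write_manifest(out_dir: Union[str, Path], command: str, seed, config=None,
                   started: Optional[float] = None, extra: Optional[dict] = None) -> Path:
    """Machine-readable run manifest (config hash, seed, version, wall time)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(
        dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
        sort_keys=True, default=str,
    )
    manifest = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "wall_time_s": None if started is None else round(time.time() - started, 3),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
    return path
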
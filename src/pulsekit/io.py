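"""File I/O: traces (HDF5/CSV), ground-truth and event tables, configs,
run manifests.

HDF5 is the canonical stream container (``/signal`` with ``fs``/``t_start``
attributes, ``/truth`` as a table); CSV is the flat interchange format
(``time_s,signal_V``).  Sampling-rate metadata is mandatory everywhere — it
is validated from the CSV time column, never guessed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .sim import DriftSpec, SimulationConfig, TrueEvent
from .trace import SignalTrace

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ["t0_s", "d_um", "A_V", "delta_s", "sigma_s",
                 "t_pos_s", "t_neg_s", "label"]
EVENT_COLUMNS = ["event_id", "t_pos_s", "t_neg_s", "v_pos_V", "v_neg_V",
                 "dV_V", "dt_s", "left_zc_s", "right_zc_s"]


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def write_trace(trace: SignalTrace, path: str | Path,
                truth: list[TrueEvent] | None = None) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("signal", data=trace.samples)
            ds.attrs["fs"] = trace.fs_Sa_s
            ds.attrs["t_start"] = trace.t_start_s
            if truth is not None:
                tdf = truth_to_frame(truth)
                g = f.create_group("truth")
                for col in TRUTH_COLUMNS:
                    data = tdf[col].to_numpy()
                    if data.dtype == object:
                        data = data.astype("S")
                    g.create_dataset(col, data=data)
    elif path.suffix == ".csv":
        df = pd.DataFrame({"time_s": trace.times(), "signal_V": trace.samples})
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        raise ConfigError(f"unsupported trace extension {path.suffix!r}")


def read_trace(path: str | Path) -> tuple[SignalTrace, list[TrueEvent] | None]:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as f:
                ds = f["signal"]
                if "fs" not in ds.attrs:
                    raise ConfigError(f"{path}: missing mandatory fs metadata")
                trace = SignalTrace(ds[...], float(ds.attrs["fs"]),
                                    float(ds.attrs.get("t_start", 0.0)))
                truth = None
                if "truth" in f:
                    g = f["truth"]
                    cols = {c: g[c][...] for c in TRUTH_COLUMNS}
                    cols["label"] = [x.decode() if isinstance(x, bytes) else str(x)
                                     for x in cols["label"]]
                    truth = frame_to_truth(pd.DataFrame(cols))
                return trace, truth
        except OSError as exc:
            raise OSError(f"{path}: unreadable or truncated HDF5 file "
                          f"(size {path.stat().st_size} bytes)") from exc
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        if not {"time_s", "signal_V"} <= set(df.columns):
            raise ConfigError(f"{path}: CSV must have time_s,signal_V columns")
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ConfigError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        fs = 1.0 / float(np.median(dt))
        if np.max(np.abs(dt - 1.0 / fs)) > 1e-6 / fs:
            raise ConfigError(f"{path}: non-uniform timestamps rejected")
        return SignalTrace(df["signal_V"].to_numpy(), fs, float(t[0])), None
    raise ConfigError(f"unsupported trace extension {path.suffix!r}")


# ---------------------------------------------------------------------------
# Ground truth and event tables
# ---------------------------------------------------------------------------

def truth_to_frame(truth: list[TrueEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(ev, c) for c in TRUTH_COLUMNS} for ev in truth],
        columns=TRUTH_COLUMNS,
    )


def frame_to_truth(df: pd.DataFrame) -> list[TrueEvent]:
    return [
        TrueEvent(**{c: (str(row[c]) if c == "label" else float(row[c]))
                     for c in TRUTH_COLUMNS})
        for _, row in df.iterrows()
    ]


def write_truth_csv(truth: list[TrueEvent], path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, index=False, float_format="%.12g")


def read_truth_csv(path: str | Path) -> list[TrueEvent]:
    df = pd.read_csv(path)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: truth CSV missing columns {sorted(missing)}")
    return frame_to_truth(df)


def events_to_frame(events, fs_Sa_s: float, t_start_s: float = 0.0) -> pd.DataFrame:
    rows = []
    for k, e in enumerate(events):
        rows.append({
            "event_id": k,
            "t_pos_s": e.t_pos_s, "t_neg_s": e.t_neg_s,
            "v_pos_V": e.v_pos_V, "v_neg_V": e.v_neg_V,
            "dV_V": e.features.dV_V if e.features else np.nan,
            "dt_s": e.features.dt_s if e.features else np.nan,
            "left_zc_s": t_start_s + e.landmarks.left_zc_idx / fs_Sa_s,
            "right_zc_s": t_start_s + e.landmarks.right_zc_idx / fs_Sa_s,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_csv(events, path: str | Path, fs_Sa_s: float,
                     t_start_s: float = 0.0) -> None:
    events_to_frame(events, fs_Sa_s, t_start_s).to_csv(
        path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Simulation configs (YAML / flat key-value)
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def parse_config(path: str | Path) -> SimulationConfig:
    """Read a simulation config; unknown keys are rejected, an empty file
    yields the all-defaults configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "drift" in data and data["drift"] is not None:
        data["drift"] = DriftSpec(**data["drift"])
    return SimulationConfig(**data)


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    if d["drift"] is not None:
        d["drift"] = dict(d["drift"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, subcommand: str, seed, inputs: dict,
                   outputs: dict, config: dict, counts: dict) -> None:
    """Record everything needed to re-execute a run bit-identically."""
    manifest = {
        "subcommand": subcommand,
        "pulsekit_version": __version__,
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,
        "config": config,
        "counts": counts,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
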
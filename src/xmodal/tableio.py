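"""File I/O: trial-table and spike CSVs, config files, and NWB-style HDF5.

Canonical interchange is plain text: the trial table as one CSV row per trial
(licks serialized as semicolon-joined ``time:port`` tokens), spikes as a
``(unit_id, spike_time)`` CSV plus a JSON unit-metadata sidecar, configs as
JSON or YAML.  The HDF5 reader understands the NWB layout conventions
(``/intervals/trials`` and ``/units`` with ragged ``spike_times`` indices)
and is strictly optional — nothing else depends on it.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from xmodal.config import AgentConfig, PopulationConfig, TaskConfig
from xmodal.core import TRIAL_COLUMNS, SpikeSet, Unit, check_trial_table
from xmodal.errors import IngestionError


# ---------------------------------------------------------------------------
# trial table CSV

def serialize_licks(licks) -> str:
    return ";".join(f"{t:.6f}:{port}" for t, port in licks)


def parse_licks(text) -> list[tuple[float, str]]:
    if not isinstance(text, str) or not text:
        return []
    out = []
    for token in text.split(";"):
        t, port = token.rsplit(":", 1)
        out.append((float(t), port))
    return out


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    check_trial_table(trials)
    out = trials.copy()
    out["licks"] = [serialize_licks(lk) for lk in out["licks"]]
    out.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise IngestionError(f"trial CSV lacks columns: {missing}")
    df["licks"] = [parse_licks(x) for x in df["licks"].fillna("")]
    df["cue"] = df["cue"].astype(bool)
    for col in ("outcome", "believed_rule"):
        df[col] = df[col].where(df[col].notna(), pd.NA)
    return df[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# spikes CSV + JSON sidecar

def write_spikes_csv(spikes: SpikeSet, spike_path, meta_path) -> None:
    rows = [
        (u.unit_id, t) for u in spikes for t in u.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_time"]).to_csv(spike_path, index=False)
    meta = dict(
        session_id=spikes.session_id,
        units=[dict(unit_id=u.unit_id, area=u.area, qc=u.qc) for u in spikes],
    )
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_spikes_csv(spike_path, meta_path) -> SpikeSet:
    df = pd.read_csv(spike_path)
    meta = json.loads(Path(meta_path).read_text())
    grouped = {k: g["spike_time"].to_numpy() for k, g in df.groupby("unit_id")}
    units = [
        Unit(
            unit_id=m["unit_id"],
            area=m["area"],
            spike_times=grouped.get(m["unit_id"], np.array([])),
            qc=m.get("qc", {}),
        )
        for m in meta["units"]
    ]
    return SpikeSet(units=units, session_id=meta["session_id"])


# ---------------------------------------------------------------------------
# configs

_CONFIG_TYPES = {"task": TaskConfig, "agent": AgentConfig, "population": PopulationConfig}


def write_config(path, task=None, agent=None, population=None) -> None:
    payload = {}
    for name, cfg in (("task", task), ("agent", agent), ("population", population)):
        if cfg is not None:
            payload[name] = asdict(cfg)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload))
    else:
        path.write_text(json.dumps(payload, indent=1))


def read_config(path) -> dict:
    """Load a config file into instantiated config objects."""
    path = Path(path)
    raw = (yaml.safe_load(path.read_text()) if path.suffix in (".yaml", ".yml")
           else json.loads(path.read_text()))
    out = {}
    for name, cls in _CONFIG_TYPES.items():
        if name in raw:
            fields = dict(raw[name])
            for key in ("block_len_range", "answer_window", "grace_window",
                        "censor_window", "lick_latency_range"):
                if key in fields and fields[key] is not None:
                    fields[key] = tuple(fields[key])
            out[name] = cls(**fields)
    return out


# ---------------------------------------------------------------------------
# NWB-style HDF5 (optional)

#: Alias map from common NWB trials-table column names to our fields.
NWB_TRIAL_ALIASES = {
    "block_rule": ("block_rule", "task_rule", "rule"),
    "modality": ("modality", "stimulus_modality", "stim_type"),
    "stim_onset": ("stim_onset", "start_time", "stimulus_onset"),
    "outcome": ("outcome", "trial_outcome", "response_type"),
    "block_index": ("block_index", "block"),
    "laser": ("laser", "opto_condition"),
    "cue": ("cue", "switch_cue"),
}


def write_nwb_like(path, trials: pd.DataFrame, spikes: SpikeSet) -> None:
    """Write a minimal NWB-layout HDF5 container (for round-trips/tests)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("intervals/trials")
        for col in TRIAL_COLUMNS:
            if col == "licks":
                g.create_dataset(
                    "licks", data=[serialize_licks(lk).encode() for lk in trials[col]])
            elif col in ("outcome", "believed_rule"):
                vals = ["" if pd.isna(v) else str(v) for v in trials[col]]
                g.create_dataset(col, data=[v.encode() for v in vals])
            elif trials[col].dtype == object:
                g.create_dataset(col, data=[str(v).encode() for v in trials[col]])
            else:
                g.create_dataset(col, data=trials[col].to_numpy())
        u = f.create_group("units")
        times = np.concatenate([unit.spike_times for unit in spikes]) \
            if len(spikes) else np.array([])
        index = np.cumsum([unit.spike_times.size for unit in spikes])
        u.create_dataset("spike_times", data=times)
        u.create_dataset("spike_times_index", data=index)
        u.create_dataset("id", data=[unit.unit_id.encode() for unit in spikes])
        u.create_dataset("area", data=[unit.area.encode() for unit in spikes])
        u.attrs["session_id"] = spikes.session_id


def read_nwb_session(path) -> tuple[pd.DataFrame, SpikeSet]:
    """Read trials and units from an NWB-layout HDF5 file.

    Requires a trials table under ``/intervals/trials`` and a ``/units``
    group with ragged ``spike_times`` + ``spike_times_index``; column names
    are resolved through :data:`NWB_TRIAL_ALIASES`.
    """
    import h5py

    def _decode(arr):
        return [v.decode() if isinstance(v, bytes) else v for v in arr]

    with h5py.File(path, "r") as f:
        if "intervals/trials" not in f:
            raise IngestionError("file lacks a trials table at /intervals/trials")
        if "units" not in f:
            raise IngestionError("file lacks a 'units' table")
        g = f["intervals/trials"]
        data = {}
        for field, aliases in NWB_TRIAL_ALIASES.items():
            found = next((a for a in aliases if a in g), None)
            if found is None:
                raise IngestionError(
                    f"trials table lacks a column for {field!r} (aliases {aliases})")
            col = g[found][()]
            data[field] = _decode(col) if col.dtype.kind in "OS" else col
        n = len(data["stim_onset"])
        for field in TRIAL_COLUMNS:
            if field in data:
                continue
            if field == "licks":
                raw = _decode(g["licks"][()]) if "licks" in g else [""] * n
                data["licks"] = [parse_licks(x) for x in raw]
            elif field in g:
                col = g[field][()]
                data[field] = _decode(col) if col.dtype.kind in "OS" else col
            else:
                data[field] = {
                    "session_id": ["session"] * n,
                    "mouse_id": ["mouse"] * n,
                    "trial_index": np.arange(1, n + 1),
                    "trial_in_block": np.zeros(n, int),
                    "believed_rule": [pd.NA] * n,
                }.get(field, [pd.NA] * n)
        trials = pd.DataFrame(data)[TRIAL_COLUMNS]
        for col in ("outcome", "believed_rule"):
            trials[col] = trials[col].replace("", pd.NA)
        trials["cue"] = np.asarray(trials["cue"], dtype=bool)

        u = f["units"]
        times = u["spike_times"][()]
        index = u["spike_times_index"][()]
        ids = _decode(u["id"][()])
        areas = _decode(u["area"][()]) if "area" in u else ["unknown"] * len(ids)
        starts = np.concatenate([[0], index[:-1]]).astype(int)
        units = [
            Unit(unit_id=str(ids[i]), area=str(areas[i]),
                 spike_times=times[starts[i]: int(index[i])])
            for i in range(len(ids))
        ]
        session_id = u.attrs.get("session_id", "session")
    return trials, SpikeSet(units=units, session_id=str(session_id))
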
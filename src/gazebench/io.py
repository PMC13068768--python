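"""Readers and writers for the sample/event CSV dialects and JSON configs.

Samples CSV: columns ``t_ms,x,y[,label]``; missing coordinates are empty
fields; labels are parsed case-insensitively.  Events CSV: one row per
event with indices (0-based, inclusive), times, and kinematic features.
Round-trips are lossless for finite values.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EventLabel, GazeRecording
from .detectors import DetectorConfig
from .events import Event
from .synthetic import SimulationConfig

__all__ = [
    "parse_label",
    "read_samples",
    "write_samples",
    "read_events",
    "write_events",
    "load_detector_config",
    "load_simulation_config",
    "dump_config",
]

_LABEL_ALIASES = {
    "undefined": EventLabel.UNDEFINED,
    "u/i": EventLabel.UNDEFINED,
    "unknown": EventLabel.UNDEFINED,
    "fixation": EventLabel.FIXATION,
    "fix": EventLabel.FIXATION,
    "saccade": EventLabel.SACCADE,
    "sac": EventLabel.SACCADE,
    "pso": EventLabel.PSO,
    "smooth_pursuit": EventLabel.SMOOTH_PURSUIT,
    "pursuit": EventLabel.SMOOTH_PURSUIT,
    "sp": EventLabel.SMOOTH_PURSUIT,
    "blink": EventLabel.BLINK,
    "bli": EventLabel.BLINK,
}


def parse_label(token: str) -> EventLabel:
    key = str(token).strip().lower()
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise ValueError(
        f"unknown label token {token!r}; valid tokens: {sorted(_LABEL_ALIASES)}"
    )


_SAMPLE_COLUMNS = ("t_ms", "x", "y", "label")


def read_samples(path: str | Path) -> tuple[GazeRecording, np.ndarray | None]:
    """Read a samples CSV; returns the recording and labels (or None)."""
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in _SAMPLE_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns {unknown} in {path}", stacklevel=2)
    for col in ("t_ms", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df.index[df["t_ms"].isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed timestamp at data row {bad[0] + 1}")
    rec = GazeRecording(
        t=df["t_ms"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
    )
    labels = None
    if "label" in df.columns:
        labels = np.array(
            [int(parse_label(v)) for v in df["label"].fillna("undefined")],
            dtype=np.int8,
        )
    return rec, labels


def write_samples(
    path: str | Path, rec: GazeRecording, labels: np.ndarray | None = None
) -> None:
    data = {"t_ms": rec.t, "x": rec.x, "y": rec.y}
    if labels is not None:
        data["label"] = [EventLabel(int(v)).name.lower() for v in labels]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


_EVENT_COLUMNS = [
    "label", "start_idx", "end_idx", "t_on_ms", "t_off_ms",
    "duration_ms", "amplitude_deg", "dispersion_deg", "vmax", "vmin",
]


def write_events(path: str | Path, events: list[Event]) -> None:
    rows = [
        [
            ev.label.name.lower(), ev.start_index, ev.end_index,
            ev.start_time, ev.end_time, ev.duration,
            ev.amplitude, ev.dispersion, ev.peak_velocity, ev.min_velocity,
        ]
        for ev in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_events(path: str | Path) -> list[Event]:
    df = pd.read_csv(path)
    return [
        Event(
            label=parse_label(r["label"]),
            start_index=int(r["start_idx"]),
            end_index=int(r["end_idx"]),
            start_time=float(r["t_on_ms"]),
            end_time=float(r["t_off_ms"]),
            duration=float(r["duration_ms"]),
            amplitude=float(r["amplitude_deg"]),
            dispersion=float(r["dispersion_deg"]),
            peak_velocity=float(r["vmax"]),
            min_velocity=float(r["vmin"]),
        )
        for _, r in df.iterrows()
    ]


def _load_config(path: str | Path, cls):
    with open(path) as fh:
        raw = json.load(fh)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        warnings.warn(f"ignoring unknown config keys {sorted(unknown)}", stacklevel=2)
    kwargs = {k: v for k, v in raw.items() if k in names}
    if cls is SimulationConfig and "saccade_amplitude_range" in kwargs:
        kwargs["saccade_amplitude_range"] = tuple(kwargs["saccade_amplitude_range"])
    return cls(**kwargs)


def load_detector_config(path: str | Path) -> DetectorConfig:
    return _load_config(path, DetectorConfig)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    return _load_config(path, SimulationConfig)


def dump_config(path: str | Path, cfg) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, default=list)
        fh.write("\n")
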
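"""Readers and writers for the plain-text interchange formats.

Spikes travel as CSV with header ``unit_id,timestamp_s`` (one spike per row)
plus an optional JSON sidecar mapping unit_id to genotype/day/session labels.
Event schedules are CSV with ``label,onset_s,duration_s,trial_index``.  Sweeps
are CSV ``time_s,value`` with a JSON sidecar carrying sampling rate and
modality metadata.  Configs are YAML mirroring :class:`ScheduleConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .protocol import (
    Epoch,
    EpochLabel,
    EventSchedule,
    Genotype,
    ScheduleConfig,
    SpikeTrain,
    ValidationError,
)

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_schedule",
    "write_schedule",
    "read_sweep",
    "write_sweep",
    "read_config",
    "write_config",
]


def write_spikes(trains: list[SpikeTrain], path: str | Path) -> None:
    path = Path(path)
    frames = [
        pd.DataFrame({"unit_id": t.unit_id, "timestamp_s": t.timestamps_s})
        for t in trains
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit_id", "timestamp_s"])
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        t.unit_id: {"genotype": t.genotype.value, "day": t.day, "session_id": t.session_id}
        for t in trains
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    """Read spike trains; timestamps round-trip bit-exactly through write_spikes."""
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"unit_id": str, "timestamp_s": float}, float_precision="round_trip"
    )
    if list(df.columns) != ["unit_id", "timestamp_s"]:
        raise ValidationError(
            f"{path}: expected header 'unit_id,timestamp_s', got {list(df.columns)}"
        )
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        m = meta.get(str(unit_id), {})
        trains.append(
            SpikeTrain(
                unit_id=str(unit_id),
                timestamps_s=grp["timestamp_s"].to_numpy(),
                genotype=Genotype(m.get("genotype", "CONTROL")),
                day=int(m.get("day", 1)),
                session_id=str(m.get("session_id", "session")),
            )
        )
    return trains


def write_schedule(schedule: EventSchedule, path: str | Path) -> None:
    rows = [
        {
            "label": e.label.value,
            "onset_s": e.onset_s,
            "duration_s": e.duration_s,
            "trial_index": "" if e.trial_index is None else e.trial_index,
        }
        for e in schedule.epochs
    ]
    pd.DataFrame(rows, columns=["label", "onset_s", "duration_s", "trial_index"]).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = {"session_id": schedule.session_id, "day": schedule.day}
    path = Path(path)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_schedule(path: str | Path) -> EventSchedule:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    epochs = tuple(
        Epoch(
            label=EpochLabel(row["label"]),
            onset_s=float(row["onset_s"]),
            duration_s=float(row["duration_s"]),
            trial_index=None if pd.isna(row["trial_index"]) else int(row["trial_index"]),
        )
        for _, row in df.iterrows()
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EventSchedule(
        epochs, session_id=meta.get("session_id", "session"), day=int(meta.get("day", 1))
    )


def write_sweep(sweep, path: str | Path) -> None:
    """Write a sweep as ``time_s,value`` CSV plus a JSON metadata sidecar."""
    from .slice_ephys import SweepTrace  # local import to avoid a cycle

    assert isinstance(sweep, SweepTrace)
    path = Path(path)
    pd.DataFrame({"time_s": sweep.times_s, "value": sweep.samples}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = {
        "sampling_rate_hz": sweep.sampling_rate_hz,
        "units": "mV" if sweep.modality.value in ("COMPOUND_PSP", "EPSP_ISOLATED") else "pA",
        "modality": sweep.modality.value,
        "stimulus_onset_s": sweep.stimulus_onset_s,
        "cell_id": sweep.cell_id,
        "condition": sweep.condition.value,
        "genotype": sweep.genotype,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_sweep(path: str | Path):
    from .slice_ephys import Condition, Modality, SweepTrace

    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "value"]:
        raise ValidationError(f"{path}: expected header 'time_s,value'")
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValidationError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    return SweepTrace(
        samples=df["value"].to_numpy(),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        modality=Modality(meta["modality"]),
        stimulus_onset_s=meta.get("stimulus_onset_s"),
        cell_id=meta.get("cell_id", "cell"),
        condition=Condition(meta.get("condition", "NAIVE")),
        genotype=meta.get("genotype", "CONTROL"),
    )


def write_config(config: ScheduleConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


def read_config(path: str | Path) -> ScheduleConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(ScheduleConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return ScheduleConfig(**data)
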
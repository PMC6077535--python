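"""Plain-text serialization of sessions, records, and metrics.

Everything round-trips through delimited text and JSON: signals as a TSV
matrix (one column per channel), events and ground truth as TSV tables,
configuration as YAML.  Floats are written with full shortest-repr
precision so save/load does not change values.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthgen import GeneratedSession, NodeTimingModel, ParadigmConfig, SubjectProfile
from .types import EEGRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_session",
    "load_session",
    "save_config",
    "load_config",
]


def save_recording(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording as TSV: header row of channel labels, one sample
    per line; sampling rate in a JSON sidecar ``<path>.json``."""
    path = Path(path)
    df = pd.DataFrame(recording.data.T, columns=recording.ch_names)
    df.to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(
        json.dumps({"sfreq": recording.sfreq, "ch_names": recording.ch_names})
    )


def load_recording(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return EEGRecording(
        data=df[meta["ch_names"]].to_numpy().T,
        sfreq=meta["sfreq"],
        ch_names=meta["ch_names"],
    )


def save_session(session: GeneratedSession, directory: str | Path) -> None:
    """Persist a generated session: signals, events, truth tables."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_recording(session.recording, d / "signals.tsv")
    session.events.to_csv(d / "events.tsv", sep="\t", index=False)
    for name, table in session.truth.items():
        table.to_csv(d / f"truth_{name}.tsv", sep="\t", index=False)


def load_session(directory: str | Path) -> GeneratedSession:
    d = Path(directory)
    recording = load_recording(d / "signals.tsv")
    events = pd.read_csv(d / "events.tsv", sep="\t", float_precision="round_trip")
    truth = {}
    for f in sorted(d.glob("truth_*.tsv")):
        truth[f.stem.removeprefix("truth_")] = pd.read_csv(
            f, sep="\t", float_precision="round_trip"
        )
    return GeneratedSession(recording=recording, events=events, truth=truth)


def save_config(
    cfg: ParadigmConfig,
    profile: SubjectProfile,
    nodes: list[NodeTimingModel],
    path: str | Path,
) -> None:
    payload = {
        "paradigm": dataclasses.asdict(cfg),
        "subject": dataclasses.asdict(profile),
        "nodes": [dataclasses.asdict(n) for n in nodes],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(
    path: str | Path,
) -> tuple[ParadigmConfig, SubjectProfile, list[NodeTimingModel]]:
    payload = yaml.safe_load(Path(path).read_text())
    para = payload.get("paradigm", {})
    for key in ("channel_labels", "phase_conditions"):
        if key in para and isinstance(para[key], list):
            para[key] = tuple(para[key])
    cfg = ParadigmConfig(**para)
    profile = SubjectProfile(**payload.get("subject", {}))
    nodes = [NodeTimingModel(**n) for n in payload.get("nodes", [])]
    return cfg, profile, nodes
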
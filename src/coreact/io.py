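"""Disk formats: long-CSV event matrices with JSON sidecars, match-table
CSVs, EEG/EMG and hypnogram CSVs, and the experiment manifest.

All formats are plain text so that simulated experiments round-trip through
the CLI deterministically. An event matrix is stored as a long CSV
``(cell_id, frame, value)`` of its nonzero entries plus a sidecar JSON with
``frame_rate``, ``timestamps`` and ``cell_ids``; the manifest JSON lists the
sessions (kind + file paths), match tables and group label of one animal.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from coreact.core import EventMatrix, ExperimentSet, MatchTable, SessionRecord
from coreact.sleep import EEGEMGRecord, Hypnogram

FLOAT_FMT = "%.10g"


def write_event_matrix(matrix: EventMatrix, stem: Path) -> dict:
    """Write ``<stem>.csv`` (long nonzero entries) + ``<stem>.json`` sidecar."""
    stem = Path(stem)
    rows, cols = np.nonzero(matrix.values)
    df = pd.DataFrame({
        "cell_id": matrix.cell_ids[rows],
        "frame": cols,
        "value": matrix.values[rows, cols],
    })
    df.to_csv(stem.with_suffix(".csv"), index=False, float_format=FLOAT_FMT)
    sidecar = {
        "frame_rate": matrix.frame_rate,
        "n_frames": matrix.n_frames,
        "timestamps": matrix.timestamps.tolist(),
        "cell_ids": matrix.cell_ids.tolist(),
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)
    return {"events": stem.with_suffix(".csv").name,
            "sidecar": stem.with_suffix(".json").name}


def read_event_matrix(events_csv: Path, sidecar_json: Path) -> EventMatrix:
    with open(sidecar_json) as fh:
        side = json.load(fh)
    cell_ids = np.asarray(side["cell_ids"])
    values = np.zeros((len(cell_ids), side["n_frames"]))
    index = {c: i for i, c in enumerate(cell_ids.tolist())}
    df = pd.read_csv(events_csv)
    if len(df):
        rows = df["cell_id"].map(index).to_numpy()
        values[rows, df["frame"].to_numpy()] = df["value"].to_numpy()
    return EventMatrix(
        values, side["frame_rate"], np.asarray(side["timestamps"]), cell_ids
    )


def write_match_tables(tables: list[MatchTable], path: Path) -> None:
    rows = [
        {"session_a": t.session_a, "session_b": t.session_b,
         "cell_id_a": a, "cell_id_b": b}
        for t in tables for a, b in t.pairs
    ]
    pd.DataFrame(
        rows, columns=["session_a", "session_b", "cell_id_a", "cell_id_b"]
    ).to_csv(path, index=False)


def read_match_tables(path: Path) -> list[MatchTable]:
    df = pd.read_csv(path)
    tables = []
    for (a, b), grp in df.groupby(["session_a", "session_b"], sort=True):
        pairs = list(zip(grp["cell_id_a"].tolist(), grp["cell_id_b"].tolist()))
        tables.append(MatchTable(str(a), str(b), pairs))
    return tables


def write_eeg_emg(record: EEGEMGRecord, path: Path) -> None:
    t = record.start_ms + np.arange(record.n_samples) * 1000.0 / record.rate
    pd.DataFrame({"time_ms": t, "eeg": record.eeg, "emg": record.emg}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_eeg_emg(path: Path) -> EEGEMGRecord:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy()
    rate = 1000.0 / float(np.median(np.diff(t))) if len(t) > 1 else 100.0
    return EEGEMGRecord(
        eeg=df["eeg"].to_numpy(), emg=df["emg"].to_numpy(),
        start_ms=float(t[0]) if len(t) else 0.0, rate=round(rate, 6),
    )


def write_hypnogram(hyp: Hypnogram, path: Path) -> None:
    pd.DataFrame({
        "epoch_start_ms": hyp.epoch_starts_ms, "state": hyp.states,
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_hypnogram(path: Path, epoch_s: float = 6.0) -> Hypnogram:
    df = pd.read_csv(path)
    starts = df["epoch_start_ms"].to_numpy()
    if len(starts) > 1:
        epoch_s = float(np.median(np.diff(starts))) / 1000.0
    return Hypnogram(
        states=df["state"].to_numpy(dtype=object), epoch_s=epoch_s,
        start_ms=float(starts[0]) if len(starts) else 0.0,
    )


def write_experiment(exp: ExperimentSet, outdir: Path) -> Path:
    """Write all sessions + match tables + manifest under ``outdir``.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"group_label": exp.group_label, "sessions": {}}
    for name in sorted(exp.sessions):
        rec = exp.sessions[name]
        entry = {"kind": rec.kind}
        entry.update(write_event_matrix(rec.matrix, outdir / name))
        if rec.locomotion is not None:
            loco = outdir / f"{name}_locomotion.csv"
            pd.DataFrame({
                "time_ms": rec.locomotion_timestamps,
                "speed": rec.locomotion,
            }).to_csv(loco, index=False, float_format=FLOAT_FMT)
            entry["locomotion"] = loco.name
        if rec.eeg_emg is not None:
            ee = outdir / f"{name}_eeg_emg.csv"
            write_eeg_emg(rec.eeg_emg, ee)
            entry["eeg_emg"] = ee.name
        manifest["sessions"][name] = entry
    write_match_tables(exp.match_tables, outdir / "match_tables.csv")
    manifest["match_tables"] = "match_tables.csv"
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def read_experiment(manifest_path: Path) -> ExperimentSet:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    sessions = {}
    for name, entry in manifest["sessions"].items():
        matrix = read_event_matrix(
            root / entry["events"], root / entry["sidecar"]
        )
        loco = loco_ts = None
        if "locomotion" in entry:
            df = pd.read_csv(root / entry["locomotion"])
            loco = df["speed"].to_numpy()
            loco_ts = df["time_ms"].to_numpy()
        eeg = None
        if "eeg_emg" in entry:
            eeg = read_eeg_emg(root / entry["eeg_emg"])
        sessions[name] = SessionRecord(
            kind=entry["kind"], matrix=matrix, locomotion=loco,
            locomotion_timestamps=loco_ts, eeg_emg=eeg,
        )
    tables = read_match_tables(root / manifest["match_tables"])
    return ExperimentSet(
        sessions=sessions, match_tables=tables,
        group_label=manifest.get("group_label", "unspecified"),
    )


def config_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def config_from_dict(cls, d: dict):
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for k, v in d.items():
        if k not in fields:
            raise KeyError(f"unknown config field {k!r}")
        default = fields[k].default
        if isinstance(v, list) and (
            isinstance(default, tuple)
            or fields[k].type in ("tuple", tuple)
        ):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)
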
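"""Session, schedule and audio file I/O.

Sessions travel either as plain CSV (one file per subject and chromophore:
a time column plus one column per channel) or as a minimal SNIRF-style HDF5
container; turn audio as 16-bit PCM WAV; schedules, ground truth and QC
reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocess import Channel, ChannelGeometry
from .synthdyad import DyadSession, SubjectRecording, Turn, TurnSchedule

__all__ = [
    "write_schedule_json",
    "read_schedule_json",
    "write_session_csv",
    "read_session_csv",
    "write_session_snirf",
    "write_wav",
    "read_wav",
    "write_qc_report",
]

CHROMOPHORES = ("hbo", "hbr", "hbt")


def write_schedule_json(schedule: TurnSchedule, path: str | Path) -> None:
    payload = {
        "run_duration": schedule.run_duration,
        "turn_duration": schedule.turn_duration,
        "turns": [
            {"index": t.index, "speaker": t.speaker, "start": t.start, "end": t.end}
            for t in schedule.turns
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_schedule_json(path: str | Path) -> TurnSchedule:
    payload = json.loads(Path(path).read_text())
    turns = tuple(
        Turn(t["index"], t["speaker"], t["start"], t["end"]) for t in payload["turns"]
    )
    return TurnSchedule(payload["run_duration"], payload["turn_duration"], turns)


def _session_meta(session: DyadSession) -> dict:
    return {
        "dyad_id": session.dyad_id,
        "condition": session.condition,
        "sampling_interval": session.sampling_interval,
        "channels": [dataclasses.asdict(ch) for ch in session.geometry.channels],
    }


def write_session_csv(session: DyadSession, out_dir: str | Path) -> None:
    """One CSV per subject and chromophore plus schedule/metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = np.arange(session.n_samples) * session.sampling_interval
    ids = [ch.channel_id for ch in session.geometry.channels]
    for sid, rec in session.subjects.items():
        for chromo in CHROMOPHORES:
            df = pd.DataFrame(rec.chromophore(chromo).T, columns=ids)
            df.insert(0, "time", t)
            df.to_csv(out / f"{session.dyad_id}_{sid}_{chromo}.csv", index=False)
    write_schedule_json(session.schedule, out / f"{session.dyad_id}_schedule.json")
    (out / f"{session.dyad_id}_meta.json").write_text(
        json.dumps(_session_meta(session), indent=2)
    )


def read_session_csv(out_dir: str | Path, dyad_id: str) -> DyadSession:
    out = Path(out_dir)
    meta = json.loads((out / f"{dyad_id}_meta.json").read_text())
    schedule = read_schedule_json(out / f"{dyad_id}_schedule.json")
    geometry = ChannelGeometry(tuple(Channel(**ch) for ch in meta["channels"]))
    subjects = {}
    for sid in schedule.subjects:
        arrays = {}
        for chromo in CHROMOPHORES:
            df = pd.read_csv(out / f"{dyad_id}_{sid}_{chromo}.csv")
            arrays[chromo] = df.drop(columns="time").to_numpy().T
        subjects[sid] = SubjectRecording(sid, arrays["hbo"], arrays["hbr"], arrays["hbt"])
    return DyadSession(
        dyad_id=meta["dyad_id"],
        condition=meta["condition"],
        schedule=schedule,
        sampling_interval=meta["sampling_interval"],
        geometry=geometry,
        subjects=subjects,
    )


def write_session_snirf(session: DyadSession, path: str | Path) -> None:
    """Minimal SNIRF-style HDF5: one /nirs{i} group per subject with the
    processed concentration time series and channel/ROI labels."""
    with h5py.File(path, "w") as f:
        f.attrs["formatVersion"] = "1.0"
        f.attrs["dyad_id"] = session.dyad_id
        f.attrs["condition"] = session.condition
        t = np.arange(session.n_samples) * session.sampling_interval
        for i, (sid, rec) in enumerate(session.subjects.items(), start=1):
            g = f.create_group(f"nirs{i}")
            g.attrs["subject_id"] = sid
            g.create_dataset("time", data=t)
            for chromo in CHROMOPHORES:
                g.create_dataset(f"dataTimeSeries_{chromo}", data=rec.chromophore(chromo))
            g.create_dataset(
                "channel_ids",
                data=np.array([ch.channel_id for ch in session.geometry.channels], dtype="S"),
            )
            g.create_dataset(
                "channel_rois",
                data=np.array([ch.roi for ch in session.geometry.channels], dtype="S"),
            )


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """16-bit PCM WAV; samples clipped to [-1, 1]."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (x * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return data, int(rate)


def write_qc_report(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default))
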
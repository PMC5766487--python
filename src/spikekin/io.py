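"""Readers and writers for the pipeline's on-disk formats.

Columnar text (tab-separated) for spike trains, kinematics, features and
training histories; flat little-endian float32 binary plus a JSON sidecar
for raw traces.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ContinuousSignal, FeatureSeries, KinematicsSeries, SpikeTrain

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_kinematics",
    "read_kinematics",
    "write_features",
    "read_features",
    "write_raw",
    "read_raw",
    "write_history",
]


def write_spikes(path, trains: Sequence[SpikeTrain]) -> None:
    path = Path(path)
    duration = max(tr.duration for tr in trains)
    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append((t, tr.unit_id))
    df = pd.DataFrame(rows, columns=["time_s", "unit_id"])
    with open(path, "w") as fh:
        fh.write(f"# duration_s={duration!r}\n")
        unit_ids = ",".join(str(tr.unit_id) for tr in trains)
        fh.write(f"# unit_ids={unit_ids}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_spikes(path) -> list[SpikeTrain]:
    path = Path(path)
    duration = None
    unit_ids: list[int] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "duration_s":
                duration = float(val)
            elif key.strip() == "unit_ids":
                unit_ids = [int(v) for v in val.split(",") if v != ""]
    df = pd.read_csv(path, sep="\t", comment="#")
    if duration is None:
        duration = float(df["time_s"].max()) if len(df) else 1.0
    if not unit_ids:
        unit_ids = sorted(df["unit_id"].unique().tolist())
    trains = []
    for uid in unit_ids:
        t = np.sort(df.loc[df["unit_id"] == uid, "time_s"].to_numpy())
        trains.append(SpikeTrain(t, int(uid), duration))
    return trains


def write_kinematics(path, kin: KinematicsSeries) -> None:
    df = pd.DataFrame(
        {
            "time_s": kin.times,
            "hip_deg": kin.hip,
            "knee_deg": kin.knee,
            "ankle_deg": kin.ankle,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_kinematics(path) -> KinematicsSeries:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("kinematics file needs >= 2 samples")
    rate = 1.0 / float(np.mean(np.diff(t)))
    return KinematicsSeries(
        times=t,
        hip=df["hip_deg"].to_numpy(),
        knee=df["knee_deg"].to_numpy(),
        ankle=df["ankle_deg"].to_numpy(),
        rate=rate,
    )


def write_features(path, features: Sequence[FeatureSeries]) -> None:
    frames = []
    for f in features:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": f.times,
                    "value": f.values,
                    "kind": f.kind,
                    "unit_id": f.unit_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_features(path) -> list[FeatureSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (kind, uid), grp in df.groupby(["kind", "unit_id"], sort=True):
        t = grp["time_s"].to_numpy()
        fs = 1.0 / float(np.mean(np.diff(t))) if t.size > 1 else 1.0
        out.append(
            FeatureSeries(
                values=grp["value"].to_numpy(),
                fs=fs,
                t0=float(t[0]),
                kind=str(kind),
                unit_id=int(uid),
            )
        )
    return out


def write_raw(path, sig: ContinuousSignal) -> None:
    """Flat little-endian float32 samples plus `<path>.json` sidecar."""
    path = Path(path)
    sig.samples.astype("<f4").tofile(path)
    sidecar = {
        "fs_hz": sig.fs,
        "n_samples": int(sig.samples.size),
        "t0_s": sig.t0,
        "dtype": "<f4",
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_raw(path) -> ContinuousSignal:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    samples = np.fromfile(path, dtype=sidecar.get("dtype", "<f4"))
    if samples.size != sidecar["n_samples"]:
        raise ValueError("sample count disagrees with sidecar")
    return ContinuousSignal(
        samples.astype(float), fs=sidecar["fs_hz"], t0=sidecar.get("t0_s", 0.0)
    )


def write_history(path, history: Sequence[dict]) -> None:
    pd.DataFrame(history, columns=["epoch", "sse_train", "sse_val", "mu"]).to_csv(
        path, sep="\t", index=False
    )
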
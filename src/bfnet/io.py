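"""Session container I/O.

Canonical on-disk layout (all open formats):

* ``lfp.h5`` — HDF5 with ``/lfp`` float32 [samples x channels] and a JSON
  metadata attribute (rate, channel table);
* ``spikes.csv`` — columns ``unit_id, time_s``;
* ``waveforms.h5`` — ``/waveforms`` [unit x channel x sample] plus unit
  and channel id vectors and the waveform sample rate;
* ``epochs.csv`` — ``trial, label, t_start_s, t_end_s`` (half-open, s);
* ``light.csv`` — ``t_s, duration_s``;
* ``ground_truth.json`` — optional synthetic-injection record;
* ``manifest.json`` — file paths, session id, config hash.

Times are seconds from session start throughout.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .lfpproc import ChannelInfo, LFPRecording
from .unitproc import SpikeUnit

MANIFEST_NAME = "manifest.json"


@dataclass
class Session:
    lfp: LFPRecording
    units: list[SpikeUnit]
    epochs: pd.DataFrame
    light: pd.DataFrame
    ground_truth: "object | None" = None
    session_id: str = ""


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------


def save_session(out_dir: Path, lfp: LFPRecording, units: list[SpikeUnit],
                 epochs: pd.DataFrame, light: pd.DataFrame,
                 ground_truth=None, session_id: str = "synthetic") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    meta = {
        "rate": lfp.rate,
        "channels": [c.__dict__ for c in lfp.channels],
    }
    with h5py.File(out_dir / "lfp.h5", "w") as f:
        f.create_dataset("lfp", data=lfp.samples.astype(np.float32),
                         track_times=False)
        f.attrs["meta"] = json.dumps(meta)

    rows = [(u.id, t) for u in units for t in u.spike_times]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        out_dir / "spikes.csv", index=False
    )

    with h5py.File(out_dir / "waveforms.h5", "w") as f:
        if units:
            wf = np.stack([u.mean_waveform for u in units])
            f.create_dataset("waveforms", data=wf, track_times=False)
            f.create_dataset("unit_ids", data=np.array([u.id for u in units]),
                             track_times=False)
            f.create_dataset(
                "channel_ids",
                data=np.array([u.waveform_channels for u in units]),
                track_times=False,
            )
            f.create_dataset(
                "peak_channels",
                data=np.array([u.peak_channel for u in units]),
                track_times=False,
            )
            f.create_dataset(
                "is_cholinergic",
                data=np.array([u.is_cholinergic for u in units], dtype=bool),
                track_times=False,
            )
            f.create_dataset(
                "regions",
                data=np.array([u.region for u in units], dtype=h5py.string_dtype()),
                track_times=False,
            )
        f.attrs["rate"] = units[0].waveform_rate if units else 20_000.0

    epochs.to_csv(out_dir / "epochs.csv", index=False)
    light.to_csv(out_dir / "light.csv", index=False)
    if ground_truth is not None:
        (out_dir / "ground_truth.json").write_text(ground_truth.to_json())

    manifest = {
        "session_id": session_id,
        "lfp": "lfp.h5",
        "spikes": "spikes.csv",
        "waveforms": "waveforms.h5",
        "epochs": "epochs.csv",
        "light": "light.csv",
        "ground_truth": "ground_truth.json" if ground_truth is not None else None,
        "config_hash": _hash_files(out_dir),
    }
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return out_dir / MANIFEST_NAME


def _hash_files(out_dir: Path) -> str:
    h = hashlib.sha256()
    for name in sorted(p.name for p in out_dir.iterdir() if p.name != MANIFEST_NAME):
        h.update(name.encode())
        h.update((out_dir / name).read_bytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------


def _validate_epochs(epochs: pd.DataFrame) -> None:
    required = {"trial", "label", "t_start_s", "t_end_s"}
    if not required <= set(epochs.columns):
        raise ValueError(f"epoch table must have columns {sorted(required)}")
    bad = epochs[epochs["t_end_s"] <= epochs["t_start_s"]]
    if len(bad):
        raise ValueError(f"epoch with non-positive duration in trial "
                         f"{bad.iloc[0]['trial']}")
    s = epochs.sort_values("t_start_s")
    overlap = s["t_start_s"].to_numpy()[1:] < s["t_end_s"].to_numpy()[:-1] - 1e-9
    if overlap.any():
        i = int(np.flatnonzero(overlap)[0])
        raise ValueError(
            f"overlapping epochs in trial {s.iloc[i]['trial']} "
            f"({s.iloc[i]['label']} / {s.iloc[i + 1]['label']})"
        )


def load_session(path: str | Path) -> Session:
    """Load a session from a manifest file or its directory.

    All container invariants are checked at load time: unique channel
    ids, consistent channel ids between the LFP and the waveforms,
    non-overlapping epochs, strictly increasing spike times.
    """
    path = Path(path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    if not path.exists():
        raise FileNotFoundError(f"no manifest at {path}")
    base = path.parent
    manifest = json.loads(path.read_text())

    with h5py.File(base / manifest["lfp"], "r") as f:
        samples = f["lfp"][()]
        meta = json.loads(f.attrs["meta"])
    channels = [ChannelInfo(**c) for c in meta["channels"]]
    lfp = LFPRecording(samples=samples, rate=meta["rate"], channels=channels)
    duration = lfp.duration

    epochs = pd.read_csv(base / manifest["epochs"])
    if len(epochs):
        _validate_epochs(epochs)
    light = pd.read_csv(base / manifest["light"])

    spikes = pd.read_csv(base / manifest["spikes"])
    units: list[SpikeUnit] = []
    with h5py.File(base / manifest["waveforms"], "r") as f:
        rate = float(f.attrs["rate"])
        if "waveforms" in f:
            wf = f["waveforms"][()]
            unit_ids = f["unit_ids"][()]
            chan_ids = f["channel_ids"][()]
            peaks = f["peak_channels"][()]
            chol = f["is_cholinergic"][()]
            regions = [r.decode() for r in f["regions"][()]]
            known = set(lfp.channel_ids)
            for i, uid in enumerate(unit_ids):
                bad = [int(c) for c in chan_ids[i] if int(c) not in known]
                if bad:
                    raise ValueError(
                        f"waveform channels not in LFP container: {bad}"
                    )
                t = spikes.loc[spikes["unit_id"] == uid, "time_s"].to_numpy()
                units.append(
                    SpikeUnit(
                        id=int(uid), region=regions[i], spike_times=np.sort(t),
                        mean_waveform=wf[i], waveform_rate=rate,
                        waveform_channels=[int(c) for c in chan_ids[i]],
                        peak_channel=int(peaks[i]), is_cholinergic=bool(chol[i]),
                        session_duration=duration,
                    )
                )

    truth = None
    gt_name = manifest.get("ground_truth")
    if gt_name and (base / gt_name).exists():
        from .synth import GroundTruth

        truth = GroundTruth.from_json((base / gt_name).read_text())
    return Session(lfp=lfp, units=units, epochs=epochs, light=light,
                   ground_truth=truth, session_id=manifest.get("session_id", ""))
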
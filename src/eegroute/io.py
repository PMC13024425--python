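"""On-disk interchange: array bundles (npz + JSON sidecar) and EDF reading.

The array bundle is the package's primary format: a compressed ``.npz``
holding the numeric arrays plus a ``.json`` sidecar with subject id, label,
sampling rate, channel names and provenance fields.  EDF files are read
through MNE; recordings are converted to µV on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synth import RawRecording
from .tensorize import EpochSet

__all__ = [
    "save_recording", "load_recording", "save_cohort", "load_cohort",
    "save_epochs", "load_epochs", "read_edf",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_recording(rec: RawRecording, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path, data=rec.data)
    meta = {
        "subject_id": rec.subject_id,
        "label": int(rec.label),
        "sfreq": float(rec.sfreq),
        "channel_names": list(rec.channel_names),
        "units": "uV",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as f:
        data = f["data"].copy()
    return RawRecording(
        subject_id=meta["subject_id"], label=int(meta["label"]),
        data=data, sfreq=float(meta["sfreq"]),
        channel_names=list(meta["channel_names"]))


def save_cohort(recs: list[RawRecording], out_dir: str | Path) -> None:
    """One bundle per subject plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for rec in recs:
        name = f"{rec.subject_id}.npz"
        save_recording(rec, out_dir / name)
        names.append(name)
    (out_dir / "manifest.json").write_text(json.dumps({"recordings": names}, indent=2))


def load_cohort(in_dir: str | Path) -> list[RawRecording]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    return [load_recording(in_dir / name) for name in manifest["recordings"]]


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path, data=epochs.data, labels=epochs.labels,
                        subject_ids=np.asarray(epochs.subject_ids, dtype=str))
    meta = {
        "sfreq": float(epochs.sfreq),
        "band_mode": epochs.band_mode,
        "units": epochs.units,
        "n_epochs": int(epochs.n_epochs),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with np.load(path) as f:
        data = f["data"].copy()
        labels = f["labels"].copy()
        subject_ids = f["subject_ids"].copy()
    return EpochSet(data=data, subject_ids=subject_ids.astype(str),
                    labels=labels.astype(int), sfreq=meta["sfreq"],
                    band_mode=meta["band_mode"], units=meta["units"])


def read_edf(path: str | Path, subject_id: str, label: int) -> RawRecording:
    """Read a continuous EDF recording into a µV RawRecording."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    return RawRecording(subject_id=subject_id, label=int(label), data=data,
                        sfreq=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names))
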
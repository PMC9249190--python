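"""HDF5 session/epoch layouts, TSV feature files and run manifests.

Canonical on-disk session layout (one file per subject x task)::

    /eeg      float64 (n_samples, n_eeg)
    /emg      float64 (n_samples, n_emg)
    /events   compound (sample int64, trial int32, task int32, phase S16)
    attrs: fs, subject, task, ground_truth (bool per sEMG channel),
           eeg_labels, emg_labels

Epoch files store ``/epochs/s<subject>/t<task>/tr<trial>/{eeg,emg}`` with
the same attributes per trial group.  Feature tables are tab-separated text
with the id columns first and one named column per EEG predictor.  The
manifest records parameters and SHA-256 hashes of every produced artifact
so identical configurations yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .preprocess import TrialEpoch
from .simulate import Event, Session

__all__ = [
    "write_session", "read_session", "write_study",
    "write_epochs", "read_epochs",
    "write_features", "read_features",
    "sha256_file", "write_manifest",
]

_EVENT_DTYPE = np.dtype([("sample", "<i8"), ("trial", "<i4"),
                         ("task", "<i4"), ("phase", "S16")])


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=session.eeg)
        f.create_dataset("emg", data=session.emg)
        ev = np.array([(e.sample, e.trial, e.task, e.phase.encode())
                       for e in session.events], dtype=_EVENT_DTYPE)
        f.create_dataset("events", data=ev)
        f.attrs["fs"] = session.fs
        f.attrs["subject"] = session.subject_id
        f.attrs["task"] = session.task_id
        f.attrs["ground_truth"] = np.asarray(session.ground_truth, dtype=bool)
        f.attrs["eeg_labels"] = [s.encode() for s in session.eeg_labels]
        f.attrs["emg_labels"] = [s.encode() for s in session.emg_labels]
    return path


def read_session(path: str | Path) -> Session:
    with h5py.File(path, "r") as f:
        try:
            events = [Event(int(r["sample"]), int(r["trial"]), int(r["task"]),
                            r["phase"].decode()) for r in f["events"][()]]
            return Session(
                eeg=f["eeg"][()], emg=f["emg"][()], fs=float(f.attrs["fs"]),
                events=events, subject_id=int(f.attrs["subject"]),
                task_id=int(f.attrs["task"]),
                ground_truth=tuple(bool(b) for b in f.attrs["ground_truth"]),
                eeg_labels=tuple(s.decode() if isinstance(s, bytes) else s
                                 for s in f.attrs["eeg_labels"]),
                emg_labels=tuple(s.decode() if isinstance(s, bytes) else s
                                 for s in f.attrs["emg_labels"]))
        except KeyError as err:
            raise IOError(f"{path}: malformed session file, missing {err}") from err


def write_study(sessions: Iterable[Session], labels: pd.DataFrame,
                out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in sessions:
        paths.append(write_session(
            s, out_dir / f"session_s{s.subject_id:02d}_t{s.task_id}.h5"))
    label_path = out_dir / "labels.tsv"
    labels.to_csv(label_path, sep="\t", index=False)
    paths.append(label_path)
    return paths


def write_epochs(epochs: Sequence[TrialEpoch], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for ep in epochs:
            g = f.create_group(
                f"epochs/s{ep.subject_id:02d}/t{ep.task_id}/tr{ep.trial_id:03d}")
            g.create_dataset("eeg", data=ep.eeg)
            g.create_dataset("emg", data=ep.emg)
            g.attrs["fs"] = ep.fs
            g.attrs["labels"] = np.asarray(ep.labels, dtype=bool)
    return path


def read_epochs(path: str | Path) -> list[TrialEpoch]:
    out: list[TrialEpoch] = []
    with h5py.File(path, "r") as f:
        root = f["epochs"]
        for skey in sorted(root):
            for tkey in sorted(root[skey]):
                for rkey in sorted(root[skey][tkey]):
                    g = root[skey][tkey][rkey]
                    out.append(TrialEpoch(
                        eeg=g["eeg"][()], emg=g["emg"][()],
                        fs=float(g.attrs["fs"]),
                        subject_id=int(skey[1:]), task_id=int(tkey[1:]),
                        trial_id=int(rkey[2:]),
                        labels=tuple(bool(b) for b in g.attrs["labels"])))
    return out


def write_features(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(params: dict, artifacts: Iterable[str | Path],
                   path: str | Path) -> Path:
    path = Path(path)
    manifest = {
        "parameters": params,
        "artifacts": {Path(p).name: sha256_file(p) for p in artifacts},
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                               default=str) + "\n")
    return path
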
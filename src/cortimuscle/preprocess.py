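"""Filtering, epoching and truncation of synchronous EEG-sEMG recordings.

The analysis band-passes EEG to 2-100 Hz and sEMG to 5-200 Hz (no sEMG
rectification anywhere), notches line interference at 50 Hz, epochs on the
contraction triggers, and keeps the central 3 s of each 5 s contraction
(1 s truncated from head and tail).  Filters are zero-phase
(forward-backward 4th-order Butterworth), which preserves the relative
EEG-EMG timing that the delay-sensitive coupling estimators depend on.

Artifact correction (ICA-based pipelines and friends) is intentionally a
no-op hook here: synthetic sessions contain no such artifacts, and real-data
users can plug their own stage in via ``artifact_hook``.

Conventions: 0-based sample indices, half-open intervals ``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import signal

from .simulate import Session

__all__ = [
    "EpochingError",
    "TrialEpoch",
    "bandpass",
    "notch",
    "epoch_and_truncate",
    "preprocess_session",
    "EEG_BAND",
    "EMG_BAND",
]

EEG_BAND: tuple[float, float] = (2.0, 100.0)
EMG_BAND: tuple[float, float] = (5.0, 200.0)


class EpochingError(RuntimeError):
    """Raised when triggers and recording length are inconsistent."""


@dataclass
class TrialEpoch:
    """One synchronous 3 s contraction segment (EEG n x 53, sEMG n x 4)."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    subject_id: int
    task_id: int
    trial_id: int
    labels: tuple[bool, ...]  # per sEMG channel: is_task_related

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != self.emg.shape[0]:
            raise ValueError("eeg and emg row counts must match")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[0]


def bandpass(x: np.ndarray, fs: float, f_low: float, f_high: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0; length-preserving."""
    if not (0.0 < f_low < f_high < fs / 2.0):
        raise ValueError(
            f"band edges ({f_low}, {f_high}) must satisfy "
            f"0 < f_low < f_high < fs/2 = {fs / 2}")
    sos = signal.butter(order, [f_low, f_high], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def notch(x: np.ndarray, fs: float, f0: float = 50.0,
          q: float = 35.0) -> np.ndarray:
    """Zero-phase IIR notch at ``f0`` (narrow: < 1 dB loss at f0 +- 5 Hz)."""
    if not (0.0 < f0 < fs / 2.0):
        raise ValueError(f"notch frequency {f0} must lie below Nyquist {fs / 2}")
    b, a = signal.iirnotch(f0, q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float), axis=0)


def epoch_and_truncate(session: Session, head_s: float = 1.0,
                       epoch_s: float = 3.0) -> list[TrialEpoch]:
    """Cut one epoch per contraction trigger: samples [onset + head_s*fs,
    onset + (head_s+epoch_s)*fs), i.e. the central 3 s of a 5 s contraction.

    Raises :class:`EpochingError`, naming the trial, if an epoch would run
    past the end of the recording; no partial epoch is emitted.
    """
    fs = session.fs
    start_off = int(round(head_s * fs))
    n_epoch = int(round(epoch_s * fs))
    onsets = [(e.trial, e.sample) for e in session.events
              if e.phase == "contraction"]
    if not onsets:
        raise EpochingError("session contains no contraction triggers")
    epochs: list[TrialEpoch] = []
    for trial, onset in onsets:
        start = onset + start_off
        stop = start + n_epoch
        if stop > session.n_samples:
            raise EpochingError(
                f"trial {trial}: epoch [{start}, {stop}) exceeds recording "
                f"length {session.n_samples}")
        epochs.append(TrialEpoch(
            eeg=session.eeg[start:stop].copy(),
            emg=session.emg[start:stop].copy(),
            fs=fs, subject_id=session.subject_id, task_id=session.task_id,
            trial_id=trial, labels=tuple(session.ground_truth)))
    return epochs


def preprocess_session(
    session: Session,
    eeg_band: tuple[float, float] = EEG_BAND,
    emg_band: tuple[float, float] = EMG_BAND,
    notch_freq: float | None = 50.0,
    artifact_hook: Callable[[Session], Session] | None = None,
) -> list[TrialEpoch]:
    """Filter a session (EEG band, sEMG band, optional notch) and epoch it.

    ``artifact_hook`` runs after filtering and before epoching; the default
    is a no-op (see module docstring).
    """
    eeg = bandpass(session.eeg, session.fs, *eeg_band)
    emg = bandpass(session.emg, session.fs, *emg_band)
    if notch_freq is not None:
        eeg = notch(eeg, session.fs, notch_freq)
        emg = notch(emg, session.fs, notch_freq)
    filtered = replace(session, eeg=eeg, emg=emg)
    if artifact_hook is not None:
        filtered = artifact_hook(filtered)
    return epoch_and_truncate(filtered)
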
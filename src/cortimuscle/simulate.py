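"""Synthetic joint EEG-sEMG session generator.

Emulates the statistical structure of a high-density EEG / multi-channel
surface-EMG contraction study: each session holds a fixed number of trials,
each trial a rest window followed by a contraction window.  During
contraction, band-limited stochastic cortical drives (band-pass filtered
Gaussian noise in the alpha, beta and gamma ranges) appear on a small set of
sensorimotor EEG channels and are transmitted -- after a corticomuscular
conduction delay -- to the sEMG channels of the muscles engaged by the task.
Non-task sEMG channels carry independent noise of matched variance, so the
generator provides exact ground truth for every downstream estimator.

The EEG background is per-channel 1/f ("pink") noise plus a shared low-rank
spatial mixture, which gives channel-selection methods a non-trivially
correlated design.  Two transmission modes are available:

* ``"modulated"`` (default): the delayed drive is added linearly to the sEMG
  channel *and* amplitude-modulates a broadband (5-200 Hz) carrier, so the
  sEMG spectrum is realistically broadband while the drive retains a linear
  (coherence-visible) component.
* ``"linear"``: pure additive transmission plus white noise -- the provable
  regime used by recovery oracles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FREQ_BANDS",
    "EEG_MONTAGE_53",
    "EMG_CHANNELS",
    "TASKS",
    "ConfigError",
    "SimulationConfig",
    "Event",
    "Session",
    "simulate_session",
    "make_study",
]


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


#: Canonical oscillation bands (Hz): name -> (f_low, f_high).
FREQ_BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 14.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 80.0),
}

#: 53-channel 10-10 montage subset (frontal through occipital rows).
EEG_MONTAGE_53: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "O1", "Oz", "O2",
)

#: Bipolar sEMG derivations: two forearm, two lower-leg muscles.
EMG_CHANNELS: tuple[str, ...] = (
    "hand_extensor", "hand_flexor", "tibialis_anterior", "soleus",
)

#: Task ids 1..4: two hand tasks (dynamic, static) and two foot tasks.
TASKS: tuple[int, ...] = (1, 2, 3, 4)


def _idx(label: str) -> int:
    return EEG_MONTAGE_53.index(label)


# Hand tasks couple through left-hemisphere hand motor/somatosensory sites,
# foot tasks through midline sites (foot area lies at the vertex).
_DEFAULT_COUPLED: dict[int, tuple[int, ...]] = {
    1: (_idx("C3"), _idx("CP3"), _idx("FC3")),
    2: (_idx("C3"), _idx("C1"), _idx("CP1")),
    3: (_idx("Cz"), _idx("FCz"), _idx("C1")),
    4: (_idx("Cz"), _idx("CPz"), _idx("C2")),
}

# Both same-limb bipolar derivations are engaged by a limb's tasks.
_DEFAULT_TASK_CHANNELS: dict[int, tuple[int, ...]] = {
    1: (0, 1), 2: (0, 1), 3: (2, 3), 4: (2, 3),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters.

    Defaults reproduce the structure of the emulated experiment: 15 subjects,
    4 tasks x 20 trials, 1200 Hz sampling, 53 EEG + 4 sEMG channels, 10 s
    rest + 5 s contraction per trial, alpha/beta/gamma drives with a 15 ms
    conduction delay.
    """

    n_subjects: int = 15
    n_trials_per_task: int = 20
    fs: float = 1200.0
    n_eeg: int = 53
    n_emg: int = 4
    rest_s: float = 10.0
    contraction_s: float = 5.0
    bands: tuple[tuple[str, float, float], ...] = tuple(
        (name, lo, hi) for name, (lo, hi) in FREQ_BANDS.items()
    )
    #: per-band transmission gain (dimensionless, amplitude scale).  The
    #: default, together with ``injection_sd``, places the study in the
    #: weak-coupling regime typical of corticomuscular data: grand-average
    #: coherence modestly above its confidence limit, single-trial
    #: coherence mostly below it.
    coupling_gain: Mapping[str, float] = field(
        default_factory=lambda: {"alpha": 0.3, "beta": 0.3, "gamma": 0.3}
    )
    delay_ms: float = 15.0
    noise_sd: float = 1.0
    background_sd: float = 1.0
    #: amplitude of a cortical drive in its EEG channel, relative to the
    #: unit background -- rhythms are a sub-unity fraction of scalp EEG.
    injection_sd: float = 0.2
    carrier_sd: float = 1.0
    mod_depth: float = 0.5
    transmission: str = "modulated"  # or "linear"
    coupled_eeg_channels: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_COUPLED)
    )
    task_channel_map: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_TASK_CHANNELS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_task < 1:
            raise ConfigError("n_subjects and n_trials_per_task must be >= 1")
        if self.n_eeg < 1 or self.n_emg < 1:
            raise ConfigError("channel counts must be >= 1")
        if self.rest_s < 0 or self.contraction_s <= 0:
            raise ConfigError("rest_s must be >= 0 and contraction_s > 0")
        highest = max(hi for _, _, hi in self.bands)
        if self.fs <= 2.0 * highest:
            raise ConfigError(
                f"fs = {self.fs} must exceed twice the highest band edge "
                f"({highest} Hz)"
            )
        for name, lo, hi in self.bands:
            if not (0.0 < lo < hi):
                raise ConfigError(f"invalid band edges for {name}: ({lo}, {hi})")
        if self.transmission not in ("modulated", "linear"):
            raise ConfigError(f"unknown transmission mode {self.transmission!r}")
        if self.delay_ms < 0:
            raise ConfigError("delay_ms must be >= 0")
        if any(g < 0 for g in self.coupling_gain.values()):
            raise ConfigError("coupling_gain values must be >= 0")
        for task, chans in self.coupled_eeg_channels.items():
            if any(not (0 <= c < self.n_eeg) for c in chans):
                raise ConfigError(f"coupled EEG index out of range for task {task}")
        for task, chans in self.task_channel_map.items():
            if any(not (0 <= c < self.n_emg) for c in chans):
                raise ConfigError(f"task sEMG index out of range for task {task}")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @property
    def trial_s(self) -> float:
        return self.rest_s + self.contraction_s

    @property
    def band_map(self) -> dict[str, tuple[float, float]]:
        return {name: (lo, hi) for name, lo, hi in self.bands}


@dataclass(frozen=True)
class Event:
    sample: int
    trial: int
    task: int
    phase: str  # "rest" | "contraction"


@dataclass
class Session:
    """One continuous synchronous EEG+sEMG recording (one subject, one task)."""

    eeg: np.ndarray  # (n_samples, n_eeg)
    emg: np.ndarray  # (n_samples, n_emg)
    fs: float
    events: list[Event]
    subject_id: int
    task_id: int
    ground_truth: tuple[bool, ...]  # per sEMG channel: is_task_related
    eeg_labels: tuple[str, ...] = EEG_MONTAGE_53
    emg_labels: tuple[str, ...] = EMG_CHANNELS

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != self.emg.shape[0]:
            raise ValueError("eeg and emg must have identical sample counts")
        samples = [e.sample for e in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.eeg.shape[0]):
            raise ValueError("event sample index outside the recording")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[0]


def _band_sos(f_low: float, f_high: float, fs: float, order: int = 4):
    return signal.butter(order, [f_low, f_high], btype="bandpass", fs=fs,
                         output="sos")


def _bandlimited_noise(rng: np.random.Generator, n: int, f_low: float,
                       f_high: float, fs: float) -> np.ndarray:
    """Unit-variance zero-phase band-pass filtered Gaussian white noise."""
    x = signal.sosfiltfilt(_band_sos(f_low, f_high, fs),
                           rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """1/f-amplitude noise along axis 0, unit variance per column."""
    n = shape[0]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=0)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale.reshape((-1,) + (1,) * (len(shape) - 1))
    x = np.fft.irfft(spec, n=n, axis=0)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _delayed(x: np.ndarray, d: int) -> np.ndarray:
    """x shifted right by d samples, zero-padded at the start."""
    if d == 0:
        return x
    out = np.zeros_like(x)
    out[d:] = x[:-d]
    return out


def _session_rng(config: SimulationConfig, subject_id: int,
                 task_id: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF,
                                 1 + int(subject_id), 101 + int(task_id)])
    return np.random.default_rng(ss)


def simulate_session(config: SimulationConfig, subject_id: int,
                     task_id: int) -> Session:
    """Simulate one subject x task recording.

    Bit-identical for identical ``(config, subject_id, task_id)``.
    """
    config.validate()
    rng = _session_rng(config, subject_id, task_id)
    fs = config.fs
    n_trial = int(round(config.trial_s * fs))
    n_rest = int(round(config.rest_s * fs))
    n_total = n_trial * config.n_trials_per_task
    delay = int(round(config.delay_ms * 1e-3 * fs))

    # contraction-window indicator and trigger events
    mask = np.zeros(n_total)
    events: list[Event] = []
    for tr in range(config.n_trials_per_task):
        t0 = tr * n_trial
        events.append(Event(t0, tr, task_id, "rest"))
        events.append(Event(t0 + n_rest, tr, task_id, "contraction"))
        mask[t0 + n_rest: t0 + n_trial] = 1.0

    # EEG background: per-channel pink noise + shared low-rank pink sources
    n_sources = 4
    eeg = config.background_sd * _pink_noise(rng, (n_total, config.n_eeg))
    sources = _pink_noise(rng, (n_total, n_sources))
    mixing = 0.4 * rng.standard_normal((n_sources, config.n_eeg))
    eeg += config.background_sd * (sources @ mixing)

    # Band-limited cortical drives: one independent drive per coupled EEG
    # channel, bands assigned cyclically (alpha, beta, gamma, alpha, ...).
    coupled = tuple(config.coupled_eeg_channels.get(task_id, ()))
    band_names = [name for name, _, _ in config.bands]
    drive_sum = np.zeros(n_total)  # delayed, gain-weighted sum seen by muscles
    for k, ch in enumerate(coupled):
        name = band_names[k % len(band_names)]
        lo, hi = config.band_map[name]
        s = _bandlimited_noise(rng, n_total, lo, hi, fs)
        eeg[:, ch] += config.injection_sd * s * mask
        gain = float(config.coupling_gain.get(name, 0.0))
        drive_sum += gain * _delayed(s, delay)
    drive_sum *= mask

    task_channels = set(config.task_channel_map.get(task_id, ()))
    emg = np.zeros((n_total, config.n_emg))
    drive_sd = drive_sum[mask > 0].std() if mask.any() else 0.0
    mod = drive_sum / drive_sd if drive_sd > 0 else np.zeros(n_total)

    task_sds = []
    for c in range(config.n_emg):
        if c in task_channels:
            y = drive_sum.copy()
            if config.transmission == "modulated":
                carrier = config.carrier_sd * _bandlimited_noise(
                    rng, n_total, 5.0, min(200.0, 0.45 * fs), fs)
                y = y + carrier * (1.0 + config.mod_depth * mod)
            y = y + config.noise_sd * rng.standard_normal(n_total)
            emg[:, c] = y
            task_sds.append(y[mask > 0].std())
    target_sd = float(np.mean(task_sds)) if task_sds else 1.0

    for c in range(config.n_emg):
        if c not in task_channels:
            if config.transmission == "modulated":
                y = config.carrier_sd * _bandlimited_noise(
                    rng, n_total, 5.0, min(200.0, 0.45 * fs), fs)
                y = y + config.noise_sd * rng.standard_normal(n_total)
            else:
                y = config.noise_sd * rng.standard_normal(n_total)
            sd = y[mask > 0].std()
            if sd > 0:
                y *= target_sd / sd
            emg[:, c] = y

    ground_truth = tuple(c in task_channels for c in range(config.n_emg))
    return Session(eeg=eeg, emg=emg, fs=fs, events=events,
                   subject_id=subject_id, task_id=task_id,
                   ground_truth=ground_truth,
                   eeg_labels=tuple(EEG_MONTAGE_53[: config.n_eeg])
                   if config.n_eeg <= 53 else
                   tuple(f"EEG{i}" for i in range(config.n_eeg)))


def make_study(config: SimulationConfig,
               tasks: Sequence[int] = TASKS) -> tuple[list[Session], pd.DataFrame]:
    """Simulate all subjects x tasks and build the ground-truth label table.

    Returns the session list and a table with one row per
    (subject, task, trial, sEMG channel) carrying ``is_task_related``.
    """
    config.validate()
    sessions: list[Session] = []
    rows = []
    for subject in range(config.n_subjects):
        for task in tasks:
            sess = simulate_session(config, subject, task)
            sessions.append(sess)
            for trial in range(config.n_trials_per_task):
                for c in range(config.n_emg):
                    rows.append((subject, task, trial, c,
                                 int(sess.ground_truth[c])))
    labels = pd.DataFrame(
        rows, columns=["subject", "task", "trial", "emg_channel",
                       "is_task_related"])
    return sessions, labels
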
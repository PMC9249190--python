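"""Cortico-muscular coherence (CMC) coupling features.

For an EEG channel x and an sEMG channel y, auto- and cross-spectra are
averaged over L windowed segments,

    Pxx(f) = (1/L) sum_i X_i(f) X_i*(f)        (and likewise Pyy),
    Pxy(f) = (1/L) sum_i X_i(f) Y_i*(f),

and the magnitude-squared coherence is

    Cxy(f) = |Pxy(f)|^2 / (Pxx(f) Pyy(f))  in [0, 1].

Under independence, segment-averaged coherence exceeds the analytic
confidence limit

    CL = 1 - (1 - alpha)^(1/(N-1))

with probability 1 - alpha per frequency bin (N = number of segments,
alpha = 0.95 by default).  The per-EEG-channel CMC feature ("mean
significant coherence") averages the positive excess over the in-band bins:

    M_sCoh = (1/n_bins) sum_{f in [f_min, f_max)} max(Cxy(f) - CL, 0).

Segmentation uses 0.75 s non-overlapping Hann windows, so a 3 s trial
contributes 4 segments and a 20-trial task pools N = 80 segments for the
grand-average profile; single-trial features recompute CL at N = 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .preprocess import TrialEpoch

__all__ = [
    "SpectraSet",
    "CoherenceProfile",
    "CouplingVector",
    "BANDS",
    "segment",
    "spectra",
    "coherence",
    "confidence_limit",
    "ms_coh",
    "band_coupling",
    "pooled_profile",
]

#: Analysis bands (Hz).  "total" is the intersection of the EEG (2-100 Hz)
#: and sEMG (5-200 Hz) passbands.
BANDS: dict[str, tuple[float, float]] = {
    "total": (5.0, 100.0),
    "alpha": (8.0, 14.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 80.0),
}

DEFAULT_SEG_LEN_S = 0.75


@dataclass
class SpectraSet:
    freqs: np.ndarray
    Pxx: np.ndarray  # real, >= 0
    Pyy: np.ndarray
    Pxy: np.ndarray  # complex
    L: int


@dataclass
class CoherenceProfile:
    """Coherence of every EEG channel with one sEMG channel."""

    freqs: np.ndarray
    Cxy: np.ndarray  # (n_eeg, n_freqs), in [0, 1]
    CL: float
    n_segments: int
    emg_channel: int = -1


@dataclass
class CouplingVector:
    """Length-n_eeg coupling values for one (trial, sEMG channel, band)."""

    values: np.ndarray
    method: str  # "msCoh" | "CD"
    band: str
    subject_id: int
    task_id: int
    trial_id: int
    emg_channel: int
    label: bool  # is_task_related

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("coupling values must be finite")
        self.values = v


def segment(x: np.ndarray, nperseg: int, noverlap: int = 0) -> np.ndarray:
    """Full segments of ``x`` along axis 0 -> (n_segments, nperseg, ...)."""
    x = np.asarray(x)
    step = nperseg - noverlap
    if step <= 0:
        raise ValueError("overlap must be smaller than the segment length")
    n_seg = 1 + (x.shape[0] - nperseg) // step if x.shape[0] >= nperseg else 0
    if n_seg < 1:
        raise ValueError(
            f"signal of length {x.shape[0]} is shorter than one segment "
            f"({nperseg} samples)")
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    return x[idx]


def _window(name: str | None, nperseg: int) -> np.ndarray:
    if name is None or name == "boxcar":
        return np.ones(nperseg)
    return _sig.get_window(name, nperseg, fftbins=True)


def spectra(x: np.ndarray, y: np.ndarray, fs: float,
            seg_len_s: float = DEFAULT_SEG_LEN_S, window: str = "hann",
            overlap: float = 0.0) -> SpectraSet:
    """Segment-averaged auto- and cross-spectra of two equal-length signals.

    ``overlap`` is a fraction of the segment length in [0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    nperseg = int(round(seg_len_s * fs))
    if nperseg < 8:
        raise ValueError("segment length must cover at least 8 samples")
    noverlap = int(round(overlap * nperseg))
    w = _window(window, nperseg)
    X = np.fft.rfft(segment(x, nperseg, noverlap) * w, axis=-1)
    Y = np.fft.rfft(segment(y, nperseg, noverlap) * w, axis=-1)
    L = X.shape[0]
    return SpectraSet(
        freqs=np.fft.rfftfreq(nperseg, d=1.0 / fs),
        Pxx=np.mean(np.abs(X) ** 2, axis=0),
        Pyy=np.mean(np.abs(Y) ** 2, axis=0),
        Pxy=np.mean(X * np.conj(Y), axis=0),
        L=L)


def coherence(s: SpectraSet) -> np.ndarray:
    """Magnitude-squared coherence; bins with zero power are set to 0."""
    denom = s.Pxx * s.Pyy
    out = np.zeros_like(np.real(denom))
    ok = denom > 0
    out[ok] = (np.abs(s.Pxy[ok]) ** 2) / denom[ok]
    # guard tiny numerical overshoot of the Cauchy-Schwarz bound
    return np.clip(out, 0.0, 1.0)


def confidence_limit(n_segments: int, alpha: float = 0.95) -> float:
    """Analytic significance threshold CL = 1 - (1-alpha)^(1/(N-1))."""
    if n_segments < 2:
        raise ValueError("confidence limit requires at least 2 segments")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return 1.0 - (1.0 - alpha) ** (1.0 / (n_segments - 1))


def _band_mask(freqs: np.ndarray, f_min: float, f_max: float) -> np.ndarray:
    mask = (freqs >= f_min) & (freqs < f_max)  # half-open [f_min, f_max)
    if not mask.any():
        raise ValueError(f"no frequency bins in band [{f_min}, {f_max}) Hz")
    return mask


def ms_coh(profile: CoherenceProfile, f_min: float, f_max: float) -> np.ndarray:
    """Mean significant coherence per EEG channel over [f_min, f_max).

    Averages the clamped excess max(Cxy - CL, 0) over the in-band bins
    (normalizer = bin count).
    """
    mask = _band_mask(profile.freqs, f_min, f_max)
    excess = np.clip(profile.Cxy[:, mask] - profile.CL, 0.0, None)
    return excess.sum(axis=1) / mask.sum()


def _epoch_spectra(epoch: TrialEpoch, seg_len_s: float, window: str,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Segment-averaged spectra of all EEG x sEMG pairs of one epoch.

    Returns (freqs, Cxy (n_emg, n_eeg, n_freq) numerators parts) via full
    spectra; implemented vectorized with one rfft per channel set.
    """
    nperseg = int(round(seg_len_s * epoch.fs))
    w = _window(window, nperseg)
    segs_e = segment(epoch.eeg, nperseg) * w[None, :, None]
    segs_m = segment(epoch.emg, nperseg) * w[None, :, None]
    X = np.fft.rfft(segs_e, axis=1)  # (L, n_freq, n_eeg)
    Y = np.fft.rfft(segs_m, axis=1)  # (L, n_freq, n_emg)
    L = X.shape[0]
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / epoch.fs)
    return freqs, X, Y, L


def _profiles_from_fts(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Cxy (n_emg, n_eeg, n_freq) from per-segment Fourier transforms."""
    Pxx = np.mean(np.abs(X) ** 2, axis=0)  # (n_freq, n_eeg)
    Pyy = np.mean(np.abs(Y) ** 2, axis=0)  # (n_freq, n_emg)
    # Pxy[f, e, m] = mean_l X[l, f, e] * conj(Y[l, f, m])
    Pxy = np.einsum("lfe,lfm->fem", X, np.conj(Y)) / X.shape[0]
    denom = Pxx[:, :, None] * Pyy[:, None, :]
    C = np.zeros(denom.shape)
    ok = denom > 0
    C[ok] = (np.abs(Pxy[ok]) ** 2) / denom[ok]
    return np.clip(np.transpose(C, (2, 1, 0)), 0.0, 1.0)


def band_coupling(epochs: Sequence[TrialEpoch], band: str = "total",
                  seg_len_s: float = DEFAULT_SEG_LEN_S, window: str = "hann",
                  alpha: float = 0.95,
                  bands: dict[str, tuple[float, float]] | None = None,
                  ) -> list[CouplingVector]:
    """Single-trial M_sCoh coupling vectors for every (trial, sEMG channel).

    Each trial uses its own segments (L = 4 for 3 s trials at 0.75 s
    segments) with CL recomputed at that segment count.
    """
    band_map = BANDS if bands is None else bands
    if band not in band_map:
        raise ValueError(f"unknown band {band!r}")
    f_min, f_max = band_map[band]
    out: list[CouplingVector] = []
    for ep in epochs:
        freqs, X, Y, L = _epoch_spectra(ep, seg_len_s, window)
        if f_max > freqs[-1]:
            raise ValueError(
                f"band edge {f_max} Hz outside spectral grid "
                f"(max {freqs[-1]} Hz)")
        C = _profiles_from_fts(X, Y)  # (n_emg, n_eeg, n_freq)
        cl = confidence_limit(L, alpha)
        for m in range(ep.emg.shape[1]):
            prof = CoherenceProfile(freqs=freqs, Cxy=C[m], CL=cl,
                                    n_segments=L, emg_channel=m)
            out.append(CouplingVector(
                values=ms_coh(prof, f_min, f_max), method="msCoh", band=band,
                subject_id=ep.subject_id, task_id=ep.task_id,
                trial_id=ep.trial_id, emg_channel=m, label=ep.labels[m]))
    return out


def pooled_profile(epochs: Sequence[TrialEpoch], emg_channel: int,
                   seg_len_s: float = DEFAULT_SEG_LEN_S, window: str = "hann",
                   alpha: float = 0.95) -> CoherenceProfile:
    """Grand-average coherence profile pooling all trials' segments.

    With 20 trials of 3 s at 0.75 s segments, N = 80 segments enter the
    average and CL is evaluated at N = 80.
    """
    Xs, Ys = [], []
    freqs = None
    for ep in epochs:
        f, X, Y, _ = _epoch_spectra(ep, seg_len_s, window)
        if freqs is None:
            freqs = f
        elif not np.array_equal(freqs, f):
            raise ValueError("epochs have inconsistent spectral grids")
        Xs.append(X)
        Ys.append(Y[:, :, emg_channel])
    X = np.concatenate(Xs, axis=0)
    Y = np.concatenate(Ys, axis=0)[:, :, None]
    C = _profiles_from_fts(X, Y)  # (1, n_eeg, n_freq)
    N = X.shape[0]
    return CoherenceProfile(freqs=freqs, Cxy=C[0], CL=confidence_limit(N, alpha),
                            n_segments=N, emg_channel=emg_channel)
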
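"""Spectra, coherence, confidence limit and the M_sCoh reduction.

The naive-DFT oracle recomputes segment-averaged coherence from explicit
discrete Fourier sums, independent of the FFT-based implementation path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortimuscle.coherence import (BANDS, CoherenceProfile, band_coupling,
                                   coherence, confidence_limit, ms_coh,
                                   pooled_profile, spectra)


def naive_coherence(x, y, fs, seg_len_s, window="hann"):
    """Direct O(n^2) DFT implementation of segment-averaged coherence."""
    from scipy.signal import get_window
    nper = int(round(seg_len_s * fs))
    L = len(x) // nper
    w = get_window(window, nper, fftbins=True)
    nfreq = nper // 2 + 1
    k = np.arange(nfreq)
    n = np.arange(nper)
    dft = np.exp(-2j * np.pi * np.outer(k, n) / nper)  # explicit DFT matrix
    Pxx = np.zeros(nfreq)
    Pyy = np.zeros(nfreq)
    Pxy = np.zeros(nfreq, dtype=complex)
    for i in range(L):
        X = dft @ (w * x[i * nper:(i + 1) * nper])
        Y = dft @ (w * y[i * nper:(i + 1) * nper])
        Pxx += np.abs(X) ** 2
        Pyy += np.abs(Y) ** 2
        Pxy += X * np.conj(Y)
    C = np.zeros(nfreq)
    ok = (Pxx > 0) & (Pyy > 0)
    C[ok] = np.abs(Pxy[ok]) ** 2 / (Pxx[ok] * Pyy[ok])
    return C


class TestSpectra:
    def test_identity_pair(self, rng):
        x = rng.standard_normal(4800)
        s = spectra(x, x, fs=1200.0)
        assert np.allclose(s.Pxx, s.Pyy)
        assert np.allclose(s.Pxy.imag, 0.0, atol=1e-9)
        assert np.allclose(s.Pxy.real, s.Pxx)

    def test_segment_count_80_on_60s(self, rng):
        # 60 s at 0.75 s non-overlapping segments -> L = 80
        fs = 1200.0
        x = rng.standard_normal(int(60 * fs))
        y = rng.standard_normal(int(60 * fs))
        s = spectra(x, y, fs=fs, seg_len_s=0.75, overlap=0.0)
        assert s.L == 80

    def test_tone_concentrates_at_its_bin(self):
        fs, f0 = 1200.0, 40.0
        t = np.arange(int(6 * fs)) / fs
        x = np.cos(2 * np.pi * f0 * t)
        s = spectra(x, x, fs=fs, seg_len_s=0.75)
        peak = s.freqs[np.argmax(s.Pxx)]
        assert peak == pytest.approx(f0, abs=fs / (0.75 * fs))
        # energy outside the peak's neighbourhood is negligible
        far = np.abs(s.freqs - f0) > 4.0
        assert s.Pxx[far].max() < 1e-6 * s.Pxx.max()

    def test_cauchy_schwarz_holds(self, rng):
        x = rng.standard_normal(2400)
        y = 0.3 * x + rng.standard_normal(2400)
        s = spectra(x, y, fs=1200.0)
        assert np.all(np.abs(s.Pxy) ** 2 <= s.Pxx * s.Pyy * (1 + 1e-12))

    def test_too_short_signal_is_error(self):
        with pytest.raises(ValueError):
            spectra(np.zeros(100), np.zeros(100), fs=1200.0, seg_len_s=0.75)


class TestCoherence:
    def test_linear_dependence_gives_unity(self, rng):
        x = rng.standard_normal(3600)
        C = coherence(spectra(x, 3.0 * x, fs=1200.0))
        s = spectra(x, 3.0 * x, fs=1200.0)
        powered = (s.Pxx * s.Pyy) > 0
        assert np.allclose(C[powered], 1.0)

    def test_single_segment_is_identically_one(self, rng):
        x = rng.standard_normal(900)
        y = rng.standard_normal(900)
        s = spectra(x, y, fs=1200.0, seg_len_s=0.75)
        assert s.L == 1
        C = coherence(s)
        ok = (s.Pxx * s.Pyy) > 0
        assert np.allclose(C[ok], 1.0)

    def test_independent_noise_mean_near_1_over_L(self, rng):
        # E[Cxy] ~ 1/L for independent signals
        fs = 1200.0
        x = rng.standard_normal(int(60 * fs))
        y = rng.standard_normal(int(60 * fs))
        s = spectra(x, y, fs=fs, seg_len_s=0.75)
        C = coherence(s)
        assert C.mean() == pytest.approx(1.0 / 80.0, rel=0.25)

    def test_matches_naive_dft_oracle(self, rng):
        fs = 48.0
        for _ in range(10):
            x = rng.standard_normal(int(5 * fs))
            y = 0.5 * x + rng.standard_normal(int(5 * fs))
            C = coherence(spectra(x, y, fs=fs, seg_len_s=0.75))
            C0 = naive_coherence(x, y, fs=fs, seg_len_s=0.75)
            assert np.max(np.abs(C - C0)) < 1e-10

    def test_matches_scipy_welch_coherence(self, rng):
        """Cross-check against scipy with matching segmentation options."""
        from scipy import signal as sig
        fs = 1200.0
        x = rng.standard_normal(int(12 * fs))
        y = 0.4 * x + rng.standard_normal(int(12 * fs))
        nper = int(0.75 * fs)
        f, C0 = sig.coherence(x, y, fs=fs, window="hann", nperseg=nper,
                              noverlap=0, detrend=False)
        C = coherence(spectra(x, y, fs=fs, seg_len_s=0.75))
        assert np.allclose(C, C0, atol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0),
           st.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, ax, ay):
        r = np.random.default_rng(seed)
        x = r.standard_normal(1800)
        y = 0.5 * x + r.standard_normal(1800)
        base = coherence(spectra(x, y, fs=1200.0))
        scaled = coherence(spectra(ax * x, ay * y, fs=1200.0))
        assert np.allclose(base, scaled, atol=1e-9)
        assert np.all(base >= 0.0) and np.all(base <= 1.0)


class TestConfidenceLimit:
    def test_two_segments_equals_alpha(self):
        assert confidence_limit(2, 0.95) == pytest.approx(0.95)

    def test_eighty_segments_value(self):
        # CL = 1 - (1 - 0.95)^(1/79)
        assert confidence_limit(80, 0.95) == pytest.approx(0.0372, abs=5e-5)

    def test_strictly_decreasing_in_n(self):
        values = [confidence_limit(n) for n in (2, 4, 10, 40, 80, 200)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            confidence_limit(1)
        with pytest.raises(ValueError):
            confidence_limit(10, alpha=1.0)


class TestMsCoh:
    def _profile(self, Cxy, freqs=None, CL=0.2):
        Cxy = np.atleast_2d(Cxy)
        if freqs is None:
            freqs = np.arange(Cxy.shape[1], dtype=float)
        return CoherenceProfile(freqs=freqs, Cxy=Cxy, CL=CL, n_segments=4)

    def test_at_threshold_gives_zero(self):
        prof = self._profile(np.full((2, 30), 0.2))
        assert np.allclose(ms_coh(prof, 0, 30), 0.0)

    def test_hand_computed_example(self):
        # two bins above CL by 0.10 and 0.20 in a 30-bin band
        # -> (0.10 + 0.20) / 30 = 0.01 under bin-count normalization
        C = np.full((1, 30), 0.05)
        C[0, 3] = 0.30
        C[0, 17] = 0.40
        prof = self._profile(C, CL=0.2)
        assert ms_coh(prof, 0, 30)[0] == pytest.approx(0.01)

    def test_all_below_cl_clamps_to_zero(self, rng):
        prof = self._profile(rng.uniform(0, 0.19, size=(5, 30)))
        assert np.all(ms_coh(prof, 0, 30) == 0.0)

    def test_empty_band_is_error(self):
        prof = self._profile(np.full((1, 30), 0.5))
        with pytest.raises(ValueError):
            ms_coh(prof, 40, 50)


class TestBandCoupling:
    def test_vector_shape_ids_and_nonnegativity(self, tiny_epochs):
        vecs = band_coupling(tiny_epochs, band="beta")
        assert len(vecs) == len(tiny_epochs) * 4
        v = vecs[0]
        assert v.values.shape == (53,)
        assert np.all(v.values >= 0.0)
        assert v.method == "msCoh" and v.band == "beta"

    def test_unknown_band_rejected(self, tiny_epochs):
        with pytest.raises(ValueError):
            band_coupling(tiny_epochs, band="delta")

    def test_pooled_profile_segment_count(self, tiny_epochs):
        prof = pooled_profile(tiny_epochs, emg_channel=0)
        # 2 trials x 4 segments of 0.75 s per 3 s trial
        assert prof.n_segments == 8
        assert prof.CL == pytest.approx(confidence_limit(8))

    def test_coupled_pair_beats_uncoupled_in_band(self):
        """Beta-coupled EEG channel shows higher beta M_sCoh than the rest."""
        from cortimuscle.preprocess import preprocess_session
        from cortimuscle.simulate import SimulationConfig, simulate_session

        gains = {"alpha": 0.0, "beta": 2.0, "gamma": 0.0}
        cfg = SimulationConfig(n_subjects=1, n_trials_per_task=20, fs=400.0,
                               rest_s=0.5, contraction_s=5.0,
                               coupling_gain=gains, injection_sd=1.0, seed=2)
        epochs = preprocess_session(simulate_session(cfg, 0, 1),
                                    emg_band=(5.0, 150.0))
        prof = pooled_profile(epochs, emg_channel=0)
        vals = ms_coh(prof, *BANDS["beta"])
        beta_ch = cfg.coupled_eeg_channels[1][1]
        others = np.delete(vals, list(cfg.coupled_eeg_channels[1]))
        assert vals[beta_ch] > others.max()
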
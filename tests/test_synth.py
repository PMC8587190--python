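"""Synthetic speech, the noise bank, SNR mixing and corpus construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sig
from scipy.stats import kurtosis

import eanr
from eanr.errors import DegenerateInputError, InvalidArgumentError
from eanr.synth import NOISE_RMS, NoiseSpec, ssn_design_response


class TestSpeechGenerator:
    def test_length_and_amplitude(self):
        w = eanr.gen_speech_like(1.0, seed=7)
        assert w.samples.size == 16_000
        assert np.max(np.abs(w.samples)) <= 1.0

    def test_deterministic_and_seed_sensitive(self):
        a = eanr.gen_speech_like(1.0, seed=7)
        b = eanr.gen_speech_like(1.0, seed=7)
        c = eanr.gen_speech_like(1.0, seed=8)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_syllabic_modulation_present(self, speech):
        # envelope spectrum should carry energy in the 2-6 Hz syllable band
        env = np.abs(sig.hilbert(speech.samples))
        env = env - env.mean()
        f, p = sig.welch(env, fs=speech.rate, nperseg=1 << 14)
        band = p[(f >= 2) & (f <= 6)].sum()
        total = p[(f > 0) & (f <= 50)].sum()
        assert band / total > 0.2

    def test_invalid_duration(self):
        with pytest.raises(InvalidArgumentError):
            eanr.gen_speech_like(0.0, seed=1)


class TestNoiseBank:
    def test_deterministic(self, bank):
        a = eanr.gen_noise(bank[0], 0.5, seed=3)
        b = eanr.gen_noise(bank[0], 0.5, seed=3)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("class_id", range(12))
    def test_rms_within_tolerance(self, bank, class_id):
        w = eanr.gen_noise(bank[class_id], 2.0, seed=11)
        assert abs(w.rms() - NOISE_RMS) / NOISE_RMS < 0.2

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidArgumentError):
            eanr.gen_noise(NoiseSpec(0, "bad", "warbler", {}), 1.0, seed=1)

    def test_impulsive_is_heavy_tailed(self, bank):
        burst = eanr.gen_noise(bank[2], 1.0, seed=1)
        white = np.random.default_rng(0).standard_normal(16_000)
        assert kurtosis(burst.samples) > kurtosis(white) + 1.0

    def test_speech_shaped_matches_design_curve(self, bank):
        w = eanr.gen_noise(bank[8], 4.0, seed=1)
        f, p = sig.welch(w.samples, fs=w.rate, nperseg=512)
        sel = (f >= 100) & (f <= 7000)
        measured = 10 * np.log10(p[sel])
        designed = ssn_design_response(f[sel])
        offset = np.mean(measured - designed)
        assert np.max(np.abs(measured - designed - offset)) < 3.0

    def test_tonal_sweep_tracks_rising_ridge(self, bank):
        w = eanr.gen_noise(bank[9], 2.0, seed=1)  # siren, 600-1500 Hz
        frames = eanr.stft_analyze(w)
        freqs = np.fft.rfftfreq(512, 1 / 16_000)
        peaks = freqs[np.argmax(frames.lps, axis=1)]
        assert peaks.min() < 750 and peaks.max() > 1300
        assert np.all((peaks > 450) & (peaks < 1800))

    def test_classes_spectrally_distinct(self, bank):
        """Mean log-spectra of different classes correlate below 0.95."""
        spectra = [
            eanr.stft_analyze(eanr.gen_noise(s, 2.0, seed=1)).lps.mean(axis=0)
            for s in bank
        ]
        for i in range(len(spectra)):
            for j in range(i + 1, len(spectra)):
                corr = np.corrcoef(spectra[i], spectra[j])[0, 1]
                assert corr < 0.95, (i, j, corr)

    def test_nearest_centroid_classifier_over_90pct(self, bank):
        """A trivial centroid rule on mean log-spectra separates the bank."""
        centroids = {
            s.class_id: np.mean(
                [eanr.stft_analyze(eanr.gen_noise(s, 1.0, sd)).lps.mean(axis=0)
                 for sd in range(100, 106)], axis=0)
            for s in bank
        }
        hits = total = 0
        for s in bank:
            for sd in range(900, 903):
                v = eanr.stft_analyze(eanr.gen_noise(s, 1.0, sd)).lps.mean(axis=0)
                pred = min(centroids, key=lambda c: np.linalg.norm(v - centroids[c]))
                hits += pred == s.class_id
                total += 1
        assert hits / total > 0.9


class TestSnrMixing:
    def test_equal_power_zero_db_gain(self):
        clean = eanr.Waveform(np.ones(1000))
        noise = eanr.Waveform(np.tile([1.0, -1.0], 500))
        mixed = eanr.mix_at_snr(clean, noise, 0.0)
        g = (mixed.samples - clean.samples) / noise.samples
        assert np.allclose(g, 1.0)

    def test_ten_db_closed_form_gain(self):
        clean = eanr.Waveform(np.ones(1000))
        noise = eanr.Waveform(np.tile([1.0, -1.0], 500))
        mixed = eanr.mix_at_snr(clean, noise, 10.0)
        g = (mixed.samples - clean.samples) / noise.samples
        assert np.allclose(g, 10 ** -0.5)
        assert abs(g[0] - 0.31623) < 1e-5

    @settings(deadline=None, max_examples=25)
    @given(snr=st.floats(-10, 10), seed=st.integers(0, 1000))
    def test_achieved_snr_exact(self, snr, seed, bank):
        clean = eanr.gen_speech_like(0.5, seed=seed)
        noise = eanr.gen_noise(bank[seed % 12], 0.5, seed=seed + 1)
        mixed = eanr.mix_at_snr(clean, noise, snr)
        assert abs(eanr.measure_snr(clean, mixed) - snr) < 1e-6

    def test_rate_mismatch_rejected(self, speech):
        noise = eanr.Waveform(np.ones(speech.samples.size), rate=8000)
        with pytest.raises(InvalidArgumentError):
            eanr.mix_at_snr(speech, noise, 0.0)

    def test_short_noise_rejected(self, speech):
        noise = eanr.Waveform(np.ones(10))
        with pytest.raises(InvalidArgumentError):
            eanr.mix_at_snr(speech, noise, 0.0)

    def test_zero_power_rejected(self, speech):
        silent = eanr.Waveform(np.zeros(speech.samples.size))
        with pytest.raises(DegenerateInputError):
            eanr.mix_at_snr(speech, silent, 0.0)


class TestCorpus:
    def test_grid_count(self):
        cfg = eanr.CorpusCfg(tuple(range(12)), (-6.0, -3.0, 0.0, 3.0, 6.0),
                             n_train=4, n_test=2, utterance_s=0.5)
        manifest = eanr.build_corpus(cfg)
        assert len(manifest.entries) == 12 * 5 * 6
        keys = {(e.class_id, e.snr_db, e.split, e.utterance_id) for e in manifest.entries}
        assert len(keys) == len(manifest.entries)

    def test_manifest_deterministic(self):
        cfg = eanr.CorpusCfg((0, 1), (0.0,), 2, 1, 0.5, master_seed=9)
        assert eanr.build_corpus(cfg) == eanr.build_corpus(cfg)

    def test_resolved_audio_bit_reproducible(self):
        cfg = eanr.CorpusCfg((0,), (0.0,), 1, 0, 0.5, master_seed=9)
        man = eanr.build_corpus(cfg)
        c1, n1 = eanr.resolve_entry(man, man.entries[0])
        c2, n2 = eanr.resolve_entry(man, man.entries[0])
        assert np.array_equal(c1.samples, c2.samples)
        assert np.array_equal(n1.samples, n2.samples)

    def test_resolved_snr_matches_request(self):
        cfg = eanr.CorpusCfg((3, 9), (-6.0, 3.0), 1, 1, 0.5, master_seed=2)
        man = eanr.build_corpus(cfg)
        for entry in man.entries:
            clean, noisy = eanr.resolve_entry(man, entry)
            assert abs(eanr.measure_snr(clean, noisy) - entry.snr_db) < 1e-6

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            eanr.build_corpus(eanr.CorpusCfg((), (0.0,), 1, 1))
        with pytest.raises(InvalidArgumentError):
            eanr.build_corpus(eanr.CorpusCfg((0,), (0.0,), 0, 0))


class TestWavIO:
    @pytest.mark.parametrize("subtype,tol", [("float32", 1e-6), ("pcm16", 1e-4)])
    def test_roundtrip(self, tmp_path, speech, subtype, tol):
        path = tmp_path / f"x_{subtype}.wav"
        eanr.write_wav(path, speech, subtype=subtype)
        back = eanr.read_wav(path)
        assert back.rate == speech.rate
        assert np.max(np.abs(back.samples - speech.samples)) < tol
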
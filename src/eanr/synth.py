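"""Synthetic speech, a 12-class noise bank, and SNR-controlled mixing.

Real hearing-in-noise corpora (Mandarin HINT sentences, recorded environmental
noises) cannot be redistributed, so this module generates stand-ins with the
acoustic properties the rest of the pipeline actually depends on: harmonic
speech-like utterances with formant structure and syllabic amplitude
modulation, and a bank of spectrally distinct noise classes (babble-like,
impulsive, tonal sweeps, speech-shaped, hum, broadband, and mixtures).
Everything is a pure function of (config, seed), so corpora are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import signal
from scipy.io import wavfile

from .errors import DegenerateInputError, InvalidArgumentError

DEFAULT_RATE = 16_000
#: RMS level clean speech is normalized to before mixing; keeps peak
#: amplitude below 1 even at -10 dB SNR.
SPEECH_RMS = 0.05
#: Long-run RMS target for generated noise (re-scaled during mixing anyway).
NOISE_RMS = 0.05


@dataclass(frozen=True)
class Waveform:
    """Mono audio: a float sample sequence plus its sample rate in Hz."""

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise InvalidArgumentError(f"rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size < 1:
            raise InvalidArgumentError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise InvalidArgumentError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def power(self) -> float:
        return float(np.mean(self.samples**2))

    def rms(self) -> float:
        return float(np.sqrt(self.power()))


def read_wav(path) -> Waveform:
    """Read a mono RIFF WAV (PCM16 or float32) into a [-1, 1] float Waveform."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise InvalidArgumentError("only mono WAV files are supported")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    return Waveform(data, rate)


def write_wav(path, wave: Waveform, subtype: str = "float32") -> None:
    """Write a mono WAV as float32 (default) or 16-bit PCM."""
    if subtype == "float32":
        wavfile.write(path, wave.rate, wave.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(wave.samples, -1.0, 1.0)
        wavfile.write(path, wave.rate, (clipped * 32767).astype(np.int16))
    else:
        raise InvalidArgumentError(f"unknown subtype {subtype!r}")


# ---------------------------------------------------------------------------
# Speech-like generator
# ---------------------------------------------------------------------------

#: (F1, F2, F3) formant targets in Hz for a small vowel inventory.
_VOWELS = (
    (730.0, 1090.0, 2440.0),
    (270.0, 2290.0, 3010.0),
    (300.0, 870.0, 2240.0),
    (530.0, 1840.0, 2480.0),
    (570.0, 840.0, 2410.0),
)


@dataclass(frozen=True)
class SpeechCfg:
    """Settings for the speech-like generator.

    f0 wanders inside [f0_min, f0_max]; syllables arrive at a rate drawn from
    syllable_rate (Hz), each a voiced burst with a raised-cosine envelope, so
    the signal has the 2-6 Hz amplitude modulation characteristic of speech.
    """

    rate: int = DEFAULT_RATE
    f0_min: float = 100.0
    f0_max: float = 250.0
    syllable_rate: tuple[float, float] = (2.5, 5.5)
    voiced_fraction: float = 0.75
    n_harmonics: int = 28
    aspiration_db: float = -24.0
    peak: float = 0.95


def _resonator_sos(freq: float, bandwidth: float, rate: int) -> np.ndarray:
    """Second-order resonator section with poles at freq +- j bandwidth."""
    r = np.exp(-np.pi * bandwidth / rate)
    theta = 2 * np.pi * freq / rate
    # unit gain at the resonance peak is not needed; energy is normalized later
    return np.array([[1.0 - r, 0.0, 0.0, 1.0, -2 * r * np.cos(theta), r * r]])


def _formant_filter(x: np.ndarray, formants, rate: int) -> np.ndarray:
    y = x
    for i, f in enumerate(formants):
        bw = 60.0 + 0.08 * f
        y = signal.sosfilt(_resonator_sos(f, bw, rate), y)
    return y


def gen_speech_like(
    duration_s: float, seed: int, cfg: SpeechCfg | None = None
) -> Waveform:
    """Generate a harmonic, formant-shaped, syllabically modulated signal.

    Deterministic in (duration_s, seed, cfg). Peak amplitude <= cfg.peak.
    """
    cfg = cfg or SpeechCfg()
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    rng = default_rng(seed)
    n = int(round(duration_s * cfg.rate))
    t = np.arange(n) / cfg.rate

    # syllable grid
    syl_rate = rng.uniform(*cfg.syllable_rate)
    syl_len = int(round(cfg.rate / syl_rate))
    n_syl = max(1, int(np.ceil(n / syl_len)))

    # piecewise-linear f0 contour between per-syllable targets
    targets = rng.uniform(cfg.f0_min, cfg.f0_max, size=n_syl + 1)
    knots = np.arange(n_syl + 1) * syl_len
    f0 = np.interp(np.arange(n), knots, targets)

    phase = 2 * np.pi * np.cumsum(f0) / cfg.rate
    harm_phases = rng.uniform(0, 2 * np.pi, size=cfg.n_harmonics)
    source = np.zeros(n)
    for h in range(1, cfg.n_harmonics + 1):
        source += (1.0 / h) * np.sin(h * phase + harm_phases[h - 1])

    # aspiration noise, later shaped by the same formants
    noise = rng.standard_normal(n) * 10 ** (cfg.aspiration_db / 20)

    # per-syllable vowel color and raised-cosine envelope
    out = np.zeros(n)
    envelope = np.zeros(n)
    for s in range(n_syl):
        a, b = s * syl_len, min((s + 1) * syl_len, n)
        if a >= n:
            break
        seg = source[a:b] + noise[a:b]
        vowel = _VOWELS[rng.integers(len(_VOWELS))]
        seg = _formant_filter(seg, vowel, cfg.rate)
        m = b - a
        # clamp: a trailing syllable can be as short as one sample
        voiced = min(m, max(2, int(m * cfg.voiced_fraction)))
        env = np.zeros(m)
        env[:voiced] = 0.5 * (1 - np.cos(2 * np.pi * np.arange(voiced) / voiced))
        out[a:b] = seg * env
        envelope[a:b] = env

    peak = np.max(np.abs(out))
    if peak > 0:
        out *= cfg.peak / peak
    return Waveform(out, cfg.rate)


# ---------------------------------------------------------------------------
# Noise bank
# ---------------------------------------------------------------------------

GeneratorKind = str  # {tonal_sweep, impulsive, babble_like, speech_shaped,
#                       narrowband_hum, broadband, mixture}


@dataclass(frozen=True)
class NoiseSpec:
    """One noise class: an id, a label, a generator kind, and its settings."""

    class_id: int
    name: str
    generator_kind: GeneratorKind
    params: dict = field(default_factory=dict)


def _tilt(x: np.ndarray, rate: int, db_per_oct: float, f_ref: float = 1000.0) -> np.ndarray:
    """Apply a constant dB/octave spectral tilt via an FFT-domain multiply."""
    if db_per_oct == 0:
        return x
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / rate)
    f = np.maximum(f, 40.0)
    gain = (f / f_ref) ** (db_per_oct / (20 * np.log10(2.0)))
    return np.fft.irfft(spec * gain, n=x.size)


def _shape(x: np.ndarray, rate: int, freqs, gains_db) -> np.ndarray:
    """Impose a piecewise-linear log-magnitude envelope via FFT multiply."""
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / rate)
    gain = 10 ** (np.interp(f, freqs, gains_db) / 20.0)
    return np.fft.irfft(spec * gain, n=x.size)


def _gen_babble(rng: Generator, n: int, rate: int, p: dict) -> np.ndarray:
    """Overlapping speech-like voices; continuous (high voiced fraction)."""
    voices = p.get("voices", [(100.0, 150.0), (180.0, 250.0)])
    out = np.zeros(n)
    for lo, hi in voices:
        cfg = SpeechCfg(
            rate=rate,
            f0_min=lo,
            f0_max=hi,
            voiced_fraction=p.get("voiced_fraction", 0.95),
            syllable_rate=(3.0, 6.0),
        )
        w = gen_speech_like(n / rate, int(rng.integers(2**31)), cfg)
        out += w.samples[:n]
    out = _tilt(out, rate, p.get("tilt_db_per_oct", 0.0))
    if "shape" in p:
        out = _shape(out, rate, *p["shape"])
    return out


def _gen_impulsive(rng: Generator, n: int, rate: int, p: dict) -> np.ndarray:
    """Repetitive decaying broadband bursts (e.g. jackhammer strikes)."""
    rep = p.get("rep_hz", 9.0)
    decay = p.get("decay_s", 0.02)
    band = p.get("band", (200.0, 6000.0))
    period = int(rate / rep)
    out = np.zeros(n)
    k = np.arange(int(3 * decay * rate))
    for start in range(0, n, period):
        jitter = int(rng.integers(-period // 8, period // 8 + 1))
        s = max(0, start + jitter)
        burst = rng.standard_normal(k.size) * np.exp(-k / (decay * rate))
        e = min(n, s + burst.size)
        if s < e:
            out[s:e] += burst[: e - s]
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    return signal.sosfilt(sos, out)


def _gen_tonal_sweep(rng: Generator, n: int, rate: int, p: dict) -> np.ndarray:
    """Periodic frequency sweep with harmonics (siren-like)."""
    f_lo = p.get("f_lo", 600.0)
    f_hi = p.get("f_hi", 1500.0)
    period_s = p.get("period_s", 1.5)
    t = np.arange(n) / rate
    tri = signal.sawtooth(2 * np.pi * t / period_s + rng.uniform(0, 2 * np.pi), 0.5)
    f = f_lo + (f_hi - f_lo) * (tri + 1) / 2
    phase = 2 * np.pi * np.cumsum(f) / rate
    out = np.sin(phase) + 0.3 * np.sin(2 * phase) + 0.1 * np.sin(3 * phase)
    return out


# Design curve for speech-shaped noise: a long-term-average-speech-spectrum
# style response, flat through the low formant region then rolling off.
SSN_DESIGN_FREQS = np.array([0.0, 100.0, 200.0, 500.0, 1000.0, 2000.0, 4000.0, 7000.0, 8000.0])
SSN_DESIGN_GAINS_DB = np.array([-30.0, 0.0, 2.0, 3.0, -3.0, -9.0, -15.0, -21.0, -30.0])


def ssn_design_response(freqs_hz: np.ndarray) -> np.ndarray:
    """The speech-shaped filter's design magnitude response in dB."""
    return np.interp(freqs_hz, SSN_DESIGN_FREQS, SSN_DESIGN_GAINS_DB)


def _gen_speech_shaped(rng: Generator, n: int, rate: int, p: dict) -> np.ndarray:
    gains = 10 ** (SSN_DESIGN_GAINS_DB / 20)
    taps = signal.firwin2(1025, SSN_DESIGN_FREQS, gains, fs=rate)
    white = rng.standard_normal(n + taps.size)
    return signal.lfilter(taps, 1.0, white)[taps.size : taps.size + n]


def _gen_hum(rng: Generator, n: int, rate: int, p: dict) -> np.ndarray:
    """Harmonic mains-style hum plus a weak low-frequency noise floor."""
    f0 = p.get("f0", 120.0)
    n_h = p.get("n_harmonics", 6)
    t = np.arange(n) / rate
    out = np.zeros(n)
    for h in range(1, n_h + 1):
        out += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
    sos = signal.butter(2, p.get("floor_cutoff", 300.0), btype="lowpass", fs=rate, output="sos")
    out += p.get("floor_level", 0.15) * signal.sosfilt(sos, rng.standard_normal(n))
    return out


def _gen_broadband(rng: Generator, n: int, rate: int, p: dict) -> np.ndarray:
    """Filtered broadband noise (fan / rumble style)."""
    sos = signal.butter(
        p.get("order", 2), p.get("cutoff", 1200.0), btype="lowpass", fs=rate, output="sos"
    )
    out = signal.sosfilt(sos, rng.standard_normal(n))
    return _tilt(out, rate, p.get("tilt_db_per_oct", 0.0))


def _gen_squeak(rng: Generator, n: int, rate: int, p: dict) -> np.ndarray:
    """Intermittent high-frequency chirps (squeaky-toy style)."""
    f_lo, f_hi = p.get("f_lo", 1800.0), p.get("f_hi", 3600.0)
    out = np.zeros(n)
    pos = 0
    while pos < n:
        gap = int(rng.uniform(0.05, 0.25) * rate)
        dur = int(rng.uniform(0.08, 0.2) * rate)
        s = pos + gap
        e = min(n, s + dur)
        if s >= n:
            break
        tt = np.arange(e - s) / rate
        f = rng.uniform(f_lo, f_hi)
        sweep = f * (1 + 0.3 * np.sin(2 * np.pi * 8.0 * tt))
        phase = 2 * np.pi * np.cumsum(sweep) / rate
        env = np.sin(np.pi * np.arange(e - s) / (e - s)) ** 2
        out[s:e] = env * (np.sin(phase) + 0.4 * np.sin(2 * phase))
        pos = e
    return out


_KIND_DISPATCH: dict[str, Callable] = {
    "babble_like": _gen_babble,
    "impulsive": _gen_impulsive,
    "tonal_sweep": _gen_tonal_sweep,
    "speech_shaped": _gen_speech_shaped,
    "narrowband_hum": _gen_hum,
    "broadband": _gen_broadband,
    "squeak": _gen_squeak,
}


def gen_noise(spec: NoiseSpec, duration_s: float, seed: int) -> Waveform:
    """Generate one noise realization; deterministic in (spec, duration, seed).

    The output is normalized to the RMS target in spec.params (default
    NOISE_RMS), so the long-run level is controlled by construction.
    """
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    rate = spec.params.get("rate", DEFAULT_RATE)
    n = int(round(duration_s * rate))
    rng = default_rng(SeedSequence([seed, spec.class_id]))
    if spec.generator_kind == "mixture":
        parts = spec.params["components"]
        out = np.zeros(n)
        for weight, sub in parts:
            sub_spec = NoiseSpec(spec.class_id, f"{spec.name}:{sub['kind']}", sub["kind"], sub.get("params", {}))
            fn = _KIND_DISPATCH.get(sub["kind"])
            if fn is None:
                raise InvalidArgumentError(f"unknown generator_kind {sub['kind']!r}")
            comp = fn(rng, n, rate, sub.get("params", {}))
            comp_rms = np.sqrt(np.mean(comp**2))
            if comp_rms > 0:
                comp = comp / comp_rms
            out += weight * comp
    else:
        fn = _KIND_DISPATCH.get(spec.generator_kind)
        if fn is None:
            raise InvalidArgumentError(
                f"unknown generator_kind {spec.generator_kind!r}"
            )
        out = fn(rng, n, rate, spec.params)
    rms = np.sqrt(np.mean(out**2))
    if rms <= 0:
        raise DegenerateInputError("generated noise has zero power")
    target = spec.params.get("rms", NOISE_RMS)
    out = out * (target / rms)
    # recording floor: real noise captures have a broadband mic/ADC floor,
    # not a digital-silence one
    floor_db = spec.params.get("floor_db", -50.0)
    out = out + target * 10 ** (floor_db / 20) * rng.standard_normal(n)
    return Waveform(out, rate)


def default_noise_bank() -> list[NoiseSpec]:
    """Twelve spectrally distinct noise classes.

    The classes emulate the qualitative categories of common environmental
    noises used in hearing-in-noise testing: several babble variants,
    an impulsive jackhammer, transit rumble, a fan, a squeaky toy,
    speech-shaped noise, a siren, and two composite scenes. Distinctness of
    mean log-spectra across classes is a designed property of the bank.
    """
    return [
        NoiseSpec(0, "babble_bright_pair", "babble_like",
                  {"voices": [(200.0, 260.0), (130.0, 170.0)],
                   "shape": ([0.0, 300.0, 800.0, 2000.0, 3000.0, 5000.0, 8000.0],
                             [-36.0, -24.0, -10.0, 0.0, 6.0, 6.0, -6.0])}),
        NoiseSpec(1, "babble_low_pair", "babble_like",
                  {"voices": [(170.0, 210.0), (100.0, 130.0)],
                   "shape": ([0.0, 200.0, 500.0, 1000.0, 2500.0, 8000.0],
                             [0.0, 2.0, 0.0, -10.0, -28.0, -40.0])}),
        NoiseSpec(2, "jackhammer", "impulsive",
                  {"rep_hz": 9.0, "decay_s": 0.02, "band": (200.0, 6000.0)}),
        NoiseSpec(3, "two_talker", "babble_like",
                  {"voices": [(110.0, 150.0), (115.0, 155.0)],
                   "voiced_fraction": 0.85,
                   "shape": ([0.0, 200.0, 500.0, 800.0, 1500.0, 3000.0, 8000.0],
                             [-30.0, -18.0, -2.0, 4.0, 2.0, -16.0, -32.0])}),
        NoiseSpec(4, "cafeteria", "mixture",
                  {"components": [
                      (0.5, {"kind": "babble_like",
                             "params": {"voices": [(100.0, 250.0)] * 4,
                                        "voiced_fraction": 0.95}}),
                      (0.3, {"kind": "impulsive",
                             "params": {"rep_hz": 2.0, "decay_s": 0.008,
                                        "band": (2500.0, 7500.0)}}),
                      (0.2, {"kind": "broadband",
                             "params": {"cutoff": 7000.0, "order": 1}}),
                  ]}),
        NoiseSpec(5, "metro", "mixture",
                  {"components": [
                      (0.85, {"kind": "broadband",
                              "params": {"cutoff": 350.0, "order": 6}}),
                      (0.15, {"kind": "tonal_sweep",
                              "params": {"f_lo": 2500.0, "f_hi": 3200.0,
                                         "period_s": 3.0}}),
                  ]}),
        NoiseSpec(6, "house_fan", "broadband",
                  {"cutoff": 1500.0, "order": 2, "tilt_db_per_oct": 1.5}),
        NoiseSpec(7, "toy_squeak", "squeak",
                  {"f_lo": 1800.0, "f_hi": 3600.0}),
        NoiseSpec(8, "speech_shaped", "speech_shaped", {}),
        NoiseSpec(9, "siren", "tonal_sweep",
                  {"f_lo": 600.0, "f_hi": 1500.0, "period_s": 1.5}),
        NoiseSpec(10, "siren_crowd", "mixture",
                   {"components": [
                       (0.7, {"kind": "tonal_sweep",
                              "params": {"f_lo": 1200.0, "f_hi": 2600.0,
                                         "period_s": 0.8}}),
                       (0.3, {"kind": "broadband",
                              "params": {"cutoff": 7500.0, "order": 1}}),
                   ]}),
        NoiseSpec(11, "scratch_boo", "mixture",
                   {"components": [
                       (0.7, {"kind": "impulsive",
                               "params": {"rep_hz": 4.0, "decay_s": 0.005,
                                          "band": (4000.0, 7800.0)}}),
                       (0.3, {"kind": "narrowband_hum",
                               "params": {"f0": 220.0, "n_harmonics": 4,
                                          "floor_level": 0.2}}),
                   ]}),
    ]


# ---------------------------------------------------------------------------
# SNR mixing
# ---------------------------------------------------------------------------


def mix_at_snr(clean: Waveform, noise: Waveform, snr_db: float) -> Waveform:
    """Add noise to clean speech at an exact SNR.

    The noise is truncated to the clean length and scaled by
    g = sqrt(P_clean / (P_noise * 10^(snr_db/10))), so the achieved
    10*log10(P_clean / P_scaled_noise) equals snr_db to numerical precision.
    """
    if clean.rate != noise.rate:
        raise InvalidArgumentError(
            f"rate mismatch: clean {clean.rate} Hz vs noise {noise.rate} Hz"
        )
    if noise.samples.size < clean.samples.size:
        raise InvalidArgumentError("noise must be at least as long as clean")
    c = clean.samples
    v = noise.samples[: c.size]
    p_clean = np.mean(c**2)
    p_noise = np.mean(v**2)
    if p_clean <= 0 or p_noise <= 0:
        raise DegenerateInputError("zero-power clean or noise signal")
    g = np.sqrt(p_clean / (p_noise * 10 ** (snr_db / 10)))
    return Waveform(c + g * v, clean.rate)


def measure_snr(clean: Waveform, noisy: Waveform) -> float:
    """SNR in dB of an additive mixture, recovered as 10*log10(Pc / P(noisy-clean))."""
    resid = noisy.samples - clean.samples
    p_r = np.mean(resid**2)
    if p_r <= 0:
        raise DegenerateInputError("mixture contains no noise")
    return float(10 * np.log10(np.mean(clean.samples**2) / p_r))


# ---------------------------------------------------------------------------
# Corpus construction
# ---------------------------------------------------------------------------

#: SNR grids used for model training and outside testing.
TRAIN_SNRS_DB = (-10.0, -7.0, -4.0, -1.0, 1.0, 4.0, 7.0, 10.0)
TEST_SNRS_DB = (-6.0, -3.0, 0.0, 3.0, 6.0)


@dataclass(frozen=True)
class CorpusCfg:
    """Grid settings for a synthetic noisy-speech corpus."""

    class_ids: tuple[int, ...]
    snrs_db: tuple[float, ...]
    n_train: int
    n_test: int
    utterance_s: float = 1.0
    master_seed: int = 0
    bank: tuple[NoiseSpec, ...] = field(default_factory=lambda: tuple(default_noise_bank()))


@dataclass(frozen=True)
class CorpusEntry:
    utterance_id: str
    class_id: int
    snr_db: float
    split: str
    seed: int
    duration_s: float


@dataclass(frozen=True)
class CorpusManifest:
    cfg: CorpusCfg
    entries: tuple[CorpusEntry, ...]

    def subset(self, split: str | None = None, class_id: int | None = None,
               snr_db: float | None = None) -> tuple[CorpusEntry, ...]:
        out = self.entries
        if split is not None:
            out = tuple(e for e in out if e.split == split)
        if class_id is not None:
            out = tuple(e for e in out if e.class_id == class_id)
        if snr_db is not None:
            out = tuple(e for e in out if e.snr_db == snr_db)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "cfg": {
                    "class_ids": list(self.cfg.class_ids),
                    "snrs_db": list(self.cfg.snrs_db),
                    "n_train": self.cfg.n_train,
                    "n_test": self.cfg.n_test,
                    "utterance_s": self.cfg.utterance_s,
                    "master_seed": self.cfg.master_seed,
                },
                "entries": [asdict(e) for e in self.entries],
            },
            indent=1,
        )


def _entry_seed(master: int, class_id: int, snr_db: float, split: str, idx: int) -> int:
    ss = SeedSequence([master, class_id, int(round(snr_db * 1000)) & 0x7FFFFFFF,
                       0 if split == "train" else 1, idx])
    return int(ss.generate_state(1)[0])


def build_corpus(cfg: CorpusCfg) -> CorpusManifest:
    """Enumerate the full (class x SNR x split) grid with per-entry seeds."""
    if not cfg.class_ids or not cfg.snrs_db or (cfg.n_train + cfg.n_test) < 1:
        raise InvalidArgumentError("corpus grid is empty")
    known = {s.class_id for s in cfg.bank}
    missing = set(cfg.class_ids) - known
    if missing:
        raise InvalidArgumentError(f"class_ids not in bank: {sorted(missing)}")
    entries = []
    for cid in cfg.class_ids:
        for snr in cfg.snrs_db:
            for split, count in (("train", cfg.n_train), ("test", cfg.n_test)):
                for i in range(count):
                    seed = _entry_seed(cfg.master_seed, cid, snr, split, i)
                    uid = f"c{cid:02d}_snr{snr:+05.1f}_{split}{i:03d}"
                    entries.append(
                        CorpusEntry(uid, cid, snr, split, seed, cfg.utterance_s)
                    )
    return CorpusManifest(cfg, tuple(entries))


def resolve_entry(manifest: CorpusManifest, entry: CorpusEntry) -> tuple[Waveform, Waveform]:
    """Materialize one manifest entry as a (clean, noisy) waveform pair.

    The clean utterance is RMS-normalized to SPEECH_RMS before mixing;
    resolving the same entry twice yields bit-identical audio.
    """
    spec = next(s for s in manifest.cfg.bank if s.class_id == entry.class_id)
    rng = default_rng(SeedSequence([entry.seed, 0xC0FFEE]))
    speech_seed = int(rng.integers(2**31))
    noise_seed = int(rng.integers(2**31))
    clean = gen_speech_like(entry.duration_s, speech_seed)
    scaled = clean.samples * (SPEECH_RMS / clean.rms())
    clean = Waveform(scaled, clean.rate)
    noise = gen_noise(spec, entry.duration_s, noise_seed)
    noisy = mix_at_snr(clean, noise, entry.snr_db)
    return clean, noisy
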
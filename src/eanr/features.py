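"""STFT analysis/synthesis, log-power-spectrum (LPS) and MFCC features.

The denoiser operates on LPS frames (natural log of |STFT|^2) and
reconstructs audio from enhanced magnitudes combined with the unmodified
noisy phase; the classifier operates on MFCCs computed from the same STFT
frames, so both models always see aligned frame grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct
from scipy.signal import ShortTimeFFT, get_window

from .errors import InvalidArgumentError
from .synth import Waveform


@dataclass(frozen=True)
class StftConfig:
    """Framing settings: 32 ms Hann frames at 50% overlap, 16 kHz default."""

    frame_len: int = 512
    hop: int = 256
    fft_size: int = 512
    window: str = "hann"
    log_floor: float = 1e-12
    rate: int = 16_000
    n_mels: int = 26
    n_mfcc: int = 13

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_len <= self.fft_size):
            raise InvalidArgumentError("need 0 < hop <= frame_len <= fft_size")
        if self.log_floor <= 0:
            raise InvalidArgumentError("log_floor must be positive")

    @property
    def n_bins(self) -> int:
        return self.fft_size // 2 + 1

    def _sft(self) -> ShortTimeFFT:
        win = get_window(self.window, self.frame_len, fftbins=True)
        return ShortTimeFFT(win, hop=self.hop, fs=self.rate,
                            mfft=self.fft_size, fft_mode="onesided")


@dataclass(frozen=True)
class SpectralFrames:
    """Paired LPS and phase matrices (frames x bins) from one STFT pass."""

    lps: np.ndarray
    phase: np.ndarray
    cfg: StftConfig
    n_samples_original: int

    def __post_init__(self) -> None:
        if self.lps.shape != self.phase.shape:
            raise InvalidArgumentError("lps and phase shapes differ")
        if self.lps.shape[1] != self.cfg.n_bins:
            raise InvalidArgumentError(
                f"expected {self.cfg.n_bins} bins, got {self.lps.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.lps.shape[0]


@dataclass(frozen=True)
class MfccMatrix:
    coeffs: np.ndarray
    cfg: StftConfig

    @property
    def n_frames(self) -> int:
        return self.coeffs.shape[0]


def stft_analyze(wave: Waveform, cfg: StftConfig | None = None) -> SpectralFrames:
    """STFT a waveform into floored LPS plus phase.

    lps[j, k] = log(max(|STFT[j, k]|^2, log_floor)); the floor is the only
    -inf protection in the pipeline, so no NaN/Inf ever leaves this module.
    """
    cfg = cfg or StftConfig(rate=wave.rate)
    if wave.rate != cfg.rate:
        raise InvalidArgumentError(f"waveform rate {wave.rate} != cfg rate {cfg.rate}")
    if wave.samples.size < cfg.frame_len:
        raise InvalidArgumentError("signal shorter than one frame")
    S = cfg._sft().stft(wave.samples)  # (bins, frames)
    power = np.abs(S.T) ** 2
    lps = np.log(np.maximum(power, cfg.log_floor))
    phase = np.angle(S.T)
    return SpectralFrames(lps, phase, cfg, wave.samples.size)


def lps_to_magnitude(lps: np.ndarray) -> np.ndarray:
    """Invert LPS to linear magnitude: exp(lps / 2), elementwise positive."""
    return np.exp(np.asarray(lps, dtype=np.float64) / 2.0)


def stft_synthesize(
    lps: np.ndarray,
    phase: np.ndarray,
    cfg: StftConfig,
    n_samples: int,
) -> Waveform:
    """Inverse STFT of exp(lps/2) * e^{i phase} via weighted overlap-add.

    With unmodified lps/phase this inverts stft_analyze to numerical
    precision (dual-window synthesis); with enhanced lps it reuses the
    noisy phase verbatim.
    """
    lps = np.asarray(lps, dtype=np.float64)
    phase = np.asarray(phase, dtype=np.float64)
    if lps.shape != phase.shape:
        raise InvalidArgumentError("lps and phase shapes differ")
    if lps.shape[1] != cfg.n_bins:
        raise InvalidArgumentError("bin count does not match cfg")
    S = (lps_to_magnitude(lps) * np.exp(1j * phase)).T
    x = cfg._sft().istft(S, k1=n_samples)
    return Waveform(np.asarray(x, dtype=np.float64), cfg.rate)


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(cfg: StftConfig) -> np.ndarray:
    """Triangular mel filterbank, (n_mels x n_bins), spanning 0..rate/2."""
    f_max = cfg.rate / 2.0
    mels = np.linspace(_hz_to_mel(0.0), _hz_to_mel(f_max), cfg.n_mels + 2)
    hz = _mel_to_hz(mels)
    bins = np.fft.rfftfreq(cfg.fft_size, 1.0 / cfg.rate)
    fb = np.zeros((cfg.n_mels, cfg.n_bins))
    for m in range(1, cfg.n_mels + 1):
        lo, mid, hi = hz[m - 1], hz[m], hz[m + 1]
        up = (bins - lo) / max(mid - lo, 1e-9)
        down = (hi - bins) / max(hi - mid, 1e-9)
        fb[m - 1] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mfcc_extract(wave: Waveform, cfg: StftConfig | None = None) -> MfccMatrix:
    """MFCCs via the standard mel-filterbank -> log -> DCT-II chain.

    Computed from the same STFT pass as stft_analyze, so the frame grid is
    identical by construction. Coefficient 0 carries overall log energy.
    """
    cfg = cfg or StftConfig(rate=wave.rate)
    frames = stft_analyze(wave, cfg)
    power = np.exp(frames.lps)  # floored power spectra
    fb = mel_filterbank(cfg)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, cfg.log_floor))
    coeffs = dct(log_mel, type=2, axis=1, norm="ortho")[:, : cfg.n_mfcc]
    return MfccMatrix(coeffs, cfg)


def stack_context(frames: np.ndarray, context: int) -> np.ndarray:
    """Stack each frame with its neighbors into a wider input vector.

    context must be odd; frame j becomes the concatenation of frames
    j-(context//2) .. j+(context//2) (edges replicated), so a denoiser with
    an input layer of width bins*context predicts the center frame.
    """
    frames = np.atleast_2d(frames)
    if context < 1 or context % 2 == 0:
        raise InvalidArgumentError("context must be a positive odd integer")
    if context == 1:
        return frames
    half = context // 2
    padded = np.pad(frames, ((half, half), (0, 0)), mode="edge")
    n = frames.shape[0]
    return np.hstack([padded[i : i + n] for i in range(context)])


# ---------------------------------------------------------------------------
# Feature normalization (z-score per bin, stats stored with each model)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormStats:
    mean: np.ndarray
    std: np.ndarray

    @staticmethod
    def fit(x: np.ndarray) -> "NormStats":
        return NormStats(x.mean(axis=0), np.maximum(x.std(axis=0), 1e-8))

    @staticmethod
    def identity(width: int) -> "NormStats":
        return NormStats(np.zeros(width), np.ones(width))

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * self.std + self.mean
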
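"""Short-time objective intelligibility (STOI), classic variant.

Implements the published correlation-based intelligibility measure: both
signals are resampled to 10 kHz, silent frames (40 dB below the loudest
clean frame) are removed, short-time one-third-octave band envelopes are
extracted (15 bands starting at 150 Hz, 384 ms analysis segments of 30 STFT
frames), the degraded envelopes are normalized and clipped at a -15 dB
signal-to-distortion bound, and the band-wise linear correlation is averaged
over all bands and segments. The score is ~[0, 1]; higher means more
intelligible.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import resample_poly

from .errors import InvalidArgumentError

FS = 10_000          # internal sample rate
N_FRAME = 256        # analysis frame (25.6 ms)
NFFT = 512
HOP = 128
NUM_BANDS = 15
MIN_FREQ = 150.0     # center frequency of the lowest one-third-octave band
N_SEG = 30           # frames per analysis segment (384 ms)
BETA = -15.0         # lower signal-to-distortion bound, dB
DYN_RANGE = 40.0     # silent-frame threshold below the loudest frame, dB


def _third_octave_matrix() -> np.ndarray:
    """(NUM_BANDS x NFFT/2+1) membership matrix of one-third-octave bands."""
    f = np.linspace(0, FS / 2, NFFT // 2 + 1)
    obm = np.zeros((NUM_BANDS, f.size))
    cf = MIN_FREQ * 2.0 ** (np.arange(NUM_BANDS) / 3.0)
    lo = cf * 2.0 ** (-1.0 / 6.0)
    hi = cf * 2.0 ** (1.0 / 6.0)
    for j in range(NUM_BANDS):
        # snap band edges to the nearest FFT bins, each bin in one band only
        i_lo = np.argmin((f - lo[j]) ** 2)
        i_hi = np.argmin((f - hi[j]) ** 2)
        obm[j, i_lo:i_hi] = 1.0
    return obm


_OBM = _third_octave_matrix()
_WIN = np.hanning(N_FRAME + 2)[1:-1]


def _frame(x: np.ndarray) -> np.ndarray:
    n = 1 + (x.size - N_FRAME) // HOP
    idx = np.arange(N_FRAME)[None, :] + HOP * np.arange(n)[:, None]
    return x[idx]


def _remove_silent_frames(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop frames whose clean energy is > DYN_RANGE dB below the maximum,
    then overlap-add the kept frames back into signals."""
    xf = _frame(x) * _WIN
    yf = _frame(y) * _WIN
    energy = 20 * np.log10(np.linalg.norm(xf, axis=1) + 1e-300)
    keep = energy > energy.max() - DYN_RANGE
    xf, yf = xf[keep], yf[keep]
    n_out = (xf.shape[0] - 1) * HOP + N_FRAME
    xs = np.zeros(n_out)
    ys = np.zeros(n_out)
    for i in range(xf.shape[0]):
        xs[i * HOP : i * HOP + N_FRAME] += xf[i]
        ys[i * HOP : i * HOP + N_FRAME] += yf[i]
    return xs, ys


def _band_envelopes(x: np.ndarray) -> np.ndarray:
    """(NUM_BANDS x n_frames) one-third-octave magnitudes from windowed FFTs."""
    frames = _frame(x) * _WIN
    spec = np.fft.rfft(frames, NFFT, axis=1)
    return np.sqrt(_OBM @ (np.abs(spec) ** 2).T)


def stoi(clean: np.ndarray, degraded: np.ndarray, rate: int) -> float:
    """Classic STOI between a clean reference and a degraded/processed signal."""
    clean = np.asarray(clean, dtype=np.float64)
    degraded = np.asarray(degraded, dtype=np.float64)
    if clean.ndim != 1 or degraded.ndim != 1:
        raise InvalidArgumentError("signals must be 1-D")
    n = min(clean.size, degraded.size)
    clean, degraded = clean[:n], degraded[:n]
    if rate != FS:
        clean = resample_poly(clean, FS, rate)
        degraded = resample_poly(degraded, FS, rate)
    if clean.size < N_FRAME + HOP * (N_SEG - 1):
        raise InvalidArgumentError(
            f"signal too short for STOI: need >= {N_FRAME + HOP * (N_SEG - 1)} "
            f"samples at {FS} Hz"
        )
    x, y = _remove_silent_frames(clean, degraded)
    X = _band_envelopes(x)
    Y = _band_envelopes(y)
    m = X.shape[1]
    if m < N_SEG:
        raise InvalidArgumentError("too few active frames for STOI")

    clip_gain = 10 ** (-BETA / 20.0)
    scores = []
    for end in range(N_SEG, m + 1):
        Xs = X[:, end - N_SEG : end]
        Ys = Y[:, end - N_SEG : end]
        alpha = np.linalg.norm(Xs, axis=1, keepdims=True) / (
            np.linalg.norm(Ys, axis=1, keepdims=True) + 1e-300
        )
        Yn = np.minimum(alpha * Ys, Xs * (1 + clip_gain))
        xz = Xs - Xs.mean(axis=1, keepdims=True)
        yz = Yn - Yn.mean(axis=1, keepdims=True)
        num = np.sum(xz * yz, axis=1)
        den = np.linalg.norm(xz, axis=1) * np.linalg.norm(yz, axis=1) + 1e-300
        scores.append(num / den)
    return float(np.mean(scores))
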
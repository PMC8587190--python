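"""Objective scoring (STOI / PESQ), word-correct-rate, and the
clean-vs-noisy layer-separability analysis.

Separability replaces a qualitative 2-D embedding overlap judgment with a
number: the silhouette score between clean-input and noisy-input activations
at each network layer. t-SNE projections remain available for plotting but
never feed the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.random import default_rng
from sklearn.metrics import silhouette_score

from .ddae import ddae_enhance  # noqa: F401  (re-exported convenience)
from .errors import InvalidArgumentError, MissingDependencyError
from .features import NormStats
from .mlp import MlpModel
from .stoi import stoi as _stoi_impl
from .synth import Waveform


@dataclass(frozen=True)
class EvalScores:
    stoi: float
    pesq: float | None
    condition: tuple  # (noise class, snr_db, method label)


def eval_stoi(clean: Waveform, processed: Waveform) -> float:
    """Classic STOI; signals are trimmed to the shorter length."""
    if clean.rate != processed.rate:
        raise InvalidArgumentError("sample-rate mismatch")
    return _stoi_impl(clean.samples, processed.samples, clean.rate)


def eval_pesq(clean: Waveform, processed: Waveform) -> float:
    """ITU P.862 PESQ (MOS-LQO) via the optional `pesq` backend.

    PESQ is a licensed standard; this package never re-implements it. When
    the backend is not installed a MissingDependencyError is raised, and
    batch evaluators report PESQ as NaN instead.
    """
    if clean.rate != processed.rate:
        raise InvalidArgumentError("sample-rate mismatch")
    if clean.rate not in (8000, 16000):
        raise InvalidArgumentError("PESQ supports 8 kHz or 16 kHz input only")
    try:
        from pesq import pesq as _pesq  # type: ignore
    except ImportError as exc:
        raise MissingDependencyError(
            "PESQ scoring requires the optional 'pesq' package"
        ) from exc
    mode = "wb" if clean.rate == 16000 else "nb"
    n = min(clean.samples.size, processed.samples.size)
    return float(_pesq(clean.rate, clean.samples[:n], processed.samples[:n], mode))


def try_eval_pesq(clean: Waveform, processed: Waveform) -> float:
    """eval_pesq, degrading to NaN when the backend is unavailable."""
    try:
        return eval_pesq(clean, processed)
    except MissingDependencyError:
        return float("nan")


def wcr(n_correct: int, n_total: int) -> float:
    """Word correct rate: 100 * n_correct / n_total, in percent."""
    if n_total <= 0 or not 0 <= n_correct <= n_total:
        raise InvalidArgumentError("need 0 <= n_correct <= n_total, n_total > 0")
    return 100.0 * n_correct / n_total


# ---------------------------------------------------------------------------
# Layer separability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeparabilityProfile:
    """Per-layer silhouette between clean-origin and noisy-origin activations."""

    scores: tuple[float, ...]  # index 0 -> layer 1 output, ..., last -> output layer
    method: str = "silhouette_on_activations"
    embedding: np.ndarray | None = None

    @property
    def peak_layer(self) -> int:
        """1-based index of the most separating layer."""
        return int(np.argmax(self.scores)) + 1


def layer_separability(
    model: MlpModel,
    noisy_lps: np.ndarray,
    clean_lps: np.ndarray,
    sample_cap: int = 2000,
    seed: int = 0,
    with_embedding: bool = False,
) -> SeparabilityProfile:
    """Quantify how well each layer separates clean from noisy inputs.

    Clean and noisy LPS frames are normalized with the model's stored stats,
    propagated through the network, and each layer's activations are scored
    with a two-class silhouette (clean vs noisy origin) after seeded
    subsampling to at most sample_cap frames per class. A high score at a
    layer means the network's representation there has pulled the two signal
    populations apart.
    """
    noisy_lps = np.atleast_2d(noisy_lps)
    clean_lps = np.atleast_2d(clean_lps)
    if noisy_lps.size == 0 or clean_lps.size == 0:
        raise InvalidArgumentError("empty input frames")
    stats = model.norm_stats or NormStats.identity(noisy_lps.shape[1])
    rng = default_rng(seed)

    def sub(x: np.ndarray) -> np.ndarray:
        if x.shape[0] <= sample_cap:
            return x
        idx = rng.choice(x.shape[0], size=sample_cap, replace=False)
        return x[idx]

    c = sub(stats.apply(clean_lps))
    n = sub(stats.apply(noisy_lps))
    _, hid_c = model.forward(c, return_hidden=True)
    _, hid_n = model.forward(n, return_hidden=True)
    labels = np.concatenate([np.zeros(c.shape[0]), np.ones(n.shape[0])])
    scores = tuple(
        float(silhouette_score(np.vstack([hc, hn]), labels))
        for hc, hn in zip(hid_c, hid_n)
    )
    embedding = None
    if with_embedding:
        from sklearn.manifold import TSNE

        peak = int(np.argmax(scores))
        stacked = np.vstack([hid_c[peak], hid_n[peak]])
        embedding = TSNE(n_components=2, random_state=seed, init="pca").fit_transform(stacked)
    return SeparabilityProfile(scores, embedding=embedding)


# ---------------------------------------------------------------------------
# Condition tables
# ---------------------------------------------------------------------------


def condition_table(rows: list[EvalScores]):
    """Aggregate per-utterance scores into one row per
    (method, class, SNR) cell with means and counts; no cell is dropped."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "class_id": [r.condition[0] for r in rows],
            "snr_db": [r.condition[1] for r in rows],
            "method": [r.condition[2] for r in rows],
            "stoi": [r.stoi for r in rows],
            "pesq": [r.pesq for r in rows],
        }
    )
    return (
        df.groupby(["method", "class_id", "snr_db"], dropna=False)
        .agg(stoi=("stoi", "mean"), pesq=("pesq", "mean"), n=("stoi", "size"))
        .reset_index()
    )
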
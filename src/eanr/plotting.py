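"""Evaluation plots: per-condition score bars and separability profiles.

matplotlib is imported lazily so the core pipeline has no plotting
dependency; install the `plot` extra to use this module.
"""

from __future__ import annotations

import numpy as np

from .evaluation import SeparabilityProfile


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_condition_scores(table, metric: str, path) -> None:
    """Grouped bars of mean scores per (class, SNR) for each method.

    `table` is the output of evaluation.condition_table.
    """
    plt = _plt()
    pivot = table.pivot_table(index=["class_id", "snr_db"], columns="method",
                              values=metric)
    ax = pivot.plot.bar(figsize=(max(6, 0.5 * len(pivot)), 4))
    ax.set_ylabel(metric.upper())
    ax.set_xlabel("(noise class, SNR dB)")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    _plt().close(ax.figure)


def plot_separability(profile: SeparabilityProfile, path) -> None:
    """Per-layer silhouette profile; the peak layer is highlighted."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    layers = np.arange(1, len(profile.scores) + 1)
    ax.plot(layers, profile.scores, "o-")
    ax.axvline(profile.peak_layer, color="tab:red", ls="--", lw=1,
               label=f"peak: h({profile.peak_layer})")
    ax.set_xticks(layers)
    ax.set_xlabel("layer output h(l)")
    ax.set_ylabel("clean/noisy silhouette")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
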
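"""The noise classifier (NC) and confidence-gated routing.

A feed-forward network with three 100-unit logistic hidden layers and a
softmax output maps per-frame MFCC vectors to posterior probabilities over
the noise classes. An utterance-level decision averages the frame posteriors;
the maximum of the averaged posterior is the confidence. If the confidence
reaches the routing threshold, the matching noise-dependent denoiser is
selected, otherwise the system falls back to the noise-independent one —
the gate that keeps an uncertain classification from mis-routing audio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError
from .features import MfccMatrix, NormStats
from .mlp import MlpModel, TrainCfg, glorot_init, train_mlp

#: Default architecture: 13 MFCCs -> 3 x 100 logistic units -> 12 classes.
DEFAULT_NC_SIZES = (13, 100, 100, 100, 12)
DEFAULT_THRESHOLD = 0.9


@dataclass(frozen=True)
class RoutingDecision:
    """Classifier output for one utterance plus the model it routes to."""

    predicted_class: int
    confidence: float
    chosen_model: str  # "ND" or "NI"
    per_frame_posteriors: np.ndarray

    @property
    def use_nd(self) -> bool:
        return self.chosen_model == "ND"


def nc_init(layer_sizes: Sequence[int] = DEFAULT_NC_SIZES, seed: int = 0) -> MlpModel:
    """Seeded scaled-uniform init, zero biases, logistic/softmax activations."""
    ws, bs = glorot_init(layer_sizes, seed)
    return MlpModel(ws, bs, hidden_activation="logistic",
                    output_activation="softmax",
                    meta={"kind": "nc", "layer_sizes": tuple(layer_sizes), "seed": seed})


def nc_train(
    model: MlpModel,
    feats: Sequence[MfccMatrix] | np.ndarray,
    labels: Sequence[int],
    cfg: TrainCfg | None = None,
) -> tuple[MlpModel, list[float]]:
    """Train by cross-entropy backpropagation on per-frame MFCCs.

    `feats` is either a list of per-utterance MFCC matrices with one label
    each (frames inherit their utterance's class) or an already-stacked frame
    matrix with one label per frame. Input normalization stats are fitted on
    the training frames and stored with the model.
    """
    cfg = cfg or TrainCfg()
    if isinstance(feats, np.ndarray):
        x = feats
        y = np.asarray(labels, dtype=int)
    else:
        if len(feats) != len(labels):
            raise InvalidArgumentError("one label per utterance required")
        x = np.vstack([f.coeffs for f in feats])
        y = np.concatenate(
            [np.full(f.n_frames, lab, dtype=int) for f, lab in zip(feats, labels)]
        )
    if x.shape[0] != y.shape[0]:
        raise InvalidArgumentError("frame/label misalignment")
    if np.unique(y).size < 2:
        raise InvalidArgumentError("training data must contain >= 2 classes")
    n_classes = model.weights[-1].shape[1]
    if y.min() < 0 or y.max() >= n_classes:
        raise InvalidArgumentError("label outside the model's class range")

    out = model.copy()
    if out.norm_stats is None:
        out.norm_stats = NormStats.fit(x)
    xn = out.norm_stats.apply(x)
    onehot = np.zeros((y.size, n_classes))
    onehot[np.arange(y.size), y] = 1.0
    trained, history = train_mlp(out, xn, onehot, cfg, loss="ce")
    return trained, history


def frame_posteriors(model: MlpModel, feats: MfccMatrix) -> np.ndarray:
    """Softmax posteriors for every frame, (n_frames, K)."""
    x = feats.coeffs
    if x.shape[0] < 1:
        raise InvalidArgumentError("empty feature matrix")
    if model.norm_stats is not None:
        x = model.norm_stats.apply(x)
    return model.forward(x)


def classify_utterance(
    model: MlpModel, feats: MfccMatrix, threshold: float = DEFAULT_THRESHOLD
) -> RoutingDecision:
    """Average frame posteriors into one utterance decision.

    predicted_class is the argmax of the mean posterior (ties broken toward
    the lowest class id); confidence is that maximum; the noise-dependent
    model is chosen iff confidence >= threshold.
    """
    post = frame_posteriors(model, feats)
    mean_post = post.mean(axis=0)
    predicted = int(np.argmax(mean_post))  # np.argmax takes lowest index on ties
    confidence = float(mean_post[predicted])
    chosen = "ND" if confidence >= threshold else "NI"
    return RoutingDecision(predicted, confidence, chosen, post)


def utterance_accuracy(
    model: MlpModel, feats: Sequence[MfccMatrix], labels: Sequence[int]
) -> float:
    """Fraction of utterances whose frame-averaged argmax matches the label."""
    if len(feats) != len(labels) or not feats:
        raise InvalidArgumentError("need matching, non-empty feats and labels")
    hits = sum(
        classify_utterance(model, f, threshold=0.0).predicted_class == lab
        for f, lab in zip(feats, labels)
    )
    return hits / len(feats)
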
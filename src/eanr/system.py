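"""End-to-end environment-aware enhancement and parameter accounting.

The full pipeline: STFT the noisy utterance, classify its background from
MFCCs, route to the noise-dependent denoiser (base model with one stored
layer swapped in) when classification confidence clears the threshold or to
the noise-independent one otherwise, enhance the LPS frames, and resynthesize
with the noisy phase.

Parameter accounting backs the system's headline efficiency argument:
deploying C explicit noise-dependent networks costs (C+1) full denoisers,
while the transfer scheme costs one denoiser plus C copies of a single
layer. With L equal-width layers the ratio tends to (L + C) / (L * (C + 1));
for L=5, C=12 that is 17/65 ~= 0.26 — about a quarter of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ddae import TransferStore, apply_transfer, ddae_enhance
from .errors import InvalidArgumentError
from .features import StftConfig, lps_to_magnitude, mfcc_extract, stft_analyze, stft_synthesize
from .mlp import MlpModel, count_parameters
from .nc import DEFAULT_THRESHOLD, RoutingDecision, classify_utterance
from .synth import Waveform


@dataclass
class EanrSystem:
    """A trained classifier, base denoiser, transfer store, and shared config."""

    nc_model: MlpModel
    ni_model: MlpModel
    store: TransferStore
    threshold: float = DEFAULT_THRESHOLD
    stft_cfg: StftConfig = StftConfig()

    def __post_init__(self) -> None:
        n_classes = self.nc_model.weights[-1].shape[1]
        if any(cid >= n_classes or cid < 0 for cid in self.store.class_ids):
            raise InvalidArgumentError("store contains classes the classifier cannot emit")


def enhance_utterance(sys: EanrSystem, noisy: Waveform) -> tuple[Waveform, RoutingDecision]:
    """Denoise one utterance and report the routing decision.

    Output length equals input length; the decision records the predicted
    class, its confidence, and which model processed the audio.
    """
    frames = stft_analyze(noisy, sys.stft_cfg)
    feats = mfcc_extract(noisy, sys.stft_cfg)
    decision = classify_utterance(sys.nc_model, feats, sys.threshold)
    if decision.use_nd and decision.predicted_class in sys.store.entries:
        model = apply_transfer(sys.ni_model, sys.store, decision.predicted_class)
    else:
        model = sys.ni_model
        if decision.use_nd:
            decision = RoutingDecision(
                decision.predicted_class, decision.confidence, "NI",
                decision.per_frame_posteriors,
            )
    enhanced_lps = ddae_enhance(model, frames)
    wave = stft_synthesize(enhanced_lps, frames.phase, sys.stft_cfg,
                           frames.n_samples_original)
    return wave, decision


@dataclass(frozen=True)
class ParamReport:
    """Footprints of the explicit-models scheme vs the transfer scheme."""

    nc_params: int
    ddae_params: int
    layer_params: int
    n_classes: int
    total_full: int
    total_transfer: int

    @property
    def ratio(self) -> float:
        return self.total_transfer / self.total_full

    @property
    def reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.ratio)

    @property
    def incremental_store(self) -> int:
        """Parameters added per deployment beyond the shared base models."""
        return self.n_classes * self.layer_params


def count_system_parameters(sys: EanrSystem, include_nc: bool = True) -> ParamReport:
    """Compare C explicit noise-dependent denoisers against the transfer store.

    full     = nc + (C + 1) * ddae          (C explicit ND models + 1 NI)
    transfer = nc + ddae + C * layer        (shared NI + C substituted layers)

    The classifier is counted identically on both sides (or excluded from
    both with include_nc=False), so the ratio reflects the denoiser savings.
    """
    C = len(sys.store.entries)
    if C == 0:
        raise InvalidArgumentError("transfer store is empty")
    idx = sys.store.substituted_index - 1
    layer_params = int(sys.ni_model.weights[idx].size + sys.ni_model.biases[idx].size)
    nc_params = count_parameters(sys.nc_model) if include_nc else 0
    ddae_params = count_parameters(sys.ni_model)
    total_full = nc_params + (C + 1) * ddae_params
    total_transfer = nc_params + ddae_params + C * layer_params
    return ParamReport(nc_params, ddae_params, layer_params, C, total_full, total_transfer)


def equal_width_ratio_limit(n_layers: int, n_classes: int) -> float:
    """Large-width limit of the transfer/full parameter ratio with equal
    layer sizes (bias terms negligible): (L + C) / (L * (C + 1))."""
    return (n_layers + n_classes) / (n_layers * (n_classes + 1))
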
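"""Denoising autoencoder (DDAE) and single-layer knowledge transfer.

The noise-independent (NI) DDAE is a 5-weight-layer ReLU network regressing
noisy LPS frames onto clean LPS frames (mean squared error). A
noise-dependent (ND) variant is derived from it by retraining exactly one
weight layer on data from a single noise environment while every other
parameter stays frozen; the collection of per-class substituted layers (a
TransferStore) is the entire incremental footprint of environment
adaptation. Counting weight layers 1..L from the input, the substituted
layer is L - r; with the defaults r=3 and L=5 that is layer 2, the layer at
which clean and noisy representations separate most strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, StaleStoreError
from .features import NormStats, SpectralFrames
from .mlp import MlpModel, TrainCfg, he_init, train_mlp

#: Default LPS-to-LPS architecture (257 bins, 4 hidden ReLU layers, L=5).
#: 256-unit hidden layers make one denoiser ~0.33M parameters, so a
#: 13-model deployment (12 noise-dependent + 1 noise-independent) sits at
#: ~4.3M — the scale the transfer scheme is designed to collapse.
DEFAULT_DDAE_DIMS = (257, 256, 256, 256, 256, 257)
#: Output-relative indexing: substituted weight layer = L - r; r=3, L=5 -> 2.
DEFAULT_R = 3


def substituted_layer_index(n_layers: int, r: int = DEFAULT_R) -> int:
    """Map the trainable-layer offset r onto a 1-based weight-layer index."""
    idx = n_layers - r
    if not 1 <= idx <= n_layers:
        raise InvalidArgumentError(f"r={r} puts the substituted layer outside 1..{n_layers}")
    return idx


def ddae_init(layer_dims: Sequence[int] = DEFAULT_DDAE_DIMS, seed: int = 0) -> MlpModel:
    """He-initialized ReLU regression network with a linear output layer."""
    if layer_dims[0] != layer_dims[-1]:
        raise InvalidArgumentError("input and output widths must match (LPS in, LPS out)")
    if len(layer_dims) < 4:
        raise InvalidArgumentError("need at least 3 weight layers")
    ws, bs = he_init(layer_dims, seed)
    return MlpModel(ws, bs, hidden_activation="relu", output_activation="linear",
                    meta={"kind": "ddae", "layer_dims": tuple(layer_dims), "seed": seed})


def ddae_train(
    model: MlpModel,
    noisy_lps: np.ndarray,
    clean_lps: np.ndarray,
    cfg: TrainCfg,
) -> tuple[MlpModel, list[float]]:
    """Fit noisy->clean LPS regression over the trainable layers only.

    Normalization stats are fitted on the noisy training frames on first
    training and reused afterwards (fine-tuning inherits the base model's
    statistics). Frozen layers are bit-identical before and after.
    """
    noisy_lps = np.atleast_2d(noisy_lps)
    clean_lps = np.atleast_2d(clean_lps)
    if noisy_lps.shape != clean_lps.shape:
        raise InvalidArgumentError("noisy/clean LPS pairs are misaligned")
    out = model.copy()
    if out.norm_stats is None:
        out.norm_stats = NormStats.fit(noisy_lps)
    xn = out.norm_stats.apply(noisy_lps)
    yn = out.norm_stats.apply(clean_lps)
    trained, history = train_mlp(out, xn, yn, cfg, loss="mse")
    return trained, history


def ddae_enhance(model: MlpModel, noisy: SpectralFrames | np.ndarray) -> np.ndarray:
    """Map noisy LPS frames through the network, back in LPS units."""
    lps = noisy.lps if isinstance(noisy, SpectralFrames) else np.atleast_2d(noisy)
    if lps.shape[1] != model.weights[0].shape[0]:
        raise InvalidArgumentError(
            f"frame width {lps.shape[1]} != model width {model.weights[0].shape[0]}"
        )
    stats = model.norm_stats or NormStats.identity(lps.shape[1])
    out = model.forward(stats.apply(lps))
    return stats.invert(out)


# ---------------------------------------------------------------------------
# Knowledge transfer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferEntry:
    class_id: int
    weight: np.ndarray
    bias: np.ndarray
    epochs: int


@dataclass
class TransferStore:
    """Per-class substituted layers keyed to one base (NI) model.

    The store plus the NI model IS the full set of ND models: applying an
    entry reconstructs the matching ND network exactly.
    """

    base_checksum: str
    substituted_index: int  # 1-based weight-layer index
    entries: dict[int, TransferEntry] = field(default_factory=dict)

    def add(self, entry: TransferEntry) -> None:
        self.entries[entry.class_id] = entry

    @property
    def class_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))


def derive_nd_layer(
    ni_model: MlpModel,
    noisy_lps: np.ndarray,
    clean_lps: np.ndarray,
    class_id: int,
    substituted_index: int | None = None,
    cfg: TrainCfg | None = None,
) -> TransferEntry:
    """Fine-tune exactly one layer on single-environment data.

    Starts from the NI parameters, trains with every other layer frozen, and
    returns only the substituted layer's (W, b). The NI model is never
    mutated. Fine-tuning defaults are deliberately gentle (10 epochs,
    lr 1e-4): a single-layer adaptation is a small-step correction.
    """
    L = ni_model.n_layers
    idx = substituted_index if substituted_index is not None else substituted_layer_index(L)
    if not 1 <= idx <= L:
        raise InvalidArgumentError(f"substituted_index {idx} outside 1..{L}")
    cfg = cfg or TrainCfg(lr=1e-4, epochs=10)
    mask = tuple(l == idx - 1 for l in range(L))
    cfg = TrainCfg(lr=cfg.lr, epochs=cfg.epochs, batch_size=cfg.batch_size,
                   seed=cfg.seed, trainable_mask=mask,
                   beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps)
    if ni_model.norm_stats is None:
        raise InvalidArgumentError("ni_model must be trained (no norm_stats found)")
    trained, _ = ddae_train(ni_model, noisy_lps, clean_lps, cfg)
    return TransferEntry(
        class_id,
        trained.weights[idx - 1].copy(),
        trained.biases[idx - 1].copy(),
        cfg.epochs,
    )


def build_store(
    ni_model: MlpModel, entries: Sequence[TransferEntry],
    substituted_index: int | None = None,
) -> TransferStore:
    idx = substituted_index if substituted_index is not None else substituted_layer_index(ni_model.n_layers)
    store = TransferStore(ni_model.checksum(), idx)
    ref_w = ni_model.weights[idx - 1]
    for e in entries:
        if e.weight.shape != ref_w.shape or e.bias.shape != ni_model.biases[idx - 1].shape:
            raise InvalidArgumentError(f"entry for class {e.class_id} has wrong layer shape")
        store.add(e)
    return store


def apply_transfer(ni_model: MlpModel, store: TransferStore, class_id: int) -> MlpModel:
    """Compose the ND model: NI parameters with one stored layer swapped in.

    Pure function — the NI model is untouched; the store must have been built
    against exactly this model (checksum match).
    """
    if store.base_checksum != ni_model.checksum():
        raise StaleStoreError("transfer store does not match this base model")
    if class_id not in store.entries:
        raise KeyError(f"no transfer entry for class {class_id}")
    entry = store.entries[class_id]
    nd = ni_model.copy()
    nd.weights[store.substituted_index - 1] = entry.weight.copy()
    nd.biases[store.substituted_index - 1] = entry.bias.copy()
    nd.meta = {**nd.meta, "nd_class": class_id, "substituted_index": store.substituted_index}
    return nd


# ---------------------------------------------------------------------------
# Layer-substitution sweep
# ---------------------------------------------------------------------------


def layer_sweep(
    ni_model: MlpModel,
    train_data: dict[int, tuple[np.ndarray, np.ndarray]],
    eval_fn,
    r_values: Sequence[int] = (0, 1, 2, 3, 4),
    cfg: TrainCfg | None = None,
):
    """Evaluate which single layer is best to substitute.

    r indexes layers from the output (substituted weight layer = L - r), so
    with L=5 the default grid r in {0..4} sweeps every layer from the output
    (r=0) down to the first weight layer (r=4).

    For every r, derives one ND layer per class from the per-class
    (noisy_lps, clean_lps) training pairs, then calls
    eval_fn(class_id, nd_model) -> dict of metric values for the held-out
    evaluation. Returns a pandas DataFrame with one row per (r, class).
    """
    import pandas as pd

    rows = []
    for r in r_values:
        idx = substituted_layer_index(ni_model.n_layers, r)
        entries = []
        for cid, (noisy, clean) in sorted(train_data.items()):
            entries.append(
                derive_nd_layer(ni_model, noisy, clean, cid, substituted_index=idx, cfg=cfg)
            )
        store = build_store(ni_model, entries, substituted_index=idx)
        for cid in store.class_ids:
            nd = apply_transfer(ni_model, store, cid)
            metrics = eval_fn(cid, nd)
            rows.append({"r": r, "substituted_index": idx, "class_id": cid, **metrics})
    return pd.DataFrame(rows)
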
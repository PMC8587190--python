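"""Model and system serialization.

Checkpoints are single .npz containers holding every parameter array plus a
JSON metadata string (architecture, activations, normalization stats). A
system bundle is a JSON manifest referencing the classifier, base denoiser,
and transfer-store checkpoints alongside the shared STFT config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ddae import TransferEntry, TransferStore
from .features import NormStats, StftConfig
from .mlp import MlpModel
from .system import EanrSystem


def save_mlp(model: MlpModel, path) -> None:
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    meta = {
        "n_layers": model.n_layers,
        "hidden_activation": model.hidden_activation,
        "output_activation": model.output_activation,
        "meta": {k: v if not isinstance(v, tuple) else list(v) for k, v in model.meta.items()},
        "checksum": model.checksum(),
    }
    if model.norm_stats is not None:
        arrays["norm_mean"] = model.norm_stats.mean
        arrays["norm_std"] = model.norm_stats.std
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_mlp(path) -> MlpModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        L = meta["n_layers"]
        ws = [data[f"W{i}"] for i in range(L)]
        bs = [data[f"b{i}"] for i in range(L)]
        stats = None
        if "norm_mean" in data:
            stats = NormStats(data["norm_mean"], data["norm_std"])
    return MlpModel(ws, bs, meta["hidden_activation"], meta["output_activation"],
                    stats, None, meta.get("meta", {}))


def save_store(store: TransferStore, path) -> None:
    arrays = {}
    for cid, e in store.entries.items():
        arrays[f"W_{cid}"] = e.weight
        arrays[f"b_{cid}"] = e.bias
    meta = {
        "base_checksum": store.base_checksum,
        "substituted_index": store.substituted_index,
        "classes": {str(cid): e.epochs for cid, e in store.entries.items()},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_store(path) -> TransferStore:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        store = TransferStore(meta["base_checksum"], meta["substituted_index"])
        for cid_s, epochs in meta["classes"].items():
            cid = int(cid_s)
            store.add(TransferEntry(cid, data[f"W_{cid}"], data[f"b_{cid}"], epochs))
    return store


def save_system(sys: EanrSystem, outdir) -> Path:
    """Write nc/ni/store checkpoints plus a JSON manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_mlp(sys.nc_model, outdir / "nc.npz")
    save_mlp(sys.ni_model, outdir / "ni.npz")
    save_store(sys.store, outdir / "store.npz")
    cfg = sys.stft_cfg
    manifest = {
        "nc": "nc.npz",
        "ni": "ni.npz",
        "store": "store.npz",
        "threshold": sys.threshold,
        "stft_cfg": {
            "frame_len": cfg.frame_len, "hop": cfg.hop, "fft_size": cfg.fft_size,
            "window": cfg.window, "log_floor": cfg.log_floor, "rate": cfg.rate,
            "n_mels": cfg.n_mels, "n_mfcc": cfg.n_mfcc,
        },
    }
    path = outdir / "system.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_system(manifest_path) -> EanrSystem:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    return EanrSystem(
        nc_model=load_mlp(base / manifest["nc"]),
        ni_model=load_mlp(base / manifest["ni"]),
        store=load_store(base / manifest["store"]),
        threshold=manifest["threshold"],
        stft_cfg=StftConfig(**manifest["stft_cfg"]),
    )
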
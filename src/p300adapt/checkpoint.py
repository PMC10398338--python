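"""Checkpoint serialization: model weights + config + seed + history.

A checkpoint is a single ``.npz`` holding every weight array plus a JSON
metadata entry. The same container stores either a plain source model or an
adapted model (source model + target extractor + discriminator info).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .adda import AdaptationResult
from .containers import SchemaError
from .nn import MLP, SpatioTemporalExtractor
from .stcnn import ModelState, STCNNConfig, init_model


def _extractor_arrays(ext: SpatioTemporalExtractor, prefix: str) -> dict:
    return {f"{prefix}Ws": ext.Ws, f"{prefix}bs": ext.bs,
            f"{prefix}Wt": ext.Wt, f"{prefix}bt": ext.bt}


def _load_extractor_into(ext: SpatioTemporalExtractor, data, prefix: str) -> None:
    ext.Ws[...] = data[f"{prefix}Ws"]
    ext.bs[...] = data[f"{prefix}bs"]
    ext.Wt[...] = data[f"{prefix}Wt"]
    ext.bt[...] = data[f"{prefix}bt"]


def _mlp_arrays(mlp: MLP, prefix: str) -> dict:
    out = {}
    for i, layer in enumerate(mlp.layers):
        out[f"{prefix}W{i}"] = layer.W
        out[f"{prefix}b{i}"] = layer.b
    return out


def _load_mlp_into(mlp: MLP, data, prefix: str) -> None:
    for i, layer in enumerate(mlp.layers):
        layer.W[...] = data[f"{prefix}W{i}"]
        layer.b[...] = data[f"{prefix}b{i}"]


def save_model(model: ModelState, path: str | Path,
               adaptation: AdaptationResult | None = None) -> None:
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "history": model.history,
        "has_adaptation": adaptation is not None,
    }
    arrays = {**_extractor_arrays(model.extractor, "ext_"),
              **_mlp_arrays(model.classifier, "clf_")}
    if adaptation is not None:
        arrays.update(_extractor_arrays(adaptation.target_extractor, "tgt_"))
        arrays.update(_mlp_arrays(adaptation.discriminator, "disc_"))
        meta["discriminator_hidden"] = [
            layer.W.shape[1] for layer in adaptation.discriminator.layers[:-1]]
        meta["discriminator_accuracy"] = adaptation.discriminator_accuracy
        arrays["d_loss_curve"] = adaptation.d_loss_curve
        arrays["mapping_loss_curve"] = adaptation.mapping_loss_curve
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> tuple[ModelState, AdaptationResult | None]:
    with np.load(path, allow_pickle=False) as data:
        if "meta" not in data:
            raise SchemaError(f"{path}: not a model checkpoint (missing meta)")
        meta = json.loads(str(data["meta"]))
        cfg = meta["config"]
        cfg["pool_shape"] = tuple(cfg["pool_shape"])
        cfg["classifier_hidden_units"] = tuple(cfg["classifier_hidden_units"])
        config = STCNNConfig(**cfg)
        model = init_model(config, meta["seed"])
        model.history = meta["history"]
        _load_extractor_into(model.extractor, data, "ext_")
        _load_mlp_into(model.classifier, data, "clf_")
        adaptation = None
        if meta.get("has_adaptation"):
            rng = np.random.default_rng(0)
            mt = model.extractor.copy()
            _load_extractor_into(mt, data, "tgt_")
            disc = MLP(model.extractor.n_features,
                       meta["discriminator_hidden"], 1, rng)
            _load_mlp_into(disc, data, "disc_")
            adaptation = AdaptationResult(
                target_extractor=mt,
                discriminator=disc,
                d_loss_curve=data["d_loss_curve"],
                mapping_loss_curve=data["mapping_loss_curve"],
                discriminator_accuracy=float(meta["discriminator_accuracy"]),
            )
    return model, adaptation
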
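"""The spatio-temporal CNN (STCNN) and its supervised pre-training.

Architecture, for a 150 x 10 input epoch (time x electrodes):

* L1 input layer: the 1 x 150 x 10 epoch (amplitudes scaled by a fixed
  input gain so tanh units operate in their linear range);
* L2 spatial convolution: kernels of length 10 spanning the full electrode
  axis (learned spatial filters), tanh;
* L3 temporal convolution: valid kernels of length 4 along time, tanh;
* L4 feature pooling: (2, 1) pooling along time.

The flattened L4 output is the feature vector; a small fully connected
softmax head on top is the label classifier. Time-axis arithmetic with the
defaults: 150 -> 150 (spatial) -> 147 (temporal, valid) -> 73 (pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import ContractError, EpochSet
from .nn import MLP, Adam, SpatioTemporalExtractor, softmax, softmax_cross_entropy


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class STCNNConfig:
    n_channels: int = 10
    n_times: int = 150
    spatial_kernel_len: int = 10
    n_spatial_filters: int = 16
    temporal_kernel_len: int = 4
    n_temporal_filters: int = 16
    pool_shape: tuple[int, int] = (2, 1)
    activation: str = "tanh"
    classifier_hidden_units: tuple[int, ...] = (32,)
    n_classes: int = 2
    pool_mode: str = "max"
    input_scale_uv: float = 10.0   # divides raw microvolt input before L2

    def __post_init__(self) -> None:
        if self.spatial_kernel_len != self.n_channels:
            raise ConfigurationError(
                "spatial kernel must span the full electrode axis "
                f"({self.spatial_kernel_len} != {self.n_channels})"
            )
        if self.pool_shape[0] < 1 or self.pool_shape[1] != 1:
            raise ConfigurationError("pool shape must be (p, 1) with p >= 1")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.temporal_kernel_len > self.n_times:
            raise ConfigurationError(
                f"temporal kernel ({self.temporal_kernel_len}) longer than "
                f"input ({self.n_times})"
            )
        if self.activation != "tanh":
            raise ConfigurationError("only tanh activation is supported")


def feature_shape(config: STCNNConfig) -> tuple[int, int]:
    """(n_feature_maps, n_time_steps) after L2-L4 with valid convolutions."""
    t_after_temporal = config.n_times - config.temporal_kernel_len + 1
    t_after_pool = t_after_temporal // config.pool_shape[0]
    return config.n_temporal_filters, t_after_pool


def feature_dim(config: STCNNConfig) -> int:
    maps, steps = feature_shape(config)
    return maps * steps


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    class_weights: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ContractError("learning rate must be > 0")
        if self.batch_size < 1:
            raise ContractError("batch size must be >= 1")


@dataclass
class ModelState:
    """A trained (or initialized) feature extractor plus classifier."""

    extractor: SpatioTemporalExtractor
    classifier: MLP
    config: STCNNConfig
    seed: int
    history: dict[str, list[float]] = field(default_factory=dict)

    def copy(self) -> "ModelState":
        import copy

        return copy.deepcopy(self)

    def weight_snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in (*self.extractor.params, *self.classifier.params)]


def init_model(config: STCNNConfig, seed: int) -> ModelState:
    rng = np.random.default_rng(seed)
    extractor = SpatioTemporalExtractor(
        n_channels=config.n_channels,
        n_times=config.n_times,
        n_spatial_filters=config.n_spatial_filters,
        temporal_kernel_len=config.temporal_kernel_len,
        n_temporal_filters=config.n_temporal_filters,
        pool=config.pool_shape[0],
        rng=rng,
        pool_mode=config.pool_mode,
    )
    classifier = MLP(extractor.n_features, config.classifier_hidden_units,
                     config.n_classes, rng, final_scale=0.01)
    return ModelState(extractor=extractor, classifier=classifier,
                      config=config, seed=seed)


def _scaled(config: STCNNConfig, epochs: np.ndarray) -> np.ndarray:
    return np.asarray(epochs, dtype=np.float64) / config.input_scale_uv


def extract_features(model_state: ModelState, epochs: np.ndarray,
                     extractor: SpatioTemporalExtractor | None = None) -> np.ndarray:
    """Deterministic forward pass through L1-L4; one row per epoch."""
    ext = extractor if extractor is not None else model_state.extractor
    return ext.forward(_scaled(model_state.config, epochs))


def classify(model_state: ModelState, features: np.ndarray) -> np.ndarray:
    """Class probabilities from the fully connected softmax head."""
    if features.ndim != 2 or features.shape[1] != model_state.extractor.n_features:
        raise ContractError(
            f"features must be (n, {model_state.extractor.n_features}), got {features.shape}"
        )
    return softmax(model_state.classifier.forward(features))


def predict_proba(model_state: ModelState, epochs: np.ndarray,
                  extractor: SpatioTemporalExtractor | None = None) -> np.ndarray:
    return classify(model_state, extract_features(model_state, epochs, extractor))


def pooled_xy(source_epochsets: Sequence[EpochSet]) -> tuple[np.ndarray, np.ndarray]:
    for es in source_epochsets:
        if not es.is_labeled:
            raise ContractError(f"source subject {es.subject_id!r} is unlabeled")
    x = np.concatenate([es.epochs for es in source_epochsets])
    y = np.concatenate([es.labels for es in source_epochsets])
    return x, y


def pretrain(config: STCNNConfig, train_config: TrainConfig,
             source_epochsets: Sequence[EpochSet]) -> ModelState:
    """Supervised pre-training of extractor + classifier on pooled sources.

    Minimizes the softmax cross-entropy with Adam over shuffled mini-batches;
    training stops early when the epoch-mean loss has not improved for
    ``patience`` epochs. The per-epoch loss/accuracy history is recorded on
    the returned :class:`ModelState`.
    """
    x, y = pooled_xy(source_epochsets)
    model = init_model(config, train_config.seed)
    rng = np.random.default_rng(train_config.seed)
    opt = Adam([*model.extractor.params, *model.classifier.params],
               lr=train_config.learning_rate)
    cw = None if train_config.class_weights is None else np.asarray(train_config.class_weights)

    xs = _scaled(config, x)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    best, since_best = np.inf, 0
    for _ in range(train_config.max_epochs):
        order = rng.permutation(len(y))
        losses, n_correct = [], 0
        for start in range(0, len(y), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            feats = model.extractor.forward(xs[idx])
            logits = model.classifier.forward(feats)
            loss, dlogits = softmax_cross_entropy(logits, y[idx], cw)
            dfeats = model.classifier.backward(dlogits)
            model.extractor.backward(dfeats)
            opt.step([*model.extractor.grads, *model.classifier.grads])
            losses.append(loss * len(idx))
            n_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        epoch_loss = float(np.sum(losses) / len(y))
        history["loss"].append(epoch_loss)
        history["accuracy"].append(n_correct / len(y))
        if epoch_loss < best - 1e-5:
            best, since_best = epoch_loss, 0
        else:
            since_best += 1
            if since_best >= train_config.patience:
                break
    model.history = history
    return model


def training_accuracy(model: ModelState, source_epochsets: Sequence[EpochSet]) -> float:
    x, y = pooled_xy(source_epochsets)
    proba = predict_proba(model, x)
    return float((proba.argmax(axis=1) == y).mean())
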
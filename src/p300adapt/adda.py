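"""Adversarial discriminative domain adaptation of the STCNN.

Three stages. (1) Pre-training: extractor ``Ms`` and classifier ``C`` are
trained on pooled labeled source subjects (``stcnn.pretrain``). (2)
Adversarial: a target extractor ``Mt`` is initialized as a copy of ``Ms``
and trained against a domain discriminator ``D`` on *unlabeled* target
epochs; updates alternate between

* ``D``:   minimize  -E log D(Ms(xs)) - E log(1 - D(Mt(xt)))  (extractors frozen)
* ``Mt``:  minimize  -E log D(Mt(xt))                          (D frozen)

so ``Mt`` maps target epochs into the feature space ``D`` attributes to the
source domain. ``Ms`` and ``C`` are frozen throughout. (3) Testing: target
epochs are classified by the *source* classifier on ``Mt`` features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .containers import ContractError, EpochSet
from .nn import MLP, Adam, bce_with_logits, sigmoid
from .preprocessing import baseline_correct, resample_epochs
from .selection import SelectionReport, rank_and_select
from .stcnn import (
    ModelState,
    STCNNConfig,
    TrainConfig,
    _scaled,
    extract_features,
    pretrain,
)
from .nn import SpatioTemporalExtractor


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Fully connected domain discriminator emitting P(feature is source)."""

    hidden_units: tuple[int, ...] = (32,)

    def __post_init__(self) -> None:
        if len(self.hidden_units) < 1:
            raise ContractError("discriminator needs at least one hidden layer")


@dataclass(frozen=True)
class AdaptConfig:
    """Adversarial stage hyperparameters.

    The defaults keep the minimax game balanced on desk-scale data: the
    discriminator learns an order of magnitude slower than the target
    extractor and sees instance-noise-corrupted, label-smoothed inputs so it
    cannot memorize the finite feature clouds and overpower the extractor.
    """

    n_adversarial_steps: int = 700
    d_learning_rate: float = 1.5e-5
    g_learning_rate: float = 1e-4
    d_steps_per_g: int = 1
    batch_size: int = 64
    instance_noise_sd: float = 0.4    # sd of noise added to D inputs
    label_smoothing: float = 0.9      # one-sided: source label for D loss
    holdout_fraction: float = 0.2     # held out for the post-hoc D accuracy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adversarial_steps < 0:
            raise ContractError("n_adversarial_steps must be >= 0")
        if self.d_learning_rate <= 0 or self.g_learning_rate <= 0:
            raise ContractError("learning rates must be > 0")


@dataclass
class AdaptationResult:
    target_extractor: SpatioTemporalExtractor   # Mt
    discriminator: MLP                          # D
    d_loss_curve: np.ndarray
    mapping_loss_curve: np.ndarray
    discriminator_accuracy: float               # held-out, balanced


def init_target_extractor(source_model: ModelState) -> SpatioTemporalExtractor:
    """Exact, isolated copy of the source extractor (Mt starts as Ms)."""
    return source_model.extractor.copy()


def discriminator_logits(disc: MLP, features: np.ndarray) -> np.ndarray:
    return disc.forward(features)


def adversarial_adapt(source_model: ModelState,
                      source_epochsets: Sequence[EpochSet],
                      target_epochs: EpochSet,
                      disc_config: DiscriminatorConfig = DiscriminatorConfig(),
                      adapt_config: AdaptConfig = AdaptConfig()) -> AdaptationResult:
    """Align a target extractor to the frozen source feature space.

    ``target_epochs`` may be unlabeled; labels, when present, are ignored
    (the adaptation is unsupervised by contract). Source features are
    computed once up front — the frozen ``Ms`` never moves.
    """
    rng = np.random.default_rng(adapt_config.seed)
    xs = np.concatenate([es.epochs for es in source_epochsets])
    source_feats = extract_features(source_model, xs)
    xt = _scaled(source_model.config, target_epochs.epochs)

    # held-out split for the post-adaptation discriminator check
    n_hold_s = max(1, int(round(adapt_config.holdout_fraction * len(source_feats))))
    n_hold_t = max(1, int(round(adapt_config.holdout_fraction * len(xt))))
    perm_s = rng.permutation(len(source_feats))
    perm_t = rng.permutation(len(xt))
    hold_s, train_s = perm_s[:n_hold_s], perm_s[n_hold_s:]
    hold_t, train_t = perm_t[:n_hold_t], perm_t[n_hold_t:]
    fs_train = source_feats[train_s]
    xt_train = xt[train_t]

    mt = init_target_extractor(source_model)
    disc = MLP(source_model.extractor.n_features, disc_config.hidden_units, 1, rng)
    opt_d = Adam(disc.params, lr=adapt_config.d_learning_rate)
    opt_g = Adam(mt.params, lr=adapt_config.g_learning_rate)

    bs = adapt_config.batch_size
    noise_sd = adapt_config.instance_noise_sd
    d_curve = np.zeros(adapt_config.n_adversarial_steps)
    g_curve = np.zeros(adapt_config.n_adversarial_steps)
    for step in range(adapt_config.n_adversarial_steps):
        for _ in range(adapt_config.d_steps_per_g):
            fs = fs_train[rng.integers(0, len(fs_train), bs)]
            ft = mt.forward(xt_train[rng.integers(0, len(xt_train), bs)])
            inputs = np.vstack([fs, ft])
            if noise_sd > 0:
                inputs = inputs + rng.normal(0.0, noise_sd, inputs.shape)
            logits = disc.forward(inputs)
            labels = np.concatenate([
                np.full(bs, adapt_config.label_smoothing), np.zeros(bs)])
            d_loss, dlogits = bce_with_logits(logits, labels)
            disc.backward(dlogits)
            opt_d.step(disc.grads)
        d_curve[step] = d_loss

        xb = xt_train[rng.integers(0, len(xt_train), bs)]
        ft = mt.forward(xb)
        if noise_sd > 0:
            logits = disc.forward(ft + rng.normal(0.0, noise_sd, ft.shape))
        else:
            logits = disc.forward(ft)
        g_loss, dlogits = bce_with_logits(logits, np.ones(bs))  # inverted labels
        dft = disc.backward(dlogits)
        mt.backward(dft)
        opt_g.step(mt.grads)
        g_curve[step] = g_loss

    fs_hold = source_feats[hold_s]
    ft_hold = mt.forward(xt[hold_t])
    n_bal = min(len(fs_hold), len(ft_hold))
    p_s = sigmoid(disc.forward(fs_hold[:n_bal])).ravel()
    p_t = sigmoid(disc.forward(ft_hold[:n_bal])).ravel()
    disc_acc = float(np.concatenate([(p_s >= 0.5), (p_t < 0.5)]).mean())

    return AdaptationResult(
        target_extractor=mt,
        discriminator=disc,
        d_loss_curve=d_curve,
        mapping_loss_curve=g_curve,
        discriminator_accuracy=disc_acc,
    )


def test_target(adapted: AdaptationResult | None, source_model: ModelState,
                labeled_target_epochs: EpochSet) -> dict:
    """Accuracy of the source classifier on (adapted) target features.

    Pass ``adapted=None`` for the direct-transfer (no adaptation) baseline,
    which uses the source extractor itself.
    """
    if not labeled_target_epochs.is_labeled:
        raise ContractError("test_target requires a labeled target epoch set")
    ext = source_model.extractor if adapted is None else adapted.target_extractor
    feats = extract_features(source_model, labeled_target_epochs.epochs, ext)
    from .stcnn import classify

    proba = classify(source_model, feats)
    pred = proba.argmax(axis=1)
    y = labeled_target_epochs.labels
    conf = np.zeros((2, 2), dtype=int)
    for yi, pi in zip(y, pred):
        conf[yi, pi] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(conf.sum(axis=1) > 0,
                          np.diag(conf) / np.maximum(conf.sum(axis=1), 1), np.nan)
    return {
        "accuracy": float((pred == y).mean()),
        "n_epochs": int(len(y)),
        "recall_nontarget": float(recall[0]),
        "recall_target": float(recall[1]),
        "confusion": conf.tolist(),
    }


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass
class PipelineConfig:
    """Everything one full cross-subject run needs, with ablation switches."""

    stcnn: STCNNConfig = field(default_factory=STCNNConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    adapt: AdaptConfig = field(default_factory=AdaptConfig)
    selection_rule: str = "below_median"
    selection_k: int = 4
    selection_representation: str = "flatten"
    selection_max_epochs: int = 200
    test_fraction: float = 0.5
    no_adapt: bool = False          # STCNN direct transfer
    no_selection: bool = False      # skip Wasserstein screening
    patient_sources: bool = False   # use other target-domain subjects as sources
    seed: int = 0

    def reseeded(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)


@dataclass
class PipelineResult:
    target_subject_id: str
    selection: SelectionReport
    source_model: ModelState
    adaptation: Optional[AdaptationResult]
    test_metrics: dict
    accuracy: float
    config: PipelineConfig
    seed: int

    def to_dict(self) -> dict:
        out = {
            "target_subject_id": self.target_subject_id,
            "selection": self.selection.to_dict(),
            "accuracy": self.accuracy,
            "test_metrics": self.test_metrics,
            "seed": self.seed,
            "pretrain_final_loss": self.source_model.history["loss"][-1],
            "pretrain_epochs": len(self.source_model.history["loss"]),
        }
        if self.adaptation is not None:
            out["discriminator_accuracy"] = self.adaptation.discriminator_accuracy
            out["n_adversarial_steps"] = int(len(self.adaptation.d_loss_curve))
        return out


def _to_network_shape(epoch_set: EpochSet, config: STCNNConfig) -> EpochSet:
    es = baseline_correct(epoch_set) if epoch_set.baseline is not None else epoch_set
    if es.n_times != config.n_times:
        es = resample_epochs(es, config.n_times)
    return es


def split_target(target: EpochSet, test_fraction: float, seed: int) -> tuple[EpochSet, EpochSet]:
    """Stratified split into an adaptation part and a held-out test part."""
    rng = np.random.default_rng(seed)
    y = target.labels
    if y is None:
        raise ContractError("splitting requires labels for the evaluation half")
    test_idx = []
    for c in (0, 1):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        test_idx.append(idx[: int(round(test_fraction * len(idx)))])
    test_idx = np.sort(np.concatenate(test_idx))
    adapt_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    pick = lambda i: replace(
        target, epochs=target.epochs[i], labels=target.labels[i],
        baseline=None if target.baseline is None else target.baseline[i])
    return pick(adapt_idx), pick(test_idx)


def run_wd_adstcn(cohort: Sequence[EpochSet], target_subject_id: str,
                  config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Full cross-subject run for one held-out target subject.

    Stages: shape the epochs for the network, Wasserstein-screen the
    candidate sources against the (unlabeled) target adaptation split,
    pre-train on the selected pool, adversarially adapt on the unlabeled
    target split, and test the adapted features under the frozen source
    classifier on the held-out labeled split. Ablations: ``no_adapt`` skips
    stage 2 (direct transfer), ``no_selection`` keeps every candidate,
    ``patient_sources`` draws candidates from the target-domain population
    instead of the source-domain one.
    """
    by_id = {es.subject_id: es for es in cohort}
    if target_subject_id not in by_id:
        raise ContractError(f"target subject {target_subject_id!r} not in cohort")
    target_raw = by_id[target_subject_id]

    if config.patient_sources:
        candidates = [es for es in cohort
                      if es.subject_id != target_subject_id and es.domain_tag == "target"]
    else:
        candidates = [es for es in cohort
                      if es.subject_id != target_subject_id and es.domain_tag == "source"]
    if any(es.subject_id == target_subject_id for es in candidates):
        raise ContractError("target subject also listed as a source")
    if not candidates:
        raise ContractError("no candidate source subjects for this configuration")

    ss = np.random.SeedSequence(config.seed)
    seed_split, seed_sel, seed_train, seed_adapt = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4))

    sources = [_to_network_shape(es, config.stcnn) for es in candidates]
    target = _to_network_shape(target_raw, config.stcnn)
    adapt_part, test_part = split_target(target, config.test_fraction, seed_split)
    adapt_unlabeled = adapt_part.without_labels()

    if config.no_selection:
        report = SelectionReport(distances={}, rule="none",
                                 selected=[es.subject_id for es in sources])
    else:
        report = rank_and_select(
            sources, adapt_unlabeled, rule=config.selection_rule,
            k=config.selection_k, representation=config.selection_representation,
            max_epochs_per_subject=config.selection_max_epochs, seed=seed_sel)
    pool = [es for es in sources if es.subject_id in report.selected]

    model = pretrain(config.stcnn, replace(config.train, seed=seed_train), pool)

    adaptation = None
    if not config.no_adapt:
        adaptation = adversarial_adapt(
            model, pool, adapt_unlabeled, config.discriminator,
            replace(config.adapt, seed=seed_adapt))

    metrics = test_target(adaptation, model, test_part)
    return PipelineResult(
        target_subject_id=target_subject_id,
        selection=report,
        source_model=model,
        adaptation=adaptation,
        test_metrics=metrics,
        accuracy=metrics["accuracy"],
        config=config,
        seed=config.seed,
    )
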
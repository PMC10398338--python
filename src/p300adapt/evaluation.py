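"""Cohort-level protocols and statistics.

Provides leave-one-subject-out evaluation, the method x subject benchmark
table, a classical one-way repeated-measures ANOVA (methods as the within
factor, subjects as the repeated measure) with Bonferroni-corrected paired
post-hoc comparisons, a chance-level criterion, and the synthetic transfer
benchmark that quantifies what adversarial adaptation recovers on a
cohort whose covariate shift is known from the simulator manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adda import (
    PipelineConfig,
    adversarial_adapt,
    run_wd_adstcn,
    split_target,
    test_target,
    _to_network_shape,
)
from .containers import ContractError, EpochSet
from .selection import rank_and_select
from .stcnn import TrainConfig, pretrain
from .synthetic import CohortConfig, make_cohort


@dataclass
class BenchmarkTable:
    """Methods (rows) by held-out subjects (columns), cells = accuracy."""

    values: np.ndarray
    methods: list[str]
    subjects: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.methods), len(self.subjects)):
            raise ContractError("table shape must be (n_methods, n_subjects)")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ContractError("accuracies must lie in [0, 1]")

    @property
    def means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.methods, columns=self.subjects)
        df["mean"] = self.means
        return df


def leave_one_subject_out(cohort: Sequence[EpochSet],
                          config: PipelineConfig = PipelineConfig()) -> dict[str, float]:
    """One accuracy per held-out subject, all others as candidate sources."""
    if len(cohort) < 2:
        raise ContractError("leave-one-subject-out needs at least 2 subjects")
    accuracies: dict[str, float] = {}
    for es in cohort:
        result = run_wd_adstcn(cohort, es.subject_id, config)
        accuracies[es.subject_id] = result.accuracy
    return accuracies


@dataclass
class RMAnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    df2_between_style: int   # the m*s - m convention some software reports
    ss_method: float
    ss_subject: float
    ss_error: float


def rm_anova(table: BenchmarkTable) -> RMAnovaResult:
    """Classical one-way repeated-measures ANOVA on the benchmark table.

    No sphericity correction is applied. Degenerate case: when the method
    effect is exactly zero the statistic is reported as F = 0, p = 1.
    """
    x = table.values
    m, s = x.shape
    if m < 2 or s < 2:
        raise ContractError("need at least 2 methods and 2 subjects")
    if np.isnan(x).any():
        raise ContractError("missing cells are not allowed")
    grand = x.mean()
    ss_method = s * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_subject = m * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_method - ss_subject
    df1, df2 = m - 1, (m - 1) * (s - 1)
    ms_method = ss_method / df1
    ms_error = ss_error / df2
    scale = max(ss_total, 1e-30)
    if ss_method <= 1e-12 * scale:
        f, p = 0.0, 1.0
    elif ms_error <= 1e-12 * scale / df2:
        f, p = np.inf, 0.0
    else:
        f = ms_method / ms_error
        p = float(stats.f.sf(f, df1, df2))
    return RMAnovaResult(F=float(f), df1=df1, df2=df2, p=p,
                         df2_between_style=m * s - m,
                         ss_method=ss_method, ss_subject=ss_subject,
                         ss_error=ss_error)


def bonferroni_pairwise(table: BenchmarkTable, reference_method: str) -> dict[str, dict]:
    """Paired t-tests of the reference against every other method.

    Corrected p = min(1, raw p * n_comparisons). A comparison with zero
    paired differences has raw p = 1 by convention.
    """
    if reference_method not in table.methods:
        raise ContractError(f"reference method {reference_method!r} not in table")
    ref = table.values[table.methods.index(reference_method)]
    others = [m for m in table.methods if m != reference_method]
    n_comp = len(others)
    out: dict[str, dict] = {}
    for name in others:
        other = table.values[table.methods.index(name)]
        diff = ref - other
        if np.allclose(diff, 0.0):
            raw = 1.0
        else:
            raw = float(stats.ttest_rel(ref, other).pvalue)
            if np.isnan(raw):
                raw = 1.0
        out[name] = {"raw_p": raw, "corrected_p": min(1.0, raw * n_comp)}
    return out


def chance_level_flag(accuracy: float, n_trials: int, criterion: str = "fixed",
                      fixed_chance: float = 0.64, alpha: float = 0.05) -> bool:
    """Is this accuracy above chance?

    ``fixed``: strict comparison against a fixed criterion (default 64%,
    the convention adopted for this paradigm). ``binomial``: exact binomial
    test of n_correct successes against p = 0.5 at level ``alpha``.
    """
    if n_trials <= 0:
        raise ContractError("n_trials must be > 0")
    if criterion == "fixed":
        return accuracy > fixed_chance
    if criterion == "binomial":
        k = int(round(accuracy * n_trials))
        return float(stats.binomtest(k, n_trials, 0.5, alternative="greater").pvalue) < alpha
    raise ContractError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# synthetic transfer benchmark


@dataclass
class TransferBenchmarkConfig:
    """Desk-scale benchmark: healthy sources, DOC-like targets, known shift."""

    n_sources: int = 8
    n_targets_per_cohort: int = 2
    n_epochs_per_class: int = 160         # per healthy source subject
    n_epochs_per_class_target: int = 300  # per DOC-like target subject
    master_seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    include_no_selection: bool = False
    pipeline: PipelineConfig = field(default_factory=lambda: PipelineConfig(
        train=TrainConfig(max_epochs=40, patience=8),
    ))
    oracle_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=60, patience=10))


def run_transfer_benchmark(config: TransferBenchmarkConfig = TransferBenchmarkConfig()) -> pd.DataFrame:
    """Direct transfer vs adversarial adaptation vs a target-supervised oracle.

    For every master seed a fresh cohort is simulated. Each DOC-like subject
    in turn is the target: candidate healthy sources are Wasserstein-
    screened, the STCNN is pre-trained on the selected pool, and the same
    pre-trained model is evaluated on the held-out target split (i) without
    adaptation (direct transfer) and (ii) after adversarial adaptation on
    the unlabeled target split. An oracle trained on the *labeled*
    adaptation split bounds what any adaptation could achieve. Returns one
    row per (seed, target) with all accuracies and the recovered fraction
    of the direct-to-oracle gap.
    """
    rows = []
    for master_seed in config.master_seeds:
        cohort_cfg = CohortConfig(
            n_healthy=config.n_sources, n_doc=config.n_targets_per_cohort,
            n_targets=config.n_epochs_per_class,
            n_nontargets=config.n_epochs_per_class,
            n_targets_doc=config.n_epochs_per_class_target,
            n_nontargets_doc=config.n_epochs_per_class_target,
            master_seed=master_seed)
        cohort, manifest, _ = make_cohort(cohort_cfg)
        pcfg = config.pipeline.reseeded(master_seed)

        ss = np.random.SeedSequence(master_seed + 10_000)
        seeds = iter(int(s.generate_state(1)[0] % (2**31 - 1))
                     for s in ss.spawn(4 * config.n_targets_per_cohort))

        sources = [_to_network_shape(es, pcfg.stcnn) for es in cohort
                   if es.domain_tag == "source"]
        for es in cohort:
            if es.domain_tag != "target":
                continue
            seed_split, seed_sel, seed_train, seed_adapt = (next(seeds) for _ in range(4))
            target = _to_network_shape(es, pcfg.stcnn)
            adapt_part, test_part = split_target(target, pcfg.test_fraction, seed_split)
            adapt_unlabeled = adapt_part.without_labels()

            report = rank_and_select(
                sources, adapt_unlabeled, rule=pcfg.selection_rule,
                k=pcfg.selection_k, representation=pcfg.selection_representation,
                max_epochs_per_subject=pcfg.selection_max_epochs, seed=seed_sel)
            pool = [s for s in sources if s.subject_id in report.selected]

            model = pretrain(pcfg.stcnn, replace(pcfg.train, seed=seed_train), pool)
            direct_acc = test_target(None, model, test_part)["accuracy"]

            adaptation = adversarial_adapt(
                model, pool, adapt_unlabeled, pcfg.discriminator,
                replace(pcfg.adapt, seed=seed_adapt))
            adapted_acc = test_target(adaptation, model, test_part)["accuracy"]

            oracle_model = pretrain(pcfg.stcnn,
                                    replace(config.oracle_train, seed=seed_train),
                                    [adapt_part])
            oracle_acc = test_target(None, oracle_model, test_part)["accuracy"]

            row = {
                "master_seed": master_seed,
                "target": es.subject_id,
                "n_selected": len(pool),
                "direct_accuracy": direct_acc,
                "adapted_accuracy": adapted_acc,
                "oracle_accuracy": oracle_acc,
                "discriminator_accuracy": adaptation.discriminator_accuracy,
                "gap": oracle_acc - direct_acc,
                "recovered_fraction": (
                    (adapted_acc - direct_acc) / (oracle_acc - direct_acc)
                    if oracle_acc > direct_acc else np.nan),
            }
            if config.include_no_selection:
                model_all = pretrain(pcfg.stcnn, replace(pcfg.train, seed=seed_train),
                                     sources)
                adaptation_all = adversarial_adapt(
                    model_all, sources, adapt_unlabeled, pcfg.discriminator,
                    replace(pcfg.adapt, seed=seed_adapt))
                row["no_selection_accuracy"] = test_target(
                    adaptation_all, model_all, test_part)["accuracy"]
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_transfer_benchmark(df: pd.DataFrame) -> dict[str, float]:
    """Median-over-seeds summary of :func:`run_transfer_benchmark` output."""
    per_seed = df.groupby("master_seed")
    out = {
        "median_direct_accuracy": float(per_seed["direct_accuracy"].mean().median()),
        "median_adapted_accuracy": float(per_seed["adapted_accuracy"].mean().median()),
        "median_oracle_accuracy": float(per_seed["oracle_accuracy"].mean().median()),
        "median_discriminator_accuracy": float(
            per_seed["discriminator_accuracy"].mean().median()),
        "median_recovered_fraction": float(
            per_seed["recovered_fraction"].mean().median()),
    }
    if "no_selection_accuracy" in df.columns:
        out["median_no_selection_accuracy"] = float(
            per_seed["no_selection_accuracy"].mean().median())
    return out
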
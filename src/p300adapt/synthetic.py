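"""Synthetic multi-subject oddball ERP cohorts.

Each simulated subject emits stimulus-locked 10-channel epochs at 250 Hz
covering [-100, 1000) ms around stimulus onset. A target epoch contains,
with probability ``occurrence_rate``, a positive Gaussian-shaped deflection
(the P300 analogue) of given amplitude, latency and width, projected onto a
parieto-central topography; non-target epochs never do. On top of that every
epoch carries white Gaussian background noise and an alpha-like background
oscillation with a random phase per epoch. Finally a per-subject invertible
channel-mixing matrix is applied, which — together with amplitude, latency
and occurrence differences — is the inter-subject covariate shift the
adversarial stage is asked to undo.

Two stereotyped populations are provided: "healthy" subjects with a clear
~300 ms deflection occurring on nearly every target trial, and "DOC-like"
subjects with delayed, weakened deflections, reduced occurrence rates and a
stronger channel mixing. The generative truth for every subject is recorded
in a manifest so recovery can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CANONICAL_MONTAGE, ContractError, EpochSet

#: Relative deflection gain per electrode, peaking at Pz/Cz (posterior
#: midline dominance typical of the P300).
DEFAULT_TOPOGRAPHY = np.array([0.5, 0.6, 0.5, 0.4, 0.7, 1.0, 0.7, 0.4, 0.5, 0.9])

SFREQ = 250.0
EPOCH_MS = ((-100.0), 1000.0)
N_BASELINE = 25   # [-100, 0) ms at 250 Hz
N_TIMES = 250     # [0, 1000) ms at 250 Hz


@dataclass
class SubjectProfile:
    """Generative ground truth for one synthetic subject."""

    subject_id: str
    p300_amplitude_uv: float = 6.0
    p300_latency_ms: float = 300.0
    p300_width_ms: float = 200.0          # FWHM of the Gaussian deflection
    occurrence_rate: float = 1.0
    topography: np.ndarray = field(default_factory=lambda: DEFAULT_TOPOGRAPHY.copy())
    noise_sd_uv: float = 4.0
    background_rhythm: tuple[float, float] = (3.0, 10.0)  # (amplitude µV, freq Hz)
    channel_mixing: np.ndarray = field(default_factory=lambda: np.eye(10))
    seed: int = 0

    def __post_init__(self) -> None:
        self.topography = np.asarray(self.topography, dtype=np.float64)
        self.channel_mixing = np.asarray(self.channel_mixing, dtype=np.float64)
        if not 0.0 <= self.occurrence_rate <= 1.0:
            raise ContractError("occurrence_rate must be in [0, 1]")
        if self.p300_amplitude_uv < 0:
            raise ContractError("p300_amplitude_uv must be >= 0")
        if (self.topography < 0).any():
            raise ContractError("topography must be nonnegative")
        if self.topography.shape != (len(CANONICAL_MONTAGE),):
            raise ContractError("topography must have one weight per montage channel")
        if abs(np.linalg.det(self.channel_mixing)) < 1e-9:
            raise ContractError("channel_mixing must be invertible")


def simulate_subject(profile: SubjectProfile, n_targets: int, n_nontargets: int) -> EpochSet:
    """Simulate one subject's labeled epochs (baseline segment attached).

    The trial order is shuffled; everything is reproducible from
    ``profile.seed``.
    """
    if n_targets < 0 or n_nontargets < 0:
        raise ContractError("epoch counts must be nonnegative")
    rng = np.random.default_rng(profile.seed)
    n = n_targets + n_nontargets
    n_ch = len(CANONICAL_MONTAGE)
    t_full = (np.arange(-N_BASELINE, N_TIMES) / SFREQ) * 1000.0  # ms

    labels = np.array([1] * n_targets + [0] * n_nontargets)
    rng.shuffle(labels)

    sigma = profile.p300_width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    bump = np.exp(-0.5 * ((t_full - profile.p300_latency_ms) / sigma) ** 2)
    deflection = profile.p300_amplitude_uv * bump[:, None] * profile.topography[None, :]

    amp_rhythm, f_rhythm = profile.background_rhythm
    data = np.empty((n, t_full.size, n_ch))
    for i in range(n):
        epoch = rng.normal(0.0, profile.noise_sd_uv, size=(t_full.size, n_ch)) \
            if profile.noise_sd_uv > 0 else np.zeros((t_full.size, n_ch))
        if amp_rhythm > 0:
            phase = rng.uniform(0, 2 * np.pi)
            epoch += amp_rhythm * np.sin(2 * np.pi * f_rhythm * t_full / 1000.0 + phase)[:, None]
        if labels[i] == 1 and rng.uniform() < profile.occurrence_rate:
            epoch = epoch + deflection
        data[i] = epoch @ profile.channel_mixing.T

    return EpochSet(
        epochs=data[:, N_BASELINE:, :],
        baseline=data[:, :N_BASELINE, :],
        labels=labels,
        times_ms=t_full[N_BASELINE:],
        sampling_rate=SFREQ,
        channel_names=list(CANONICAL_MONTAGE),
        subject_id=profile.subject_id,
        domain_tag="source",
    )


@dataclass
class ParameterRanges:
    """Uniform sampling ranges for one population's subject profiles.

    ``posterior_attenuation`` scales down the channels carrying the
    deflection (strongest at Pz/Cz) inside the mixing matrix, modeling
    damaged parieto-central generators; together with ``mixing_strength``
    it forms the linear, invertible part of the covariate shift that the
    adversarial stage is expected to undo. Background noise and rhythm are
    held common across subjects by default so the inter-subject shift is
    carried by the deflection parameters and the channel mixing.
    """

    amplitude_uv: tuple[float, float]
    latency_ms: tuple[float, float]
    width_ms: tuple[float, float]
    occurrence: tuple[float, float]
    noise_sd_uv: tuple[float, float]
    rhythm_amplitude_uv: tuple[float, float]
    rhythm_freq_hz: tuple[float, float]
    mixing_strength: tuple[float, float]
    posterior_attenuation: tuple[float, float] = (0.0, 0.0)


#: Healthy population: prominent ~300 ms deflection on almost every target
#: trial, mild subject-specific channel mixing.
HEALTHY_RANGES = ParameterRanges(
    amplitude_uv=(4.0, 8.0),
    latency_ms=(280.0, 320.0),
    width_ms=(150.0, 250.0),
    occurrence=(0.9, 1.0),
    noise_sd_uv=(4.0, 4.0),
    rhythm_amplitude_uv=(3.0, 3.0),
    rhythm_freq_hz=(10.0, 10.0),
    mixing_strength=(0.0, 0.15),
)

#: DOC-like population, modeled on patients whose deflection is detectable
#: but degraded: weakened and moderately delayed deflections, reduced
#: occurrence rate, and a strong (but invertible) spatial shift — random
#: channel mixing plus attenuation of the parieto-central channels.
DOC_RANGES = ParameterRanges(
    amplitude_uv=(2.5, 3.5),
    latency_ms=(330.0, 380.0),
    width_ms=(200.0, 300.0),
    occurrence=(0.75, 0.9),
    noise_sd_uv=(4.0, 4.0),
    rhythm_amplitude_uv=(3.0, 3.0),
    rhythm_freq_hz=(10.0, 10.0),
    mixing_strength=(0.5, 0.8),
    posterior_attenuation=(0.6, 0.85),
)

#: A severe phenotype (strongly delayed, weak, rare deflections) on which
#: cross-subject transfer — adapted or not — is expected to fail; mirrors
#: the patients for whom no method achieved usable accuracy.
SEVERE_DOC_RANGES = ParameterRanges(
    amplitude_uv=(1.0, 2.0),
    latency_ms=(420.0, 500.0),
    width_ms=(150.0, 300.0),
    occurrence=(0.3, 0.5),
    noise_sd_uv=(4.0, 4.0),
    rhythm_amplitude_uv=(3.0, 3.0),
    rhythm_freq_hz=(10.0, 10.0),
    mixing_strength=(0.5, 0.8),
    posterior_attenuation=(0.6, 0.85),
)


@dataclass
class CohortConfig:
    """A cohort: healthy subjects plus DOC-like subjects, 1:1 target ratio.

    ``n_targets``/``n_nontargets`` are per healthy subject;
    ``n_targets_doc``/``n_nontargets_doc`` override the counts for DOC-like
    subjects (patients are recorded over multiple sessions, and their data
    must feed both the unlabeled adaptation split and the labeled test
    split). ``None`` means same as healthy.
    """

    n_healthy: int = 8
    n_doc: int = 3
    n_targets: int = 150
    n_nontargets: int = 150
    n_targets_doc: int | None = None
    n_nontargets_doc: int | None = None
    healthy_ranges: ParameterRanges = field(default_factory=lambda: HEALTHY_RANGES)
    doc_ranges: ParameterRanges = field(default_factory=lambda: DOC_RANGES)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_doc < 0 or self.n_healthy + self.n_doc == 0:
            raise ContractError("cohort must contain at least one subject")
        if self.n_targets <= 0 or self.n_nontargets <= 0:
            raise ContractError("per-subject epoch counts must be > 0")


def _mixing_matrix(rng: np.random.Generator, strength: float, n_ch: int = 10) -> np.ndarray:
    """Invertible mixing ``I + strength * G`` (redrawn if near-singular)."""
    for _ in range(100):
        g = rng.normal(0.0, 1.0 / np.sqrt(n_ch), size=(n_ch, n_ch))
        m = np.eye(n_ch) + strength * g
        if abs(np.linalg.det(m)) > 1e-3:
            return m
    raise RuntimeError("could not draw an invertible mixing matrix")


def _draw_profile(subject_id: str, ranges: ParameterRanges, seed: int) -> SubjectProfile:
    rng = np.random.default_rng(seed)
    u = lambda lo_hi: float(rng.uniform(*lo_hi)) if lo_hi[0] != lo_hi[1] else float(lo_hi[0])
    beta = u(ranges.posterior_attenuation)
    attenuation = 1.0 - beta * (DEFAULT_TOPOGRAPHY / DEFAULT_TOPOGRAPHY.max())
    mixing = _mixing_matrix(rng, u(ranges.mixing_strength)) @ np.diag(attenuation)
    return SubjectProfile(
        subject_id=subject_id,
        p300_amplitude_uv=u(ranges.amplitude_uv),
        p300_latency_ms=u(ranges.latency_ms),
        p300_width_ms=u(ranges.width_ms),
        occurrence_rate=u(ranges.occurrence),
        noise_sd_uv=u(ranges.noise_sd_uv),
        background_rhythm=(u(ranges.rhythm_amplitude_uv), u(ranges.rhythm_freq_hz)),
        channel_mixing=mixing,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_cohort(config: CohortConfig) -> tuple[list[EpochSet], pd.DataFrame, list[SubjectProfile]]:
    """Simulate a full cohort.

    Returns the per-subject epoch sets, a manifest of the generative truth
    (one row per subject), and the drawn profiles. Per-subject seeds derive
    deterministically from the master seed, so two cohorts with the same
    config are identical.
    """
    ss = np.random.SeedSequence(config.master_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in
                   ss.spawn(config.n_healthy + config.n_doc)]
    profiles: list[SubjectProfile] = []
    for i in range(config.n_healthy):
        profiles.append(_draw_profile(f"H{i + 1}", config.healthy_ranges, child_seeds[i]))
    for j in range(config.n_doc):
        profiles.append(_draw_profile(f"P{j + 1}", config.doc_ranges,
                                      child_seeds[config.n_healthy + j]))

    nt_doc = config.n_targets_doc or config.n_targets
    nnt_doc = config.n_nontargets_doc or config.n_nontargets
    epoch_sets, rows = [], []
    for prof in profiles:
        if prof.subject_id.startswith("H"):
            es = simulate_subject(prof, config.n_targets, config.n_nontargets)
        else:
            es = simulate_subject(prof, nt_doc, nnt_doc)
        es.domain_tag = "source" if prof.subject_id.startswith("H") else "target"
        epoch_sets.append(es)
        row = {k: v for k, v in asdict(prof).items()
               if k not in ("topography", "channel_mixing")}
        row["population"] = "healthy" if prof.subject_id.startswith("H") else "doc_like"
        row["rhythm_amplitude_uv"], row["rhythm_freq_hz"] = row.pop("background_rhythm")
        row["mixing_offdiag_norm"] = float(
            np.linalg.norm(prof.channel_mixing - np.eye(10)))
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return epoch_sets, manifest, profiles
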
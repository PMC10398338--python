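"""Wasserstein-distance screening of candidate source subjects.

Each subject's epochs are embedded as an empirical distribution (one point
per epoch, uniform weights) and the Wasserstein-1 distance
``W(p, q) = inf_{gamma in Pi(p, q)} E ||x - y||`` with Euclidean ground cost
is estimated between every candidate source and the target subject. Source
subjects closer to the target keep their place in the training pool.

Three estimators are provided: ``exact_lp`` (the transportation linear
program, any sizes/weights), ``assignment`` (Hungarian algorithm — exact for
equal-size uniform-weight sets and much faster), and ``sliced`` (random
1-D projections; an approximation, used only when dimensions/sizes make the
LP unattractive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.spatial.distance import cdist

from .containers import ContractError, EpochSet


@dataclass
class EmpiricalDistribution:
    """Uniformly weighted point cloud standing in for a subject's distribution."""

    points: np.ndarray                      # (n_points, d)
    weights: Optional[np.ndarray] = None    # defaults to uniform
    origin_subject_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2:
            raise ContractError("points must be 2-D (n_points, d)")
        if self.weights is None:
            self.weights = np.full(self.n, 1.0 / self.n)
        else:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape != (self.n,):
                raise ContractError("weights must have one entry per point")
            if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
                raise ContractError("weights must be nonnegative and sum to 1")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass
class TransportPlan:
    """An optimal coupling between two empirical distributions."""

    coupling: np.ndarray   # (n_source, n_target), nonnegative mass
    cost: float            # sum(coupling * pairwise Euclidean cost)

    def check(self, p: EmpiricalDistribution, q: EmpiricalDistribution,
              atol: float = 1e-8) -> None:
        if (self.coupling < -atol).any():
            raise ContractError("coupling has negative mass")
        if not np.allclose(self.coupling.sum(axis=1), p.weights, atol=atol):
            raise ContractError("coupling row sums do not match source weights")
        if not np.allclose(self.coupling.sum(axis=0), q.weights, atol=atol):
            raise ContractError("coupling column sums do not match target weights")
        cost = float((self.coupling * cdist(p.points, q.points)).sum())
        if abs(cost - self.cost) > atol * max(1.0, abs(cost)):
            raise ContractError("stored cost inconsistent with coupling")


Representation = Literal["flatten", "channel_mean_erp", "pca_k"]


def epochs_to_distribution(epoch_set: EpochSet, representation: Representation = "flatten",
                           pca_components: int = 10,
                           fit_union: Optional[Sequence[EpochSet]] = None) -> EmpiricalDistribution:
    """Embed an epoch set as an empirical distribution.

    ``flatten`` turns each epoch into one ``n_times * n_channels`` vector.
    ``channel_mean_erp`` yields one point per class (the concatenated
    per-channel mean ERP) and requires labels. ``pca_k`` flattens then
    projects onto the top ``pca_components`` principal axes fit on the union
    of ``fit_union`` (default: this set alone).
    """
    flat = epoch_set.epochs.reshape(epoch_set.n_epochs, -1)
    if representation == "flatten":
        pts = flat
    elif representation == "channel_mean_erp":
        if not epoch_set.is_labeled:
            raise ContractError("channel_mean_erp requires labeled data")
        pts = np.stack([
            epoch_set.epochs[epoch_set.labels == c].mean(axis=0).ravel()
            for c in (0, 1)
        ])
    elif representation == "pca_k":
        pool = flat if fit_union is None else np.vstack(
            [e.epochs.reshape(e.n_epochs, -1) for e in fit_union])
        mean = pool.mean(axis=0)
        _, _, vt = np.linalg.svd(pool - mean, full_matrices=False)
        pts = (flat - mean) @ vt[:pca_components].T
    else:
        raise ContractError(f"unknown representation {representation!r}")
    return EmpiricalDistribution(points=pts, origin_subject_id=epoch_set.subject_id)


def _exact_lp(p: EmpiricalDistribution, q: EmpiricalDistribution):
    cost = cdist(p.points, q.points)
    n, m = cost.shape
    # marginal constraints: n row-sum equalities + m column-sum equalities
    # (one is redundant; HiGHS copes).
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([p.weights, q.weights])
    res = optimize.linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq,
                           bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    gamma = res.x.reshape(n, m)
    value = float((gamma * cost).sum())
    return value, TransportPlan(coupling=gamma, cost=value)


def _assignment(p: EmpiricalDistribution, q: EmpiricalDistribution):
    if p.n != q.n:
        raise ContractError("assignment method requires equal-size point sets")
    if not (np.allclose(p.weights, 1.0 / p.n) and np.allclose(q.weights, 1.0 / q.n)):
        raise ContractError("assignment method requires uniform weights")
    cost = cdist(p.points, q.points)
    rows, cols = optimize.linear_sum_assignment(cost)
    gamma = np.zeros_like(cost)
    gamma[rows, cols] = 1.0 / p.n
    value = float(cost[rows, cols].mean())
    return value, TransportPlan(coupling=gamma, cost=value)


def _sliced(p: EmpiricalDistribution, q: EmpiricalDistribution,
            n_projections: int, seed: int):
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_projections):
        u = rng.normal(size=p.dim)
        u /= np.linalg.norm(u)
        a = np.sort(p.points @ u)
        b = np.sort(q.points @ u)
        if a.size == b.size:
            total += np.abs(a - b).mean()
        else:  # evaluate both empirical quantile functions on a common grid
            grid = np.linspace(0, 1, 200, endpoint=False) + 0.5 / 200
            total += np.abs(np.quantile(a, grid) - np.quantile(b, grid)).mean()
    return total / n_projections, None


def wasserstein_distance(p: EmpiricalDistribution, q: EmpiricalDistribution,
                         method: str = "auto", n_projections: int = 500,
                         seed: int = 0) -> tuple[float, Optional[TransportPlan]]:
    """Wasserstein-1 distance between two empirical distributions.

    ``method`` is one of ``exact_lp``, ``assignment``, ``sliced`` or
    ``auto`` (assignment when applicable, else exact LP). The sliced
    estimator returns no transport plan.
    """
    if p.dim != q.dim:
        raise ContractError(f"dimension mismatch: {p.dim} vs {q.dim}")
    if method == "auto":
        uniform = np.allclose(p.weights, 1.0 / p.n) and np.allclose(q.weights, 1.0 / q.n)
        method = "assignment" if (p.n == q.n and uniform) else "exact_lp"
    if method == "exact_lp":
        return _exact_lp(p, q)
    if method == "assignment":
        return _assignment(p, q)
    if method == "sliced":
        return _sliced(p, q, n_projections, seed)
    raise ContractError(f"unknown method {method!r}")


@dataclass
class SelectionReport:
    """Per-source Wasserstein distances and the resulting training pool."""

    distances: dict[str, float]
    rule: str
    selected: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"distances": dict(sorted(self.distances.items())),
                "rule": self.rule, "selected": sorted(self.selected)}


def _subsample(epoch_set: EpochSet, max_epochs: int, seed: int) -> EpochSet:
    if epoch_set.n_epochs <= max_epochs:
        return epoch_set
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(epoch_set.n_epochs, size=max_epochs, replace=False))
    from dataclasses import replace

    return replace(epoch_set, epochs=epoch_set.epochs[idx],
                   labels=None if epoch_set.labels is None else epoch_set.labels[idx],
                   baseline=None if epoch_set.baseline is None else epoch_set.baseline[idx])


def rank_and_select(sources: Sequence[EpochSet], target: EpochSet,
                    rule: str = "below_median", k: int = 4, threshold: float = np.inf,
                    representation: Representation = "flatten",
                    max_epochs_per_subject: int = 200, method: str = "auto",
                    seed: int = 0) -> SelectionReport:
    """Score each source subject against the target and pick the pool.

    Rules: ``top_k`` (k closest), ``below_median`` (distance <= median),
    ``threshold`` (distance <= tau). Ties break by lexicographic subject id.
    Epoch sets larger than ``max_epochs_per_subject`` are subsampled
    (seeded) before the distance computation for tractability.
    """
    if not sources:
        raise ContractError("need at least one candidate source subject")
    import warnings

    tgt = _subsample(target, max_epochs_per_subject, seed)
    q = epochs_to_distribution(tgt, representation)
    distances: dict[str, float] = {}
    for i, src in enumerate(sources):
        sub = _subsample(src, max_epochs_per_subject, seed + 1 + i)
        p = epochs_to_distribution(sub, representation)
        distances[src.subject_id], _ = wasserstein_distance(p, q, method=method, seed=seed)

    order = sorted(distances, key=lambda s: (distances[s], s))
    if rule == "top_k":
        if k > len(order):
            warnings.warn(f"top_k k={k} exceeds {len(order)} sources; clamping",
                          stacklevel=2)
            k = len(order)
        selected = order[:k]
    elif rule == "below_median":
        med = float(np.median(list(distances.values())))
        selected = [s for s in order if distances[s] <= med]
    elif rule == "threshold":
        selected = [s for s in order if distances[s] <= threshold]
    else:
        raise ContractError(f"unknown selection rule {rule!r}")
    if not selected:  # never return an empty training pool
        selected = order[:1]
    return SelectionReport(distances=distances, rule=rule, selected=selected)
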
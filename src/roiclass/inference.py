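"""Permutation-null significance and between-model distribution comparison.

The null protocol repeats the evaluation cycle with the training/validation
labels permuted (test labels untouched) and no grid search: the winning
hyperparameters of the real-label run are fixed, 10-fold CV picks the
highest-accuracy fold pipeline on shuffled labels, and that pipeline is
scored on the real-label test split. The p-value is the fraction of null
metric values at or above the real-label mean. The frequency distribution
comparison index (FDCI) quantifies how often one model's accuracy exceeds
the other's (0.5 = equipoise, near 1 = first model dominates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .evaluate import (
    METRIC_NAMES,
    EvaluationError,
    EvaluationSummary,
    GridSpec,
    MetricSet,
    evaluate_test,
    grid_search_cv,
    iteration_seeds,
    stratified_split,
)
from .pipeline import balance_indices


class InferenceError(ValueError):
    pass


@dataclass
class NullDistribution:
    """Metric distributions from permuted-label ("non-optimal") pipelines."""

    metrics: list[MetricSet]
    R: int
    master_seed: int
    kind: str
    fixed_hyperparams: dict = field(default_factory=dict)

    def values(self, metric: str) -> np.ndarray:
        if metric not in METRIC_NAMES:
            raise InferenceError(f"unknown metric {metric!r}")
        return np.array([m.get(metric) for m in self.metrics])


@dataclass(frozen=True)
class SignificanceEntry:
    metric: str
    optimal_mean: float
    null_mean: float
    null_sd: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InferenceError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class SignificanceReport:
    entries: dict[str, SignificanceEntry]

    def p_value(self, metric: str) -> float:
        return self.entries[metric].p_value

    def as_dict(self) -> dict:
        return {
            m: {
                "optimal_mean": e.optimal_mean,
                "null_mean": e.null_mean,
                "null_sd": e.null_sd,
                "p_value": e.p_value,
            }
            for m, e in self.entries.items()
        }


@dataclass(frozen=True)
class ComparisonResult:
    fdci: float
    n_first: int
    n_second: int
    ties: int
    paired: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdci <= 1.0:
            raise InferenceError("FDCI must lie in [0, 1]")


def run_null_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    fixed_hyperparams: dict,
    R: int = 1000,
    master_seed: int = 0,
    k: int = 10,
    test_fraction: float = 0.2,
    balance: bool = True,
) -> NullDistribution:
    """Permuted-label counterpart of the repeated evaluation.

    Per iteration: balanced subsample, stratified 80/20 split, permutation of
    the 80% labels only, 10-fold CV at the fixed hyperparameters, best fold
    pipeline evaluated against the true test labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = GridSpec.fixed(kind, fixed_hyperparams)
    metrics: list[MetricSet] = []

    for ss in iteration_seeds(master_seed, R):
        rng = np.random.default_rng(ss)
        idx = balance_indices(y, rng) if balance else np.arange(y.size)
        Xb, yb = X[idx], y[idx]
        tr, te = stratified_split(yb, test_fraction, rng)
        y_perm = rng.permutation(yb[tr])  # test labels never permuted
        pipe, _, _ = grid_search_cv(Xb[tr], y_perm, grid, k=k, seed=rng)
        _, ms = evaluate_test(pipe, Xb[te], yb[te])
        metrics.append(ms)

    return NullDistribution(
        metrics=metrics,
        R=R,
        master_seed=master_seed,
        kind=kind,
        fixed_hyperparams=dict(fixed_hyperparams),
    )


def compute_p(
    optimal: EvaluationSummary | float,
    null: NullDistribution | Sequence[float],
    metric: str = "acc",
    smoothed: bool = False,
) -> SignificanceEntry:
    """Counting-rule p-value: share of null values >= the optimal mean.

    ``smoothed=True`` applies the (b+1)/(R+1) permutation correction.
    """
    if isinstance(optimal, EvaluationSummary):
        optimal_mean = optimal.mean(metric)
    else:
        optimal_mean = float(optimal)
    null_values = null.values(metric) if isinstance(null, NullDistribution) else np.asarray(
        null, dtype=float
    )
    if null_values.size == 0:
        raise InferenceError("null distribution is empty")
    exceed = int(np.sum(null_values >= optimal_mean))
    if smoothed:
        p = (exceed + 1) / (null_values.size + 1)
    else:
        p = exceed / null_values.size
    return SignificanceEntry(
        metric=metric,
        optimal_mean=optimal_mean,
        null_mean=float(np.mean(null_values)),
        null_sd=float(np.std(null_values, ddof=1)) if null_values.size > 1 else 0.0,
        p_value=float(p),
    )


def significance_report(
    optimal: EvaluationSummary,
    null: NullDistribution,
    metrics: Sequence[str] = METRIC_NAMES,
    smoothed: bool = False,
) -> SignificanceReport:
    return SignificanceReport(
        entries={m: compute_p(optimal, null, m, smoothed=smoothed) for m in metrics}
    )


def compute_fdci(
    acc_first: Sequence[float],
    acc_second: Sequence[float],
    paired: bool = False,
) -> ComparisonResult:
    """Fraction of comparisons where the first accuracy exceeds the second.

    Default compares all pairs (the normalized Mann-Whitney U statistic,
    ties at half weight), so FDCI(a,b) + FDCI(b,a) = 1. ``paired=True``
    compares iteration-by-iteration instead and requires equal lengths.
    """
    a = np.asarray(acc_first, dtype=float)
    b = np.asarray(acc_second, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InferenceError("accuracy vectors must be non-empty")
    if paired:
        if a.size != b.size:
            raise InferenceError("paired FDCI requires equal-length vectors")
        ties = int(np.sum(a == b))
        fdci = float(np.mean((a > b) + 0.5 * (a == b)))
    else:
        ranks = rankdata(np.concatenate([a, b]))
        u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
        fdci = float(u / (a.size * b.size))
        ties = int(np.sum(a[:, None] == b[None, :])) if a.size * b.size <= 10**6 else -1
    return ComparisonResult(
        fdci=fdci, n_first=int(a.size), n_second=int(b.size), ties=ties, paired=paired
    )
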
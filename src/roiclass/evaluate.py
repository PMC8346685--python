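"""Repeated nested-CV evaluation protocol.

Each iteration: (1) rebalance classes by undersampling and stratified-split
80/20, (2) run a 10-fold stratified grid search on the 80% portion with the
scaler fit inside each training fold, (3) keep the fold pipeline with the
highest validation accuracy, (4) score it on the untouched 20% with
confusion-matrix metrics plus rank-based AUC. The whole cycle repeats R
times with per-iteration seeds derived from one master seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .pipeline import (
    PipelineError,
    PipelineModel,
    apply_scaler,
    balance_indices,
    fit_scaler,
    train_svc,
    train_dlc,
    svc_grid,
    SVCConfig,
    DLCConfig,
)

METRIC_NAMES: tuple[str, ...] = ("ppv", "npv", "sen", "spc", "auc", "acc")

#: Full hyperparameter ranges searched for the dense network.
DLC_GRID_RANGES: dict[str, list] = {
    "learning_rate": [round(0.001 + 0.0005 * i, 10) for i in range(19)],  # 0.001..0.01
    "epochs": list(range(100, 801, 50)),
    "hidden1": list(range(5, 101, 5)),
    "hidden2": list(range(3, 21, 1)),
    "l2_penalty": [round(0.1 * i, 10) for i in range(1, 8)],  # 0.1..0.7
    "dropout_rate": [round(0.2 + 0.1 * i, 10) for i in range(4)],  # 0.2..0.5
}


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# grid specification


@dataclass(frozen=True)
class GridSpec:
    """Candidate hyperparameter sets for one model kind.

    ``mode="exhaustive"`` enumerates the full product of ``ranges``;
    ``mode="random_subsample"`` draws ``k`` distinct combinations (the
    desk-scale default for the dense network, whose full grid is ~3M
    combinations). Candidates are ordered by the tie-break key: ascending C
    for the SVC; (total hidden units, learning rate, remaining fields) for
    the network.
    """

    kind: str
    candidates: tuple[tuple, ...]  # sorted tuples of (name, value) pairs

    @staticmethod
    def for_svc(C_values: Sequence[float] | None = None) -> "GridSpec":
        values = sorted(C_values if C_values is not None else svc_grid())
        return GridSpec(kind="svc", candidates=tuple((("C", float(c)),) for c in values))

    @staticmethod
    def for_dlc(
        mode: str = "random_subsample",
        k: int = 60,
        seed: int = 0,
        ranges: dict | None = None,
    ) -> "GridSpec":
        ranges = dict(DLC_GRID_RANGES if ranges is None else ranges)
        keys = list(ranges)
        if mode == "exhaustive":
            combos = [dict(zip(keys, vals)) for vals in itertools.product(*ranges.values())]
        elif mode == "random_subsample":
            sizes = [len(ranges[k_]) for k_ in keys]
            total = int(np.prod(sizes))
            rng = np.random.default_rng(seed)
            flat = rng.choice(total, size=min(k, total), replace=False)
            combos = []
            for f in flat:
                combo = {}
                for key, size in zip(keys, sizes):
                    combo[key] = ranges[key][f % size]
                    f //= size
                combos.append(combo)
        else:
            raise EvaluationError(f"unknown grid mode {mode!r}")
        combos.sort(
            key=lambda c: (
                c["hidden1"] + c["hidden2"],
                c["learning_rate"],
                c["epochs"],
                c["l2_penalty"],
                c["dropout_rate"],
            )
        )
        return GridSpec(
            kind="dlc", candidates=tuple(tuple(sorted(c.items())) for c in combos)
        )

    @staticmethod
    def fixed(kind: str, hyperparams: dict) -> "GridSpec":
        """Single-candidate grid (used by the permutation-null protocol)."""
        clean = {k: v for k, v in hyperparams.items() if k != "seed"}
        return GridSpec(kind=kind, candidates=(tuple(sorted(clean.items())),))

    def as_dicts(self) -> list[dict]:
        return [dict(c) for c in self.candidates]


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    ppv: float
    npv: float
    sen: float
    spc: float
    auc: float
    acc: float

    def get(self, name: str) -> float:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with ties counted at half weight."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y_true == 1))
    n0 = y_true.size - n1
    if n1 == 0 or n0 == 0:
        raise EvaluationError("AUC requires both classes in the test set")
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def metric_set(cm: ConfusionMatrix, y_true: np.ndarray, scores: np.ndarray) -> MetricSet:
    return MetricSet(
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        sen=_ratio(cm.tp, cm.tp + cm.fn),
        spc=_ratio(cm.tn, cm.tn + cm.fp),
        auc=auc_score(y_true, scores),
        acc=_ratio(cm.tp + cm.tn, cm.total),
    )


# ---------------------------------------------------------------------------
# protocol steps


def stratified_split(
    labels: np.ndarray,
    test_fraction: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle rows, then split preserving class proportions within rounding.

    Returns (train_val_idx, test_idx): disjoint, exhaustive positional
    indices.
    """
    labels = np.asarray(labels)
    if not 0 < test_fraction < 1:
        raise EvaluationError("test_fraction must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(labels.size)
    test_parts, train_parts = [], []
    for cls in np.unique(labels):
        cls_idx = order[labels[order] == cls]
        if cls_idx.size < 5:
            raise EvaluationError(f"class {cls!r} has fewer than 5 members")
        n_test = int(round(test_fraction * cls_idx.size))
        n_test = min(max(n_test, 1), cls_idx.size - 1)
        test_parts.append(cls_idx[:n_test])
        train_parts.append(cls_idx[n_test:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def _train(kind: str, X: np.ndarray, y: np.ndarray, hyperparams: dict, seed: int):
    if kind == "svc":
        return train_svc(X, y, SVCConfig(**hyperparams))
    if kind == "dlc":
        return train_dlc(X, y, DLCConfig(**hyperparams, seed=seed))
    raise EvaluationError(f"unknown model kind {kind!r}")


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: GridSpec,
    k: int = 10,
    seed: int | np.random.Generator = 0,
    refit: bool = False,
) -> tuple[PipelineModel, dict, list[float]]:
    """Stratified k-fold grid search returning the best fold pipeline.

    Per fold, every candidate is trained on the k-1 training folds (scaler
    fit there too) and scored on the held-out fold; ties go to the earlier
    candidate in tie-break order. The fold pipeline with the highest
    validation accuracy overall is returned; ``refit=True`` retrains it on
    all of ``X`` with the winning hyperparameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < k:
        raise EvaluationError(f"smallest class ({counts.min()}) cannot fill {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))

    fold_accuracies: list[float] = []
    best: tuple[float, int] | None = None  # (val_acc, fold) with first-wins ties
    best_pipeline: PipelineModel | None = None
    best_params: dict | None = None

    for fold, (tr, va) in enumerate(skf.split(X, y)):
        scaler = fit_scaler(X[tr])
        Xtr, Xva = apply_scaler(scaler, X[tr]), apply_scaler(scaler, X[va])
        fold_best_acc = -1.0
        fold_best_model = None
        fold_best_params: dict = {}
        for cand in grid.as_dicts():
            model = _train(grid.kind, Xtr, y[tr], cand, seed=int(rng.integers(2**31)))
            acc = float(np.mean(model.predict(Xva) == y[va]))
            if acc > fold_best_acc:
                fold_best_acc = acc
                fold_best_model = model
                fold_best_params = cand
        fold_accuracies.append(fold_best_acc)
        if best is None or fold_best_acc > best[0]:
            best = (fold_best_acc, fold)
            best_pipeline = PipelineModel(
                scaler=scaler, classifier=fold_best_model, hyperparams=fold_best_params
            )
            best_params = fold_best_params

    assert best_pipeline is not None and best_params is not None
    if refit:
        scaler = fit_scaler(X)
        Xs = apply_scaler(scaler, X)
        model = _train(grid.kind, Xs, y, best_params, seed=int(rng.integers(2**31)))
        best_pipeline = PipelineModel(scaler=scaler, classifier=model, hyperparams=best_params)
    return best_pipeline, best_params, fold_accuracies


def evaluate_test(
    pipeline: PipelineModel, X_test: np.ndarray, y_test: np.ndarray
) -> tuple[ConfusionMatrix, MetricSet]:
    """Confusion matrix + six metrics of a trained pipeline on held-out rows."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if X_test.shape[0] == 0:
        raise EvaluationError("test set is empty")
    pred = pipeline.predict(X_test)
    scores = pipeline.decision_scores(X_test)
    cm = confusion_matrix(y_test, pred)
    return cm, metric_set(cm, y_test, scores)


# ---------------------------------------------------------------------------
# the repeated protocol


@dataclass
class EvaluationSummary:
    """Per-iteration metrics of the repeated protocol plus bookkeeping."""

    metrics: list[MetricSet]
    hyperparams: list[dict]
    confusions: list[ConfusionMatrix]
    R: int
    master_seed: int
    kind: str
    models: list[PipelineModel] = field(default_factory=list)

    def values(self, metric: str) -> np.ndarray:
        return np.array([m.get(metric) for m in self.metrics])

    def mean(self, metric: str) -> float:
        return float(np.mean(self.values(metric)))

    def sd(self, metric: str) -> float:
        return float(np.std(self.values(metric), ddof=1)) if self.R > 1 else 0.0

    def modal_hyperparams(self) -> dict:
        """Most frequently selected hyperparameter set (first on ties)."""
        keys = [tuple(sorted(h.items())) for h in self.hyperparams]
        order: dict[tuple, int] = {}
        counts: dict[tuple, int] = {}
        for i, k in enumerate(keys):
            counts[k] = counts.get(k, 0) + 1
            order.setdefault(k, i)
        best = max(counts, key=lambda k: (counts[k], -order[k]))
        return dict(best)

    def summary_dict(self) -> dict:
        return {
            "kind": self.kind,
            "R": self.R,
            "master_seed": self.master_seed,
            "metrics": {
                m: {"mean": self.mean(m), "sd": self.sd(m)} for m in METRIC_NAMES
            },
            "modal_hyperparams": self.modal_hyperparams(),
        }


def iteration_seeds(master_seed: int, R: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(R)


def run_repeated_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    grid: GridSpec,
    R: int = 1000,
    master_seed: int = 0,
    k: int = 10,
    test_fraction: float = 0.2,
    balance: bool = True,
    refit: bool = False,
    keep_models: bool = False,
    preprocess: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None,
    log: Callable[[str], None] | None = None,
) -> EvaluationSummary:
    """Run the four-step protocol R times with derived per-iteration seeds.

    ``preprocess(balanced_idx, train_idx, test_idx)`` hooks in split-aware
    transforms (e.g. leakage-free harmonization refit on the 80% portion of
    every iteration); it must return the replacement feature matrix for the
    balanced rows, ``balanced_idx`` indexing the original ``X`` and the split
    indices indexing that balanced subset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    metrics: list[MetricSet] = []
    hyperparams: list[dict] = []
    confusions: list[ConfusionMatrix] = []
    models: list[PipelineModel] = []

    for r, ss in enumerate(iteration_seeds(master_seed, R)):
        rng = np.random.default_rng(ss)
        idx = balance_indices(y, rng) if balance else np.arange(y.size)
        Xb, yb = X[idx], y[idx]
        tr, te = stratified_split(yb, test_fraction, rng)
        if np.intersect1d(tr, te).size:
            raise EvaluationError("train/test partitions overlap")  # pragma: no cover
        if preprocess is not None:
            Xb = np.asarray(preprocess(idx, tr, te), dtype=float)
        pipe, params, _ = grid_search_cv(Xb[tr], yb[tr], grid, k=k, seed=rng, refit=refit)
        cm, ms = evaluate_test(pipe, Xb[te], yb[te])
        metrics.append(ms)
        hyperparams.append(params)
        confusions.append(cm)
        if keep_models:
            models.append(pipe)
        if log is not None:
            log(f"iteration {r}: params={params} acc={ms.acc:.3f}")

    return EvaluationSummary(
        metrics=metrics,
        hyperparams=hyperparams,
        confusions=confusions,
        R=R,
        master_seed=master_seed,
        kind=grid.kind,
        models=models,
    )
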
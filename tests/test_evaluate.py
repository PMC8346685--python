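import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from roiclass.evaluate import (
    DLC_GRID_RANGES,
    ConfusionMatrix,
    EvaluationError,
    GridSpec,
    auc_score,
    confusion_matrix,
    evaluate_test,
    grid_search_cv,
    metric_set,
    run_repeated_evaluation,
    stratified_split,
)
from roiclass.pipeline import train_pipeline


def signal_data(n_per_class=60, n_features=6, d=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    X[y == 1, :2] += d
    return X, y


class TestStratifiedSplit:
    def test_balanced_200_gives_exact_80_20(self):
        y = np.array([0] * 100 + [1] * 100)
        tr, te = stratified_split(y, 0.2, seed=0)
        assert len(te) == 40 and len(tr) == 160
        assert np.sum(y[te] == 0) == 20 and np.sum(y[te] == 1) == 20

    def test_same_seed_identical_partition(self):
        y = np.array([0] * 50 + [1] * 50)
        a = stratified_split(y, 0.2, seed=3)
        b = stratified_split(y, 0.2, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_unbalanced_proportions_within_one_subject(self):
        y = np.array([0] * 60 + [1] * 40)
        tr, te = stratified_split(y, 0.2, seed=1)
        assert abs(np.sum(y[te] == 0) - 12) <= 1
        assert abs(np.sum(y[te] == 1) - 8) <= 1

    def test_partition_disjoint_and_exhaustive(self):
        y = np.array([0] * 37 + [1] * 23)
        tr, te = stratified_split(y, 0.2, seed=5)
        assert np.intersect1d(tr, te).size == 0
        assert sorted(np.r_[tr, te]) == list(range(60))

    def test_small_class_rejected(self):
        y = np.array([0] * 50 + [1] * 3)
        with pytest.raises(EvaluationError, match="fewer than 5"):
            stratified_split(y, 0.2, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(EvaluationError):
            stratified_split(np.array([0, 1] * 10), 1.5, seed=0)

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_disjoint_exhaustive_property(self, seed):
        rng = np.random.default_rng(seed)
        n0, n1 = rng.integers(6, 60, 2)
        y = rng.permutation(np.r_[np.zeros(n0, int), np.ones(n1, int)])
        tr, te = stratified_split(y, 0.2, seed=rng)
        assert np.intersect1d(tr, te).size == 0
        assert len(tr) + len(te) == n0 + n1


class TestGridSpec:
    def test_default_svc_grid_has_39_candidates(self):
        assert len(GridSpec.for_svc().candidates) == 39

    def test_dlc_ranges_match_stated_bounds(self):
        r = DLC_GRID_RANGES
        assert r["learning_rate"][0] == 0.001 and r["learning_rate"][-1] == 0.01
        assert r["epochs"][0] == 100 and r["epochs"][-1] == 800
        assert r["hidden1"][0] == 5 and r["hidden1"][-1] == 100
        assert r["hidden2"][0] == 3 and r["hidden2"][-1] == 20
        assert r["l2_penalty"][0] == pytest.approx(0.1)
        assert r["l2_penalty"][-1] == pytest.approx(0.7)
        assert r["dropout_rate"] == [0.2, 0.3, 0.4, 0.5]

    def test_full_dlc_grid_size(self):
        sizes = [len(v) for v in DLC_GRID_RANGES.values()]
        assert int(np.prod(sizes)) == 19 * 15 * 20 * 18 * 7 * 4

    def test_random_subsample_within_ranges(self):
        spec = GridSpec.for_dlc(mode="random_subsample", k=40, seed=1)
        assert len(spec.candidates) == 40
        for cand in spec.as_dicts():
            for key, value in cand.items():
                assert value in DLC_GRID_RANGES[key]

    def test_random_subsample_distinct_and_seeded(self):
        a = GridSpec.for_dlc(k=30, seed=5)
        b = GridSpec.for_dlc(k=30, seed=5)
        assert a.candidates == b.candidates
        assert len(set(a.candidates)) == 30

    def test_exhaustive_small_ranges(self):
        ranges = {
            "learning_rate": [0.005],
            "epochs": [100, 200],
            "hidden1": [5, 10],
            "hidden2": [3],
            "l2_penalty": [0.1],
            "dropout_rate": [0.2],
        }
        spec = GridSpec.for_dlc(mode="exhaustive", ranges=ranges)
        assert len(spec.candidates) == 4

    def test_fixed_strips_seed(self):
        spec = GridSpec.fixed("dlc", {"epochs": 100, "seed": 99})
        assert dict(spec.candidates[0]) == {"epochs": 100}


class TestMetrics:
    def test_closed_form_counts(self):
        cm = ConfusionMatrix(tp=8, fp=2, fn=2, tn=8)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        scores = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
        ms = metric_set(cm, y, scores)
        assert ms.acc == ms.sen == ms.spc == ms.ppv == ms.npv == pytest.approx(0.8)

    def test_perfect_ranking_auc_one(self):
        y = np.array([0, 0, 1, 1])
        assert auc_score(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_all_tied_scores_auc_half(self):
        y = np.array([0, 1, 0, 1])
        assert auc_score(y, np.zeros(4)) == 0.5

    def test_degenerate_ratios_are_zero(self):
        cm = ConfusionMatrix(tp=0, fp=0, fn=5, tn=5)
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        ms = metric_set(cm, y, np.linspace(0, 1, 10))
        assert ms.ppv == 0.0 and ms.sen == 0.0

    def test_confusion_matrix_from_predictions(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 0, 1, 1])
        cm = confusion_matrix(y, p)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 1)
        assert cm.total == 5

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)

    def test_single_class_auc_rejected(self):
        with pytest.raises(EvaluationError):
            auc_score(np.ones(4, int), np.linspace(0, 1, 4))

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_auc_matches_sklearn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        scores = rng.integers(0, 5, 2 * n).astype(float)  # forces ties
        assert auc_score(y, scores) == pytest.approx(roc_auc_score(y, scores))


class TestGridSearchCV:
    def test_single_candidate_returned(self):
        X, y = signal_data()
        pipe, params, fold_accs = grid_search_cv(X, y, GridSpec.for_svc([0.7]), k=5, seed=0)
        assert params == {"C": 0.7}
        assert len(fold_accs) == 5
        assert pipe.kind == "svc"

    def test_strong_signal_high_validation_accuracy(self):
        X, y = signal_data(d=2.0)
        _, _, fold_accs = grid_search_cv(
            X, y, GridSpec.for_svc([0.1, 1.0, 2.0]), k=10, seed=0
        )
        assert max(fold_accs) >= 0.85

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degenerate_candidate_never_selected(self, seed):
        # at C=1e-9 the SVC collapses to a class-mean-difference rule, which
        # correlated noise defeats; the properly regularized candidate must
        # win every fold
        rng = np.random.default_rng(seed)
        n = 100
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        noise = rng.normal(0, 1.0, 2 * n)
        signal = 1.0 * y + rng.normal(0, 0.15, 2 * n)
        X = np.column_stack([signal + noise, noise])
        _, params, _ = grid_search_cv(X, y, GridSpec.for_svc([1e-9, 1.0]), k=10, seed=seed)
        assert params == {"C": 1.0}

    def test_ties_break_to_smaller_C(self):
        X, y = signal_data(d=5.0)  # everything separates perfectly
        _, params, _ = grid_search_cv(X, y, GridSpec.for_svc([0.5, 1.0, 2.0]), k=5, seed=0)
        assert params == {"C": 0.5}

    def test_k_larger_than_class_rejected(self):
        X, y = signal_data(n_per_class=8)
        with pytest.raises(EvaluationError):
            grid_search_cv(X, y, GridSpec.for_svc([1.0]), k=10, seed=0)

    def test_refit_uses_full_split(self):
        X, y = signal_data()
        pipe, _, _ = grid_search_cv(X, y, GridSpec.for_svc([1.0]), k=5, seed=0, refit=True)
        # refit scaler saw all rows of X
        assert np.allclose(pipe.scaler.minimum, X.min(axis=0))

    def test_dlc_grid_search_runs(self):
        X, y = signal_data(n_per_class=30, d=3.0)
        ranges = {
            "learning_rate": [0.01],
            "epochs": [100],
            "hidden1": [5, 10],
            "hidden2": [3],
            "l2_penalty": [0.1],
            "dropout_rate": [0.2],
        }
        pipe, params, _ = grid_search_cv(
            X, y, GridSpec.for_dlc(mode="exhaustive", ranges=ranges), k=5, seed=0
        )
        assert pipe.kind == "dlc"
        assert params["hidden1"] in (5, 10)


class TestEvaluateTest:
    def test_metrics_on_separable_data(self, separable_data):
        X, y = separable_data
        pipe = train_pipeline(X, y, "svc", {"C": 1.0})
        cm, ms = evaluate_test(pipe, X, y)
        assert ms.acc == 1.0 and ms.auc == 1.0
        assert cm.total == len(y)

    def test_empty_test_set_rejected(self, separable_data):
        X, y = separable_data
        pipe = train_pipeline(X, y, "svc", {"C": 1.0})
        with pytest.raises(EvaluationError):
            evaluate_test(pipe, np.empty((0, 2)), np.empty(0, dtype=int))


class TestRepeatedEvaluation:
    def test_reproducible_from_master_seed(self):
        X, y = signal_data(n_per_class=40)
        grid = GridSpec.for_svc([0.5, 1.0])
        a = run_repeated_evaluation(X, y, grid, R=2, master_seed=7)
        b = run_repeated_evaluation(X, y, grid, R=2, master_seed=7)
        assert [m.as_dict() for m in a.metrics] == [m.as_dict() for m in b.metrics]
        assert a.hyperparams == b.hyperparams

    def test_summary_mean_sd_recompute(self):
        X, y = signal_data(n_per_class=40)
        summary = run_repeated_evaluation(X, y, GridSpec.for_svc([1.0]), R=4, master_seed=1)
        accs = summary.values("acc")
        assert summary.mean("acc") == pytest.approx(np.mean(accs), abs=1e-12)
        assert summary.sd("acc") == pytest.approx(np.std(accs, ddof=1), abs=1e-12)
        assert summary.R == len(summary.metrics) == 4

    def test_chance_level_on_null_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 5))
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        summary = run_repeated_evaluation(X, y, GridSpec.for_svc([1.0]), R=20, master_seed=2)
        assert abs(summary.mean("acc") - 0.5) < 0.12

    def test_coin_flip_labels_near_chance(self):
        X, _ = signal_data(n_per_class=60, d=2.0, seed=4)
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, len(X))
        summary = run_repeated_evaluation(X, y, GridSpec.for_svc([1.0]), R=15, master_seed=3)
        assert abs(summary.mean("acc") - 0.5) < 0.12

    def test_imbalance_correction_rebalances_each_iteration(self):
        X, y = signal_data(n_per_class=50)
        X, y = np.vstack([X, X[y == 0]]), np.r_[y, np.zeros(50, int)]  # 100 vs 50
        summary = run_repeated_evaluation(X, y, GridSpec.for_svc([1.0]), R=2, master_seed=0)
        for cm in summary.confusions:
            assert cm.tp + cm.fn == cm.tn + cm.fp  # balanced test split

    def test_modal_hyperparams(self):
        X, y = signal_data()
        summary = run_repeated_evaluation(
            X, y, GridSpec.for_svc([0.5, 1.0]), R=3, master_seed=5
        )
        assert summary.modal_hyperparams() in ({"C": 0.5}, {"C": 1.0})

    def test_keep_models(self):
        X, y = signal_data(n_per_class=30)
        summary = run_repeated_evaluation(
            X, y, GridSpec.for_svc([1.0]), R=2, master_seed=6, keep_models=True
        )
        assert len(summary.models) == 2

    def test_preprocess_hook_receives_indices(self):
        X, y = signal_data(n_per_class=30)
        calls = []

        def hook(idx, tr, te):
            calls.append((len(idx), len(tr), len(te)))
            assert np.intersect1d(tr, te).size == 0
            return X[idx]

        run_repeated_evaluation(
            X, y, GridSpec.for_svc([1.0]), R=2, master_seed=0, preprocess=hook
        )
        assert len(calls) == 2
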
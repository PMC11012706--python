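import numpy as np
import pytest

from profwise import (
    ConfusionCounts,
    ExpressionMatrix,
    ModelConfig,
    TargetVector,
    accuracy,
    alteration_analysis,
    evaluate_subset,
    make_folds,
    mean_squared_error,
)


class TestAccuracy:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,expected",
        [
            (27, 0, 38, 0, 1.0),
            (1, 1, 1, 1, 0.5),
            (0, 2, 0, 3, 0.0),
            (3, 1, 4, 2, 0.7),
            (10, 5, 30, 5, 0.8),
            (1, 0, 0, 0, 1.0),
            (0, 1, 0, 0, 0.0),
            (5, 5, 5, 5, 0.5),
            (60, 10, 20, 10, 0.8),
            (13, 2, 52, 33, 0.65),
        ],
    )
    def test_hand_computed(self, tp, fp, tn, fn, expected):
        assert accuracy(ConfusionCounts(tp, fp, tn, fn)) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 1, 0)


class TestMeanSquaredError:
    @pytest.mark.parametrize(
        "actual,predicted,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([0, 0], [1, 1], 1.0),
            ([1, 2, 3], [2, 2, 2], 2 / 3),
            ([5], [3], 4.0),
            ([1, 1, 1, 1], [0, 2, 0, 2], 1.0),
            ([0.5, -0.5], [0, 0], 0.25),
            ([10, 20], [10, 26], 18.0),
            ([-1, -2, -3], [-1, -2, -4], 1 / 3),
            ([2, 4, 6, 8], [1, 3, 5, 7], 1.0),
            ([0, 3], [4, 0], 12.5),
        ],
    )
    def test_hand_computed(self, actual, predicted, expected):
        assert mean_squared_error(actual, predicted) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mean_squared_error([1, 2], [1])

    def test_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        assert mean_squared_error(a, a) == 0.0
        assert mean_squared_error(a, a + 1e-6) > 0


class TestMakeFolds:
    def _binary(self, n_pos, n_neg):
        labels = np.array(["methylated"] * n_pos + ["unmethylated"] * n_neg)
        return TargetVector("binary", labels)

    def test_27_38_stratification(self):
        target = self._binary(27, 38)
        plan = make_folds(target, 5, seed=0)
        codes = target.binary_codes()
        for fold in range(5):
            test = plan.test_indices(fold)
            pos = int((codes[test] == 1).sum())
            neg = int((codes[test] == 0).sum())
            assert pos in (5, 6)
            assert neg in (7, 8)

    @pytest.mark.parametrize("n_pos,n_neg", [(10, 50), (23, 41), (38, 52)])
    def test_per_fold_deviation_at_most_one(self, n_pos, n_neg):
        target = self._binary(n_pos, n_neg)
        plan = make_folds(target, 5, seed=3)
        codes = target.binary_codes()
        n = n_pos + n_neg
        for fold in range(5):
            test = plan.test_indices(fold)
            share = len(test) / n
            for cls, total in ((1, n_pos), (0, n_neg)):
                got = int((codes[test] == cls).sum())
                assert abs(got - share * total) <= 1

    def test_partition_and_determinism(self):
        target = self._binary(27, 38)
        a = make_folds(target, 5, seed=0)
        b = make_folds(target, 5, seed=0)
        assert np.array_equal(a.assignments, b.assignments)
        all_test = np.concatenate([a.test_indices(f) for f in range(5)])
        assert sorted(all_test) == list(range(65))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            make_folds(self._binary(3, 40), 5)

    def test_continuous_plain_folds(self):
        target = TargetVector("continuous", np.arange(20.0))
        plan = make_folds(target, 5, seed=0)
        assert not plan.stratified
        assert sorted(np.concatenate(
            [plan.test_indices(f) for f in range(5)])) == list(range(20))

    def test_continuous_with_status_stratifies(self):
        target = TargetVector("continuous", np.arange(30.0))
        status = np.array([0] * 10 + [1] * 20)
        plan = make_folds(target, 5, seed=0, stratify_labels=status)
        assert plan.stratified
        for fold in range(5):
            test = plan.test_indices(fold)
            assert (status[test] == 0).sum() == 2
            assert (status[test] == 1).sum() == 4


def _matrix_for_eval(rng, n, p, planted_shift=None, codes=None):
    values = rng.normal(size=(n, p))
    if planted_shift is not None:
        values[:, 0] += planted_shift * codes
    return ExpressionMatrix(
        [f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)], values
    )


class TestEvaluateSubset:
    def test_constant_predictor_majority_rate(self):
        # with a single constant feature every classifier must fall back to a
        # constant prediction; per-fold ACC is then the rate of the predicted
        # class in that fold, which for a majority learner is the majority rate
        rng = np.random.default_rng(4)
        n = 40
        codes = np.array([1] * 10 + [0] * 30)
        m = ExpressionMatrix(
            [f"s{i}" for i in range(n)], ["flat"], np.ones((n, 1))
        )
        target = TargetVector(
            "binary", np.where(codes == 1, "methylated", "unmethylated")
        )
        plan = make_folds(target, 5, seed=0)
        models = ModelConfig(task="classification")
        scores = evaluate_subset(m, target, ["flat"], models, plan)
        expected = []
        for fold in range(5):
            test = plan.test_indices(fold)
            expected.append((codes[test] == 0).mean())  # majority = negative
        for name in ("LR", "RF", "AdaBoost", "SVM"):
            assert scores[name] == pytest.approx(np.mean(expected))

    def test_perfect_separation_gives_acc_one(self):
        rng = np.random.default_rng(5)
        n = 60
        codes = np.array([1, 0] * 30)
        m = _matrix_for_eval(rng, n, 5, planted_shift=10.0, codes=codes)
        target = TargetVector(
            "binary", np.where(codes == 1, "methylated", "unmethylated")
        )
        plan = make_folds(target, 5, seed=0)
        scores = evaluate_subset(
            m, target, ["f0"], ModelConfig(task="classification"), plan
        )
        assert scores["LR"] == 1.0
        assert scores["SVM"] == 1.0

    def test_deterministic_and_order_invariant(self, small_classification):
        matrix, target, _ = small_classification
        plan = make_folds(target, 5, seed=0)
        models = ModelConfig(task="classification")
        subset = matrix.feature_ids[:8]
        a = evaluate_subset(matrix, target, subset, models, plan)
        b = evaluate_subset(matrix, target, list(reversed(subset)), models, plan)
        assert a == b

    def test_empty_subset_rejected(self, small_classification):
        matrix, target, _ = small_classification
        plan = make_folds(target, 5, seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate_subset(matrix, target, [],
                            ModelConfig(task="classification"), plan)

    def test_mean_of_folds_equals_pooled_for_equal_folds(self):
        # 50 samples, 5 folds of exactly 10 -> mean of fold ACCs == pooled ACC
        rng = np.random.default_rng(6)
        n = 50
        codes = np.array([1, 0] * 25)
        m = _matrix_for_eval(rng, n, 3, planted_shift=1.0, codes=codes)
        target = TargetVector(
            "binary", np.where(codes == 1, "methylated", "unmethylated")
        )
        plan = make_folds(target, 5, seed=1)
        models = ModelConfig(task="classification")
        means, folds = evaluate_subset(m, target, ["f0"], models, plan,
                                       per_fold=True)
        for name, fold_scores in folds.items():
            sizes = [len(plan.test_indices(f)) for f in range(5)]
            assert sizes == [10] * 5
            pooled = sum(s * 10 for s in fold_scores) / 50
            assert means[name] == pytest.approx(pooled)

    def test_regression_models_report_mse(self, small_regression):
        matrix, target, _ = small_regression
        plan = make_folds(target, 5, seed=0)
        scores = evaluate_subset(matrix, target, matrix.feature_ids[:5],
                                 ModelConfig(task="regression"), plan)
        assert set(scores) == {"SVR", "RF"}
        assert all(v >= 0 for v in scores.values())


class TestAlterationAnalysis:
    def _setup(self):
        rng = np.random.default_rng(7)
        n = 30
        codes = np.array([1] * 15 + [0] * 15)
        m = _matrix_for_eval(rng, n, 4, planted_shift=1.0, codes=codes)
        target = TargetVector(
            "binary", np.where(codes == 1, "methylated", "unmethylated")
        )
        return m, target, codes

    def test_diff_and_flagging(self):
        m, target, codes = self._setup()
        table = alteration_analysis(m, target, band=0.3)
        row = table[table.feature_id == "f0"].iloc[0]
        expected = m.values[codes == 1, 0].mean() - m.values[codes == 0, 0].mean()
        assert row["diff"] == pytest.approx(expected)
        assert bool(row["flagged"]) == (abs(expected) > 0.3)
        assert table.iloc[0]["rank"] == 1
        assert (table["diff"].abs().diff().dropna() <= 1e-12).all()

    def test_identical_class_means_not_flagged(self):
        m = ExpressionMatrix(
            ["s1", "s2", "s3", "s4"], ["fA"],
            np.array([[1.0], [2.0], [1.0], [2.0]]),
        )
        target = TargetVector(
            "binary",
            np.array(["methylated", "methylated", "unmethylated", "unmethylated"]),
        )
        table = alteration_analysis(m, target)
        assert table.iloc[0]["diff"] == 0.0
        assert not table.iloc[0]["flagged"]

    def test_swapping_convention_negates_diff(self):
        m, target, _ = self._setup()
        a = alteration_analysis(m, target)
        flipped = TargetVector("binary", target.values,
                               positive_label="unmethylated")
        b = alteration_analysis(m, flipped)
        merged = a.set_index("feature_id")["diff"]
        merged_b = b.set_index("feature_id")["diff"]
        assert np.allclose(merged, -merged_b[merged.index])

    def test_requires_both_classes(self):
        m, target, _ = self._setup()
        with pytest.raises(ValueError):
            alteration_analysis(m, TargetVector("continuous", np.arange(30.0)))
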
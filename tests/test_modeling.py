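"""Cohort splitting, ROC/AUC, evaluation metrics, fusion and correlation."""

import numpy as np
import pandas as pd
import pytest

from vasarad.modeling import (
    ModelConfig,
    augment_with_clinical,
    evaluate,
    feature_correlation,
    fuse_probabilities,
    predict_probability,
    roc_auc,
    split_cohort,
    sweep_model_order,
    train_model,
    _metrics_at_threshold,
)
from vasarad.types import FeatureTable


def make_table(columns, labels):
    ids = [f"s{i}" for i in range(len(labels))]
    data = pd.DataFrame(columns, index=ids, dtype=float)
    return FeatureTable(data, pd.Series(labels, index=ids))


def study_cohort_labels():
    labels = {}
    for i in range(50):
        labels[f"m{i}"] = "mutant"
    for i in range(52):
        labels[f"w{i}"] = "wildtype"
    return labels


class TestSplit:
    def test_102_subjects_at_67_fraction_split_67_35(self):
        labels = study_cohort_labels()
        split = split_cohort(list(labels), labels, 67 / 102, seed=0)
        assert len(split.train_ids) == 67
        assert len(split.validation_ids) == 35
        train_mut = sum(labels[i] == "mutant" for i in split.train_ids)
        assert train_mut == 33  # stratified: 33/34 train, 17/18 validation

    def test_degenerate_fraction_rejected(self):
        labels = study_cohort_labels()
        with pytest.raises(ValueError):
            split_cohort(list(labels), labels, 1.0)

    def test_same_seed_same_split(self):
        labels = study_cohort_labels()
        a = split_cohort(list(labels), labels, 0.7, seed=3)
        b = split_cohort(list(labels), labels, 0.7, seed=3)
        assert a.train_ids == b.train_ids and a.validation_ids == b.validation_ids

    def test_both_classes_on_both_sides(self):
        labels = {"a": "mutant", "b": "mutant", "c": "wildtype", "d": "wildtype"}
        split = split_cohort(list(labels), labels, 0.5, seed=0)
        for side in (split.train_ids, split.validation_ids):
            assert {labels[i] for i in side} == {"mutant", "wildtype"}


class TestRocAuc:
    def test_perfect_separation(self):
        auc = roc_auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]).auc
        assert auc == 1.0

    def test_three_of_four_pairs_correct_gives_075(self):
        auc = roc_auc([0.9, 0.3, 0.5, 0.2], [1, 1, 0, 0]).auc
        assert auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = rng.choice([0.1, 0.2, 0.5, 0.7], size=30)  # with ties
            assert roc_auc(s, y).auc == pytest.approx(roc_auc_score(y, s))

    def test_curve_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        roc = roc_auc(s, y)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 40)
        s = rng.random(40)
        assert roc_auc(np.exp(3 * s), y).auc == pytest.approx(roc_auc(s, y).auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestTrainPredict:
    def test_separable_feature_memorized(self):
        y = [0] * 10 + [1] * 10
        labels = [["mutant", "wildtype"][v] for v in y]
        table = make_table({"f": [float(v) for v in y]}, labels)
        model = train_model(table, ["f"], ModelConfig(n_trees=25, seed=0))
        scores = predict_probability(model, table)
        assert roc_auc(scores.to_numpy(), np.array(y)).auc == 1.0
        assert scores.between(0, 1).all()

    def test_refit_same_seed_identical_predictions(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 30)
        table = make_table(
            {"f": rng.normal(size=30) + y}, [["mutant", "wildtype"][v] for v in y]
        )
        cfg = ModelConfig(n_trees=30, seed=9)
        p1 = predict_probability(train_model(table, ["f"], cfg), table)
        p2 = predict_probability(train_model(table, ["f"], cfg), table)
        pd.testing.assert_series_equal(p1, p2)

    def test_unknown_feature_rejected(self):
        table = make_table({"f": [0.0, 1.0, 0.0, 1.0]}, ["mutant", "wildtype"] * 2)
        with pytest.raises(KeyError):
            train_model(table, ["g"])

    def test_single_feature_model_monotone_on_grid(self):
        # a forest fit on a monotone feature has nondecreasing probabilities
        y = np.array([0] * 15 + [1] * 15)
        x = np.concatenate([np.linspace(0, 0.45, 15), np.linspace(0.55, 1.0, 15)])
        table = make_table({"f": x}, [["mutant", "wildtype"][v] for v in y])
        model = train_model(table, ["f"], ModelConfig(n_trees=50, seed=0))
        grid = make_table({"f": np.linspace(0, 1, 21)}, ["mutant"] * 21)
        p = predict_probability(model, grid).to_numpy()
        assert np.all(np.diff(p) >= -1e-12)


class TestEvaluate:
    def test_perfect_scores_give_unit_metrics(self):
        s, p, a = _metrics_at_threshold(
            np.array([1.0, 1.0, 0.0, 0.0]), np.array([1, 1, 0, 0]), 0.5
        )
        assert (s, p, a) == (1.0, 1.0, 1.0)

    def test_all_half_probabilities_predict_positive_under_ge_rule(self):
        y = np.array([1, 1, 0, 0, 0])
        s, p, a = _metrics_at_threshold(np.full(5, 0.5), y, 0.5)
        assert s == 1.0 and p == 0.0 and a == pytest.approx(2 / 5)

    def test_hand_confusion_counts(self):
        y = np.concatenate([np.ones(40), np.zeros(39)]).astype(int)
        scores = np.concatenate(
            [np.ones(29), np.zeros(11), np.zeros(30), np.ones(9)]
        )
        s, p, a = _metrics_at_threshold(scores, y, 0.5)
        assert s == pytest.approx(29 / 40, abs=1e-9)
        assert p == pytest.approx(30 / 39, abs=1e-9)
        assert a == pytest.approx(59 / 79, abs=1e-9)

    def test_report_means_and_sds_over_repeats(self):
        rng = np.random.default_rng(6)
        y = np.array([0, 1] * 15)
        table = make_table(
            {"f": y + rng.normal(0, 0.4, 30)}, [["mutant", "wildtype"][v] for v in y]
        )
        report = evaluate(table, table, ["f"], ModelConfig(n_trees=20, n_repeats=4))
        for v in (report.auc, report.sensitivity, report.specificity, report.accuracy):
            assert 0 <= v <= 1
        assert report.n_repeats == 4
        assert report.auc_sd >= 0


class TestSweep:
    def test_single_feature_selection_returns_order_one(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 30)
        table = make_table(
            {"f": y + rng.normal(0, 0.3, 30)}, [["mutant", "wildtype"][v] for v in y]
        )
        sweep = sweep_model_order(["f"], table, ModelConfig(n_trees=10),
                                  n_replicates=10, seed=0)
        assert sweep.optimal_order == 1 and sweep.orders == [1]

    def test_orders_contiguous_and_optimal_maximizes(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 40)
        cols = {f"f{i}": y + rng.normal(0, 0.5 + i, 40) for i in range(4)}
        table = make_table(cols, [["mutant", "wildtype"][v] for v in y])
        sweep = sweep_model_order(
            [f"f{i}" for i in range(4)], table, ModelConfig(n_trees=10),
            n_replicates=10, seed=0,
        )
        assert sweep.orders == [1, 2, 3, 4]
        aucs = [e.combined for e in sweep.estimates]
        assert sweep.optimal_auc == max(aucs)
        assert aucs.index(max(aucs)) + 1 == sweep.optimal_order


class TestFusion:
    def test_weighted_mean_arithmetic(self):
        assert fuse_probabilities(0.6, 0.8, 0.5) == pytest.approx(0.7)

    def test_degenerate_weights_reproduce_single_model(self):
        p_v = np.array([0.2, 0.9])
        p_r = np.array([0.6, 0.1])
        np.testing.assert_array_equal(fuse_probabilities(p_v, p_r, 1.0), p_v)
        np.testing.assert_array_equal(fuse_probabilities(p_v, p_r, 0.0), p_r)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            fuse_probabilities(np.array([1.2]), np.array([0.5]), 0.5)
        with pytest.raises(ValueError):
            fuse_probabilities(np.array([0.5]), np.array([0.5]), 1.5)

    def test_fused_auc_continuous_in_weight(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 60)
        p_v = np.clip(y * 0.4 + rng.random(60) * 0.6, 0, 1)
        p_r = np.clip(y * 0.4 + rng.random(60) * 0.6, 0, 1)
        aucs = [
            roc_auc(fuse_probabilities(p_v, p_r, w), y).auc
            for w in np.linspace(0, 1, 21)
        ]
        assert max(abs(np.diff(aucs))) < 0.12  # no jumps beyond one pair swap scale


class TestCorrelation:
    def _tables(self, cols_v, cols_r, n):
        labels = ["mutant", "wildtype"] * (n // 2)
        return make_table(cols_v, labels), make_table(cols_r, labels)

    def test_identical_columns_correlate_perfectly(self):
        x = np.random.default_rng(0).normal(size=20)
        tv, tr = self._tables({"v": x}, {"r": x.copy()}, 20)
        corr = feature_correlation(tv, tr)
        assert corr.loc["v", "r"] == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        x = np.random.default_rng(1).normal(size=20)
        tv, tr = self._tables({"v": x}, {"r": -x}, 20)
        assert feature_correlation(tv, tr).loc["v", "r"] == pytest.approx(-1.0)

    def test_independent_columns_mostly_uncorrelated(self):
        rng = np.random.default_rng(2)
        tv, tr = self._tables(
            {f"v{i}": rng.normal(size=100) for i in range(5)},
            {f"r{i}": rng.normal(size=100) for i in range(8)},
            100,
        )
        corr = feature_correlation(tv, tr).to_numpy()
        assert (np.abs(corr) < 0.3).mean() >= 0.95

    def test_constant_column_flagged_as_degenerate_zero(self):
        x = np.random.default_rng(3).normal(size=20)
        tv, tr = self._tables({"v": np.ones(20)}, {"r": x}, 20)
        corr = feature_correlation(tv, tr)
        assert corr.loc["v", "r"] == 0.0
        assert ("v", "r") in corr.attrs["degenerate"]

    def test_subject_mismatch_rejected(self):
        x = np.random.default_rng(4).normal(size=20)
        tv, tr = self._tables({"v": x}, {"r": x}, 20)
        tr_swapped = tr.subset(list(reversed(tr.subject_ids)))
        with pytest.raises(ValueError):
            feature_correlation(tv, tr_swapped)


class TestClinical:
    def test_append_then_drop_round_trip(self):
        table = make_table({"f": [0.1, 0.9, 0.4, 0.6]}, ["mutant", "wildtype"] * 2)
        age = pd.Series([40.0, 50, 60, 70], index=table.data.index)
        gender = pd.Series(["male", "female", "male", "female"], index=table.data.index)
        augmented = augment_with_clinical(table, age, gender)
        assert list(augmented.data.columns) == ["f", "age", "gender"]
        assert augmented.data["age"].between(0, 1).all()
        pd.testing.assert_frame_equal(augmented.data.drop(columns=["age", "gender"]),
                                      table.data)

    def test_constant_age_flagged_degenerate(self):
        table = make_table({"f": [0.1, 0.9]}, ["mutant", "wildtype"])
        age = pd.Series([50.0, 50.0], index=table.data.index)
        gender = pd.Series(["male", "female"], index=table.data.index)
        augmented = augment_with_clinical(table, age, gender)
        assert (augmented.data["age"] == 0).all()
        assert "age" in augmented.degenerate

    def test_missing_covariate_rejected(self):
        table = make_table({"f": [0.1, 0.9]}, ["mutant", "wildtype"])
        age = pd.Series([50.0], index=[table.data.index[0]])
        gender = pd.Series(["male", "female"], index=table.data.index)
        with pytest.raises(ValueError):
            augment_with_clinical(table, age, gender)
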
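"""Evaluation harness: directed AUC, classifiers, Wilcoxon, design operators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import parenclitic as pc
from parenclitic.errors import InvalidLabelsError, SchemaError
from parenclitic.evaluation import REAL_DATASET_SHELLS, small_p_dataset_names
from parenclitic.table import FeatureTable


class TestDirectedAuc:
    def test_perfect_separation(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        scores = labels.astype(float)
        res = pc.directed_auc(scores, labels, scores, labels)
        assert res.auc_train == 1.0 and res.auc_test == 1.0
        assert res.direction == "controls_lt_cases"

    def test_direction_locked_on_train(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        scores = labels.astype(float)
        res = pc.directed_auc(scores, labels, 1 - scores, labels)
        assert res.auc_train == 1.0
        assert res.auc_test == 0.0  # TEST reversed, direction not re-chosen

    def test_flip_when_controls_score_high(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        res = pc.directed_auc(1 - labels, labels, 1 - labels, labels)
        assert res.direction == "controls_gt_cases"
        assert res.auc_train == 1.0 and res.auc_test == 1.0

    def test_ties_give_half(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        const = np.ones(10)
        res = pc.directed_auc(const, labels, const, labels)
        assert res.auc_train == 0.5 and res.auc_test == 0.5

    def test_single_class_train_rejected(self):
        with pytest.raises(InvalidLabelsError):
            pc.directed_auc([1, 2, 3], [1, 1, 1], [1], [0])

    def test_null_scores_train_above_half_test_symmetric(self):
        """With scores independent of labels, auc_train >= 0.5 by
        construction and auc_test scatters symmetrically around 0.5."""
        rng = np.random.default_rng(8)
        labels = np.r_[np.zeros(20), np.ones(20)].astype(int)
        test_aucs = []
        for _ in range(300):
            res = pc.directed_auc(rng.normal(size=40), labels,
                                  rng.normal(size=40), labels)
            assert res.auc_train >= 0.5
            test_aucs.append(res.auc_test)
        assert abs(np.mean(test_aucs) - 0.5) < 0.02

    @given(st.sampled_from([np.exp, np.tanh, lambda x: 3 * x + 1]))
    def test_monotone_transform_invariance(self, f):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.normal(size=40)
        a = pc.directed_auc(scores, labels, scores, labels)
        b = pc.directed_auc(f(scores), labels, f(scores), labels)
        assert a.auc_train == pytest.approx(b.auc_train)
        assert a.auc_test == pytest.approx(b.auc_test)


class TestUnivariateLogistic:
    def test_feature_equals_label(self):
        labels = np.r_[np.zeros(10), np.ones(10)].astype(int)
        res = pc.univariate_logistic_auc(labels.astype(float), labels,
                                         labels.astype(float), labels)
        assert res.auc_test == 1.0

    def test_independent_feature_near_half(self):
        rng = np.random.default_rng(42)
        labels = np.r_[np.zeros(100), np.ones(100)].astype(int)
        feature = rng.permutation(np.arange(200.0))
        res = pc.univariate_logistic_auc(feature, labels, feature, labels)
        assert 0.4 <= res.auc_test <= 0.6

    def test_zero_variance_feature(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        with pytest.warns(UserWarning):
            res = pc.univariate_logistic_auc(np.ones(10), labels,
                                             np.ones(10), labels)
        assert res.auc_test == 0.5


@pytest.fixture(scope="module")
def separable():
    """Linearly separable two-cluster data for the classifier harness."""
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0, 0.5, (30, 2)), rng.normal(4, 0.5, (30, 2))])
    y = np.r_[np.zeros(30), np.ones(30)].astype(int)
    return X, y


class TestClassifierHarness:
    @pytest.mark.parametrize("kind", pc.CLASSIFIER_KINDS)
    def test_separable_data_high_cv_auc(self, kind, separable):
        X, y = separable
        model = pc.fit_classifier(kind, X, y, seed=0)
        assert model.best_score_ >= 0.95

    def test_deterministic_selection(self, separable):
        X, y = separable
        a = pc.fit_classifier("gradient_boosted_trees", X, y, seed=3)
        b = pc.fit_classifier("gradient_boosted_trees", X, y, seed=3)
        assert a.best_params_ == b.best_params_

    def test_unknown_kind(self, separable):
        X, y = separable
        with pytest.raises(ValueError):
            pc.fit_classifier("random_forest", X, y)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidLabelsError):
            pc.fit_classifier("elastic_net_logistic", np.eye(5),
                              np.zeros(5, int))


class TestCompareRawVsStrengths:
    def test_identity_strengths_give_zero_difference(self, rng):
        X = rng.normal(size=(40, 3))
        labels = np.r_[np.zeros(20), np.ones(20)].astype(int)
        folds = np.array(["TRAIN", "TEST"] * 20, dtype=object)
        table = FeatureTable(pd.DataFrame(X, columns=list("abc")), labels, folds)
        result = pc.compare_raw_vs_strengths(table, table, seed=0)
        assert len(result) == 6  # 3 kinds x 2 representations
        pivot = result.pivot(index="classifier", columns="representation",
                             values="auc_test")
        assert np.allclose(pivot["raw"], pivot["strengths"])

    def test_fold_mismatch_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        a = FeatureTable(pd.DataFrame(X), labels, ["TRAIN", "TEST"] * 5)
        b = FeatureTable(pd.DataFrame(X), labels, ["TRAIN"] * 10)
        with pytest.raises(SchemaError):
            pc.compare_raw_vs_strengths(a, b)


class TestPairedWilcoxon:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning):
            assert pc.paired_wilcoxon(np.ones(6), np.ones(6)) == 1.0

    def test_exact_all_positive_shifts(self):
        a = np.arange(10, dtype=float) + 1
        b = np.arange(10, dtype=float)
        assert pc.paired_wilcoxon(a, b) == pytest.approx(2 / 2**10)

    def test_pair_order_invariance(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        perm = rng.permutation(12)
        assert pc.paired_wilcoxon(a, b) == pytest.approx(
            pc.paired_wilcoxon(a[perm], b[perm]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pc.paired_wilcoxon(np.ones(6), np.ones(7))


class TestRadiusCorrelations:
    def make_chars(self, radii, extra=None):
        df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(radii))],
                           "label": 0, "fold": "TEST"})
        df["stat_r"] = radii
        df["stat_affine"] = -2 * np.asarray(radii) + 7
        df["stat_const"] = 3.3
        if extra is not None:
            df["stat_extra"] = extra
        return df

    def test_exact_and_affine_and_constant(self, rng):
        radii = rng.uniform(0, 1, 30)
        corr = pc.radius_correlations(self.make_chars(radii), radii)
        assert corr["stat_r"] == pytest.approx(1.0)
        assert corr["stat_affine"] == pytest.approx(1.0)
        assert corr["stat_const"] == 0.0

    def test_length_mismatch(self, rng):
        radii = rng.uniform(0, 1, 10)
        with pytest.raises(ValueError):
            pc.radius_correlations(self.make_chars(radii), radii[:5])


class TestRealDataDesign:
    def make_table(self, n_cases, n_controls, dim=5, seed=0):
        rng = np.random.default_rng(seed)
        n = n_cases + n_controls
        labels = np.r_[np.ones(n_cases), np.zeros(n_controls)].astype(int)
        return FeatureTable(
            pd.DataFrame(rng.normal(size=(n, dim)),
                         columns=[f"f{i}" for i in range(dim)]),
            labels, ["TRAIN"] * n)

    def test_subset_design(self):
        table = self.make_table(60, 80)
        subsets = pc.make_real_subsets(table, n_rep=20, seed=1)
        assert len(subsets) == 20
        for sub in subsets:
            assert len(sub) == 80
            for label in (0, 1):
                for fold in ("TRAIN", "TEST"):
                    assert ((sub.labels == label)
                            & (sub.folds == fold)).sum() == 20

    def test_subsets_are_reproducible_and_varied(self):
        table = self.make_table(60, 80)
        a = pc.make_real_subsets(table, n_rep=3, seed=5)
        b = pc.make_real_subsets(table, n_rep=3, seed=5)
        assert all(np.array_equal(x.sample_ids, y.sample_ids)
                   for x, y in zip(a, b))
        assert not np.array_equal(a[0].sample_ids, a[1].sample_ids)

    def test_insufficient_class_rejected(self):
        with pytest.raises(InvalidLabelsError):
            pc.make_real_subsets(self.make_table(39, 80))

    def test_preprocess_imputation_and_dropping(self):
        df = pd.DataFrame({
            "label": ["g", "b", "g"],
            "f1": [1.0, None, 3.0],
            "f2": [2.0, 2.0, 2.0],        # constant: dropped
            "f3": [None, None, None],     # all-missing: dropped
        })
        with pytest.warns(UserWarning):
            table = pc.preprocess_table(df, label_map={"g": 0, "b": 1})
        assert table.feature_names == ["f1"]
        assert np.allclose(table.features["f1"], [1.0, 2.0, 3.0])
        assert np.array_equal(table.labels, [0, 1, 0])

    def test_preprocess_case_label(self):
        df = pd.DataFrame({"label": ["g", "x", "y"], "f1": [1.0, 2.0, 3.0]})
        table = pc.preprocess_table(df, case_label="g")
        assert np.array_equal(table.labels, [1, 0, 0])

    def test_unmappable_label(self):
        df = pd.DataFrame({"label": ["g", "q"], "f1": [1.0, 2.0]})
        with pytest.raises(SchemaError):
            pc.preprocess_table(df, label_map={"g": 0})


class TestSmallSampleRule:
    def test_threshold_rule_on_benchmark_dims(self):
        selected = small_p_dataset_names(train_size=40)
        assert len(selected) == 7
        dims = {dim for name, dim, _, _ in REAL_DATASET_SHELLS
                if name in selected}
        assert dims == {33, 41, 44, 60, 77, 147, 260}

    @pytest.mark.parametrize("train,dim,expected", [
        (40, 33, True), (40, 22, False), (40, 41, True), (30, 30, True),
    ])
    def test_indicator(self, train, dim, expected):
        assert pc.is_small_sample_regime(train, dim) is expected
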
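"""Tests of the cross-validation protocol: stratification, PCA capping,
univariate selection, oversampling, leakage safety and metrics."""

import numpy as np
import pandas as pd
import pytest

from pedmri.classify import (
    ExperimentConfig,
    feature_columns_for,
    grade_task_labels,
    knn_k,
    oversample,
    pca_reduce,
    perturbation_analysis,
    stratified_kfold,
    train_and_evaluate,
    univariate_select,
)
from pedmri.features import FEATURE_COLUMNS
from pedmri.synthetic import sample_feature_table


def _labels_221710():
    return np.array(
        ["pilocytic_astrocytoma"] * 22 + ["medulloblastoma"] * 17 +
        ["ependymoma"] * 10
    )


class TestGradeLabels:
    def test_study_counts(self):
        grades = grade_task_labels(_labels_221710())
        assert (grades == "low").sum() == 22
        assert (grades == "high").sum() == 27

    def test_all_low(self):
        assert (grade_task_labels(["pilocytic_astrocytoma"] * 3) == "low").all()

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            grade_task_labels(["oligodendroglioma"])


class TestStratifiedKFold:
    def test_partition_and_balance(self):
        labels = _labels_221710()
        folds = stratified_kfold(labels, k=3, seed=0)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(49))  # disjoint cover
        for cls, total in (("pilocytic_astrocytoma", 22),
                           ("medulloblastoma", 17), ("ependymoma", 10)):
            counts = sorted(
                (labels[te] == cls).sum() for _, te in folds
            )
            assert sum(counts) == total
            assert counts[-1] - counts[0] <= 1

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(_labels_221710(), k=1)

    def test_small_class_error_names_it(self):
        labels = np.array(["a"] * 10 + ["b"] * 2)
        with pytest.raises(ValueError, match="'b'"):
            stratified_kfold(labels, k=3)

    def test_deterministic(self):
        labels = _labels_221710()
        f1 = stratified_kfold(labels, seed=5)
        f2 = stratified_kfold(labels, seed=5)
        for (_, a), (_, b) in zip(f1, f2):
            assert np.array_equal(a, b)


class TestPCAReduce:
    def test_cap_at_smallest_group_minus_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(49, 33))
        Xtr, Xte, m = pca_reduce(X, X[:5], _labels_221710())
        assert m <= 9  # smallest group is 10 -> at most 9 components

    def test_rank_two_data_gives_two_components(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 20))
        X = rng.normal(size=(30, 2)) @ basis
        _, _, m = pca_reduce(X, X[:3], ["a"] * 15 + ["b"] * 15)
        assert m == 2

    def test_test_set_does_not_leak_into_loadings(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 10))
        labels = ["a"] * 20 + ["b"] * 20
        tr1, _, _ = pca_reduce(X, rng.normal(size=(5, 10)), labels)
        tr2, _, _ = pca_reduce(X, 100 + rng.normal(size=(5, 10)), labels)
        assert np.allclose(tr1, tr2)

    def test_variance_target_monotone_in_components(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 12)) * np.linspace(3, 0.1, 12)
        labels = ["a"] * 20 + ["b"] * 20
        _, _, m_low = pca_reduce(X, X[:2], labels, variance_target=0.5)
        _, _, m_high = pca_reduce(X, X[:2], labels, variance_target=0.95)
        assert m_low <= m_high


class TestUnivariateSelect:
    def test_perfect_separator_selected(self):
        rng = np.random.default_rng(4)
        n = 30
        table = pd.DataFrame({
            "noise1": rng.normal(size=n),
            "signal": np.r_[rng.normal(0, 0.1, 15), rng.normal(10, 0.1, 15)],
            "noise2": rng.normal(size=n),
        })
        labels = ["a"] * 15 + ["b"] * 15
        sel = univariate_select(table, labels, list(table.columns))
        assert sel[0] == "signal"

    def test_fallback_to_best_auc_when_nothing_significant(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("xyz"))
        labels = ["a"] * 10 + ["b"] * 10
        sel = univariate_select(table, labels, list("xyz"))
        assert len(sel) == 1

    def test_selection_varies_across_folds(self, feature_table):
        cfg = ExperimentConfig(task="type", reduction="univariate",
                               classifier="knn", seed=0, hyperopt_budget=1)
        rep = train_and_evaluate(feature_table, cfg)
        selections = [tuple(d["selected_features"]) for d in rep.fold_details]
        assert len(set(selections)) > 1  # training folds differ, so can picks

    def test_permuted_labels_give_chance_test_auc(self):
        # features selected on label-permuted training data carry no signal:
        # their held-out AUC averages ~0.5
        from pedmri.stats import roc_auc

        rng = np.random.default_rng(6)
        aucs = []
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(40, 8)),
                             columns=[f"f{i}" for i in range(8)])
            labels = np.array(["a", "b"] * 20)
            perm = rng.permutation(labels)
            sel = univariate_select(X.iloc[:24], perm[:24], list(X.columns))
            aucs.append(roc_auc(X[sel[0]].to_numpy()[24:], perm[24:], "a"))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.08)


class TestOversample:
    def test_replicate_doubles_minority(self):
        X = np.arange(24, dtype=float).reshape(12, 2)
        y = np.array(["ependymoma"] * 6 + ["other"] * 6)
        X2, y2 = oversample(X, y, "replicate")
        assert (y2 == "ependymoma").sum() == 12
        assert (y2 == "other").sum() == 6

    def test_smote_doubles_and_interpolates(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 3))
        y = np.array(["ependymoma"] * 6 + ["other"] * 6)
        X2, y2 = oversample(X, y, "smote", rng=rng)
        assert (y2 == "ependymoma").sum() == 12
        new = X2[12:]
        minority = X[:6]
        # each synthetic point lies coordinate-wise within the minority hull
        # segment between two existing minority points
        for p in new:
            ok = False
            for i in range(6):
                for j in range(6):
                    if i == j:
                        continue
                    lo = np.minimum(minority[i], minority[j])
                    hi = np.maximum(minority[i], minority[j])
                    if ((p >= lo - 1e-9) & (p <= hi + 1e-9)).all():
                        ok = True
            assert ok

    def test_none_is_identity(self):
        X = np.ones((4, 2))
        y = np.array(["ependymoma"] * 2 + ["other"] * 2)
        X2, y2 = oversample(X, y, "none")
        assert X2 is X and y2 is y

    def test_smote_single_minority_rejected(self):
        X = np.ones((4, 2))
        y = np.array(["ependymoma"] + ["other"] * 3)
        with pytest.raises(ValueError):
            oversample(X, y, "smote", rng=0)


class TestKnnK:
    def test_sqrt_rule(self):
        assert knn_k(25) == 5
        assert knn_k(1) == 1

    def test_round_not_floor(self):
        assert knn_k(16) == 4
        assert knn_k(30) == 5  # sqrt(30) = 5.48 rounds down
        assert knn_k(31) == 6  # sqrt(31) = 5.57 rounds up


class TestTrainAndEvaluate:
    def test_perfect_separability_saturates(self):
        rng = np.random.default_rng(8)
        n = 15
        rows = []
        for i, cls in enumerate(["pilocytic_astrocytoma", "medulloblastoma",
                                 "ependymoma"]):
            for _ in range(n):
                rows.append({"f1": rng.normal(10 * i, 0.1),
                             "f2": rng.normal(-5 * i, 0.1),
                             "label": cls})
        table = pd.DataFrame(rows)
        cfg = ExperimentConfig(task="type", reduction="none", classifier="knn",
                               seed=0, hyperopt_budget=1)
        rep = train_and_evaluate(table, cfg, columns=["f1", "f2"])
        assert rep.bar == pytest.approx(100.0)
        assert rep.f_stat == pytest.approx(1.0)

    def test_confusion_rows_sum_to_class_counts(self, feature_table):
        cfg = ExperimentConfig(task="type", reduction="pca", classifier="knn",
                               seed=1, hyperopt_budget=1)
        rep = train_and_evaluate(feature_table, cfg)
        counts = feature_table["label"].value_counts()
        for cls in counts.index:
            assert rep.confusion.loc[cls].sum() == counts[cls]

    def test_grade_task_binary_confusion(self, feature_table):
        cfg = ExperimentConfig(task="grade", reduction="univariate",
                               classifier="adaboost", seed=0, hyperopt_budget=1)
        rep = train_and_evaluate(feature_table, cfg)
        assert set(rep.confusion.index) == {"low", "high"}
        assert rep.confusion.to_numpy().sum() == 49
        assert rep.bar > 50.0  # profile effect sizes are discriminative

    def test_deterministic_under_seed(self, feature_table):
        cfg = ExperimentConfig(task="type", reduction="univariate",
                               classifier="knn", seed=3, hyperopt_budget=1)
        r1 = train_and_evaluate(feature_table, cfg)
        r2 = train_and_evaluate(feature_table, cfg)
        assert r1.bar == r2.bar
        assert np.array_equal(r1.y_pred, r2.y_pred)

    def test_fitting_blind_to_test_values(self, feature_table):
        # replacing test-fold feature values with constants must leave the
        # per-fold selected features and hyperparameters unchanged
        cfg = ExperimentConfig(task="type", reduction="univariate",
                               classifier="knn", seed=2, hyperopt_budget=1)
        base = train_and_evaluate(feature_table, cfg)
        labels = feature_table["label"].to_numpy()
        folds = stratified_kfold(labels, k=3, seed=cfg.seed)
        mangled = feature_table.copy()
        _, te0 = folds[0]
        mangled.iloc[te0, : len(FEATURE_COLUMNS)] = 7.77
        alt = train_and_evaluate(mangled, cfg)
        # fold 0's own training rows are untouched (the mangled rows are only
        # training rows of the *other* folds), so its fit must be identical
        d1, d2 = base.fold_details[0], alt.fold_details[0]
        assert d1["selected_features"] == d2["selected_features"]
        assert d1["hyperparameters"] == d2["hyperparameters"]

    def test_oversampling_runs_and_leaves_test_rows(self, feature_table):
        # the internal hash assert verifies test folds are untouched
        for method in ("replicate", "smote"):
            cfg = ExperimentConfig(task="type", reduction="pca",
                                   classifier="knn", oversampling=method,
                                   seed=0, hyperopt_budget=1)
            rep = train_and_evaluate(feature_table, cfg)
            assert rep.confusion.to_numpy().sum() == 49
            for d in rep.fold_details:
                assert d["n_train"] > 32  # 49 - 17 test + ~6 extra ependymoma

    @pytest.mark.parametrize("kw", [
        dict(task="volume"), dict(reduction="lda"), dict(classifier="svc"),
        dict(oversampling="adasyn"), dict(n_folds=1),
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            ExperimentConfig(**kw)


class TestPerturbation:
    def test_one_row_per_partner_and_dominance(self):
        rng = np.random.default_rng(9)
        table = sample_feature_table(n_per_class=(12, 12, 8), seed=10)
        # make one ROI feature pure noise and one a copy of the informative base
        table["UCBV_ROI_mean"] = rng.normal(size=len(table))
        table["CCBV_ROI_mean"] = table["ADC_ROI_mean"] + rng.normal(
            0, 1e-3, len(table)
        )
        cfg = ExperimentConfig(task="type", classifier="knn", seed=0,
                               hyperopt_budget=1)
        res = perturbation_analysis(table, cfg, family="roi")
        roi_cols = [c for c in feature_columns_for("roi") if c != "ADC_ROI_mean"]
        assert sorted(res.index) == sorted(roi_cols)
        assert res.loc["CCBV_ROI_mean", "precision"] >= \
            res.loc["UCBV_ROI_mean", "precision"]

    def test_deterministic(self, feature_table):
        cfg = ExperimentConfig(task="grade", classifier="knn", seed=4,
                               hyperopt_budget=1)
        a = perturbation_analysis(feature_table, cfg, family="wb")
        b = perturbation_analysis(feature_table, cfg, family="wb")
        pd.testing.assert_frame_equal(a, b)
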
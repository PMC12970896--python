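"""Fold planning, leakage-safe scaling, metrics and classification harness."""

import warnings

import numpy as np
import pandas as pd
import pytest

import eegmark as em
from eegmark.dynamic import BASE_FEATURES
from eegmark.evaluation import (
    ConfusionMatrix,
    apply_scaler,
    build_fold_plan,
    compute_metrics,
    cross_dataset_eval,
    fit_fold_scaler,
    make_classifier,
    permute_recording_labels,
    prepare_fold_features,
    run_task,
    subset_columns,
)


def synthetic_feature_table(n_rec_per_class=12, windows=8, sep=5.0, seed=0,
                            noise=1.0):
    """Two well-separated classes: a quick stand-in feature table."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls, shift in (("interictal", 0.0), ("ictal", sep)):
        for r in range(n_rec_per_class):
            rid = f"{cls}_{r}"
            for w in range(windows):
                vals = rng.normal(loc=shift, scale=noise, size=4)
                rows.append({"recording_id": rid, "window_index": w,
                             "label": cls,
                             **dict(zip(BASE_FEATURES, vals))})
    return pd.DataFrame(rows)


class TestFoldPlan:
    def test_balanced_stratified_assignment(self):
        labels = {f"a{i}": "ictal" for i in range(50)}
        labels.update({f"b{i}": "interictal" for i in range(50)})
        plan = build_fold_plan(labels, n_folds=10, seed=3)
        for fold in range(10):
            _, test_ids = plan.train_test_ids(fold)
            got = sorted(labels[r] for r in test_ids)
            assert got == ["ictal"] * 5 + ["interictal"] * 5

    def test_deterministic_given_seed(self):
        labels = {f"r{i}": ("ictal" if i % 2 else "interictal")
                  for i in range(40)}
        p1 = build_fold_plan(labels, 10, seed=9)
        p2 = build_fold_plan(labels, 10, seed=9)
        assert p1.assignment == p2.assignment
        p3 = build_fold_plan(labels, 10, seed=10)
        assert p3.assignment != p1.assignment

    def test_too_few_recordings_rejected(self):
        labels = {f"r{i}": "ictal" for i in range(5)}
        with pytest.raises(ValueError, match="5 recordings"):
            build_fold_plan(labels, n_folds=10)

    def test_every_recording_in_exactly_one_fold(self, small_labels):
        plan = build_fold_plan(small_labels, n_folds=4, seed=0)
        assert set(plan.assignment) == set(small_labels)
        assert set(plan.assignment.values()) <= set(range(4))


class TestScaler:
    def test_train_statistics_applied_to_test(self):
        train = pd.DataFrame({f: [0.0, 10.0] for f in BASE_FEATURES})
        scaler = fit_fold_scaler(train)
        test = pd.DataFrame({f: [5.0] for f in BASE_FEATURES})
        out = apply_scaler(test, scaler)
        assert np.allclose(out.to_numpy(), 0.5)

    def test_zero_variance_feature_warns_and_maps_to_zero(self):
        train = pd.DataFrame({f: [2.0, 2.0] for f in BASE_FEATURES})
        with pytest.warns(UserWarning, match="zero variance"):
            scaler = fit_fold_scaler(train)
        out = apply_scaler(train, scaler)
        assert np.array_equal(out.to_numpy(), np.zeros((2, 4)))

    def test_out_of_range_test_values_clipped(self):
        train = pd.DataFrame({f: [0.0, 10.0] for f in BASE_FEATURES})
        scaler = fit_fold_scaler(train)
        test = pd.DataFrame({f: [-3.0, 12.0] for f in BASE_FEATURES})
        out = apply_scaler(test, scaler)
        assert np.array_equal(out.to_numpy()[:, 0], [0.0, 1.0])

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            fit_fold_scaler(pd.DataFrame({f: [] for f in BASE_FEATURES}))


class TestMetrics:
    def test_fixture_confusion_matrix_arithmetic(self):
        cm = ConfusionMatrix.from_binary_counts(tp=90, fn=10, tn=80, fp=20)
        m = compute_metrics(cm, "binary", positive="epileptic")
        assert m.acc == pytest.approx(0.85, abs=1e-12)
        assert m.sen == pytest.approx(0.90, abs=1e-12)
        assert m.spe == pytest.approx(0.80, abs=1e-12)
        assert m.pre == pytest.approx(90 / 110, abs=1e-12)
        assert m.f1 == pytest.approx(2 * (90 / 110) * 0.9 / (90 / 110 + 0.9),
                                     abs=1e-12)

    def test_perfect_diagonal_binary(self):
        cm = ConfusionMatrix.from_binary_counts(tp=40, fn=0, tn=60, fp=0)
        m = compute_metrics(cm, "binary")
        assert m.as_dict() == {"acc": 1.0, "spe": 1.0, "sen": 1.0,
                               "pre": 1.0, "f1": 1.0}

    def test_perfect_diagonal_macro(self):
        cm = ConfusionMatrix(["a", "b", "c"], np.diag([30, 30, 40]))
        m = compute_metrics(cm, "macro")
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_macro_invariant_under_class_relabeling(self, rng):
        counts = rng.integers(0, 50, size=(3, 3))
        cm = ConfusionMatrix(["a", "b", "c"], counts)
        perm = [2, 0, 1]
        cm_perm = ConfusionMatrix(
            ["c", "a", "b"], counts[np.ix_(perm, perm)])
        m1 = compute_metrics(cm, "macro")
        m2 = compute_metrics(cm_perm, "macro")
        for k, v in m1.as_dict().items():
            assert m2.as_dict()[k] == pytest.approx(v, abs=1e-12)

    def test_zero_denominator_convention(self):
        # no predicted positives: precision 0/0 -> 0 with warning
        cm = ConfusionMatrix.from_binary_counts(tp=0, fn=10, tn=90, fp=0)
        with pytest.warns(UserWarning, match="0/0"):
            m = compute_metrics(cm, "binary")
        assert m.pre == 0.0 and m.f1 == 0.0

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix.empty(["a", "b"])
        with pytest.raises(ValueError):
            compute_metrics(cm, "binary")


class TestSubsets:
    def test_subset_expansion(self):
        assert subset_columns("plf") == ["spike_energy", "sharp_energy"]
        assert subset_columns("ndf") == ["hfd", "pe"]
        assert subset_columns("plf+ndf+dfi") == subset_columns("all")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            subset_columns("plf+wavelet")


class TestRunTask:
    def test_separable_classes_perfect_accuracy(self):
        # point clusters: no test draw can land inside the class margin
        feats = synthetic_feature_table(sep=1.0, noise=0.0)
        labels = feats.groupby("recording_id")["label"].first().to_dict()
        plan = build_fold_plan(labels, n_folds=4, seed=1)
        res = run_task(feats, plan, classifiers=("dt", "knn", "xgb"),
                       feature_subsets=("all",), seed=1)
        for clf in ("dt", "knn", "xgb"):
            assert res["all"][clf]["metrics"].acc == 1.0

    def test_positive_class_is_ictal(self):
        feats = synthetic_feature_table(sep=8.0)
        labels = feats.groupby("recording_id")["label"].first().to_dict()
        plan = build_fold_plan(labels, n_folds=4, seed=1)
        res = run_task(feats, plan, classifiers=("dt",),
                       feature_subsets=("plf",), seed=1)
        cm = res["plf"]["dt"]["confusion"]
        assert set(cm.classes) == {"ictal", "interictal"}
        assert cm.total == len(feats)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("mlp")

    def test_reproducible_given_seed(self, small_features, small_labels):
        plan = build_fold_plan(small_labels, n_folds=3, seed=5)
        kwargs = dict(classifiers=("xgb",), feature_subsets=("all",), seed=5)
        r1 = run_task(small_features, plan, **kwargs)
        r2 = run_task(small_features, plan, **kwargs)
        m1 = r1["all"]["xgb"]["metrics"]
        m2 = r2["all"]["xgb"]["metrics"]
        assert m1.as_dict() == m2.as_dict()


class TestLeakageGuard:
    def test_scaler_ignores_test_rows(self, small_features, small_labels):
        """Deleting test-fold rows before scaler fitting changes nothing."""
        plan = build_fold_plan(small_labels, n_folds=3, seed=2)
        train_ids, test_ids = plan.train_test_ids(0)
        full = small_features
        pruned = full[~full["recording_id"].isin(set(test_ids))]
        s_full = fit_fold_scaler(
            full[full["recording_id"].isin(set(train_ids))])
        s_pruned = fit_fold_scaler(
            pruned[pruned["recording_id"].isin(set(train_ids))])
        assert s_full == s_pruned

    def test_fold_features_bitwise_identical_without_test_rows(
            self, small_features, small_labels):
        """Train-fold outputs are bit-identical whether or not the test
        fold's rows are present in the table at all."""
        plan = build_fold_plan(small_labels, n_folds=3, seed=2)
        train_ids, test_ids = plan.train_test_ids(1)
        tr_full, te_full = prepare_fold_features(small_features, train_ids,
                                                 test_ids)
        without_test = small_features[
            ~small_features["recording_id"].isin(set(test_ids))]
        tr_pruned, _ = prepare_fold_features(without_test, train_ids, [])
        cols = BASE_FEATURES + ["dfi"]
        assert tr_full[cols].reset_index(drop=True).equals(
            tr_pruned[cols].reset_index(drop=True))
        assert len(te_full) > 0


class TestCrossDataset:
    def test_self_transfer_equals_resubstitution(self):
        feats = synthetic_feature_table(sep=8.0, seed=3)
        m, cm = cross_dataset_eval(feats, feats, classifier="dt", seed=0)
        assert m.acc == 1.0
        assert cm.total == len(feats)

    def test_matched_domains_close_to_cv(self):
        src = synthetic_feature_table(sep=3.0, seed=10)
        tgt = synthetic_feature_table(sep=3.0, seed=11)
        m, _ = cross_dataset_eval(src, tgt, classifier="xgb", seed=0)
        labels = src.groupby("recording_id")["label"].first().to_dict()
        plan = build_fold_plan(labels, n_folds=4, seed=0)
        cv = run_task(src, plan, classifiers=("xgb",),
                      feature_subsets=("all",), seed=0)
        assert abs(m.acc - cv["all"]["xgb"]["metrics"].acc) < 0.1

    def test_degrades_with_domain_shift(self):
        src = synthetic_feature_table(sep=3.0, seed=20)
        accs = []
        for shift in (0.0, 2.0, 8.0):
            tgt = synthetic_feature_table(sep=3.0, seed=21)
            tgt[BASE_FEATURES] += shift
            m, _ = cross_dataset_eval(src, tgt, classifier="knn", seed=0)
            accs.append(m.acc)
        assert accs[0] >= accs[1] >= accs[2]
        assert accs[0] - accs[2] > 0.1

    def test_schema_mismatch_rejected(self):
        src = synthetic_feature_table(seed=1)
        with pytest.raises(ValueError):
            cross_dataset_eval(src, src.drop(columns=["hfd"]))


class TestPermutationNull:
    def test_labels_move_with_recordings(self, small_features):
        out = permute_recording_labels(small_features, seed=4)
        per_rec = out.groupby("recording_id")["label"].nunique()
        assert (per_rec == 1).all()
        # label multiset is preserved at the recording level
        orig = small_features.groupby("recording_id")["label"].first()
        perm = out.groupby("recording_id")["label"].first()
        assert sorted(orig) == sorted(perm)
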
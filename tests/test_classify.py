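"""Balancing, stratified folds, feature extraction and channel cross-validation."""

import numpy as np
import pandas as pd
import pytest

from skinspec import (
    ClassifierSpec,
    CvConfig,
    FeatureSpec,
    balance_classes,
    crossvalidate_channel,
    extract_features,
    stratified_folds,
)
from skinspec.classify import AutoencoderTransform, make_fold_plan
from skinspec.datamodel import ConfigError


class TestBalanceClasses:
    def test_downsamples_to_smallest_class(self):
        labels = np.array(["BCC"] * 90 + ["SCC"] * 57)
        idx = balance_classes(labels, seed=0)
        kept = labels[idx]
        assert (kept == "BCC").sum() == 57
        assert (kept == "SCC").sum() == 57

    def test_already_balanced_is_identity(self):
        labels = np.array(["A", "B"] * 10)
        np.testing.assert_array_equal(balance_classes(labels, seed=3), np.arange(20))

    def test_three_classes_to_common_minimum(self):
        labels = np.array(["A"] * 10 + ["B"] * 7 + ["C"] * 7)
        kept = labels[balance_classes(labels, seed=1)]
        assert sorted(np.unique(kept, return_counts=True)[1]) == [7, 7, 7]

    def test_pure_function_of_labels_and_seed(self):
        labels = np.array(["A"] * 30 + ["B"] * 12)
        a = balance_classes(labels, seed=7)
        b = balance_classes(labels, seed=7)
        c = balance_classes(labels, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            balance_classes(np.array(["A", "A"]), seed=0)


class TestStratifiedFolds:
    def test_balanced_two_class_k5(self):
        labels = np.array(["A"] * 10 + ["B"] * 10)
        folds = stratified_folds(labels, k=5, seed=0)
        for f in range(5):
            sel = labels[folds == f]
            assert (sel == "A").sum() == 2 and (sel == "B").sum() == 2

    def test_folds_partition_index_set(self):
        labels = np.array(["A", "B", "C"] * 7)
        folds = stratified_folds(labels, k=3, seed=2)
        assert folds.size == labels.size
        assert set(folds) == {0, 1, 2}
        # per-class counts differ by <= 1 across folds
        for cls in "ABC":
            counts = [np.sum((folds == f) & (labels == cls)) for f in range(3)]
            assert max(counts) - min(counts) <= 1

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ConfigError, match="k=5"):
            stratified_folds(np.array(["A"] * 3 + ["B"] * 10), k=5, seed=0)


class TestExtractFeatures:
    def test_pca_recovers_planar_data_exactly(self, rng):
        basis = rng.normal(size=(2, 30))
        coeffs = rng.normal(size=(40, 2))
        X = coeffs @ basis + 5.0
        ftr, fte, pca = extract_features(X, X[:5], FeatureSpec(n_components=2))
        recon = pca.inverse_transform(ftr)
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_pca_transform_of_train_mean_is_zero(self, rng):
        X = rng.normal(size=(20, 10))
        _ftr, fte, _pca = extract_features(
            X, X.mean(axis=0, keepdims=True), FeatureSpec(n_components=3)
        )
        np.testing.assert_allclose(fte, 0.0, atol=1e-9)

    def test_infeasible_components_error_or_clamp(self, rng):
        X = rng.normal(size=(5, 8))
        with pytest.raises(ConfigError, match="n_components"):
            extract_features(X, X, FeatureSpec(n_components=10))
        ftr, _f, _p = extract_features(X, X, FeatureSpec(n_components=10), clamp=True)
        assert ftr.shape[1] == 5

    def test_linear_autoencoder_approaches_pca_on_low_rank_data(self, rng):
        # noiseless rank-2 data; identity activations; bottleneck 2
        basis = rng.normal(size=(2, 12))
        X = rng.normal(size=(60, 2)) @ basis
        spec = FeatureSpec(
            method="autoencoder", hidden=(8, 2, 8), activation="identity",
            solver="lbfgs", max_iter=2000,
        )
        ftr, _fte, ae = extract_features(X, X[:3], spec, seed=0)
        assert ftr.shape == (60, 2)
        recon_err = np.linalg.norm(ae.reconstruct(X) - X) / np.linalg.norm(X)
        assert recon_err < 0.05  # PCA subspace fit achieves 0

    def test_autoencoder_bottleneck_dimension(self, rng):
        X = rng.normal(size=(30, 20))
        ae = AutoencoderTransform(hidden=(16, 5, 16), max_iter=50, seed=1).fit(X)
        assert ae.transform(X).shape == (30, 5)


def two_blob_data(n_per=30, sep=8.0, dim=12, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, dim))
    b = rng.normal(sep, 1.0, size=(n_per, dim))
    X = np.vstack([a, b])
    y = np.array(["H"] * n_per + ["BCC"] * n_per)
    return X, y


class TestCrossValidate:
    def test_separable_data_reaches_perfect_accuracy(self):
        X, y = two_blob_data(sep=10.0)
        cfg = CvConfig(k=5, n_repeats=2, seed=0, feature=FeatureSpec(n_components=3))
        table, metrics = crossvalidate_channel(X, y, cfg)
        assert metrics["accuracy_mean"] == 1.0
        assert metrics["accuracy_sd"] == 0.0

    def test_each_sample_predicted_once_per_repeat(self):
        X, y = two_blob_data(sep=2.0)
        cfg = CvConfig(k=5, n_repeats=3, seed=1, feature=FeatureSpec(n_components=3))
        table, _m = crossvalidate_channel(X, y, cfg)
        counts = table.groupby(["sample_id", "repeat"]).size()
        assert (counts == 1).all()
        assert table["repeat"].nunique() == 3

    def test_determinism(self):
        X, y = two_blob_data(sep=1.0, seed=5)
        cfg = CvConfig(k=4, n_repeats=2, seed=9, feature=FeatureSpec(n_components=2))
        t1, m1 = crossvalidate_channel(X, y, cfg)
        t2, m2 = crossvalidate_channel(X, y, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert m1["per_repeat_accuracy"] == m2["per_repeat_accuracy"]

    def test_hyperparameter_grid_prefers_simplest_on_ties(self):
        X, y = two_blob_data(sep=10.0)
        grid = [
            ClassifierSpec(kind="svm", kernel="linear"),
            ClassifierSpec(kind="svm", kernel="rbf"),
        ]
        cfg = CvConfig(
            k=3, n_repeats=1, seed=0,
            feature=FeatureSpec(n_components=2), classifier=grid,
        )
        _t, metrics = crossvalidate_channel(X, y, cfg)
        # both reach 100%; the earlier (linear) candidate must win the tie
        assert metrics["classifier"].kernel == "linear"

    @pytest.mark.parametrize("kind", ["svm", "mlp", "lda"])
    def test_all_classifier_kinds_run(self, kind):
        X, y = two_blob_data(sep=6.0, n_per=20)
        cfg = CvConfig(
            k=3, n_repeats=1, seed=0,
            feature=FeatureSpec(n_components=2),
            classifier=ClassifierSpec(kind=kind, max_iter=300),
        )
        _t, metrics = crossvalidate_channel(X, y, cfg)
        assert metrics["accuracy_mean"] > 0.9

    def test_normalizer_receives_disjoint_train_test_ids(self):
        X, y = two_blob_data(sep=3.0)
        seen = []

        def spy(Xtr, Xte, tr_ids, te_ids):
            seen.append((set(tr_ids), set(te_ids)))
            return Xtr, Xte

        cfg = CvConfig(k=5, n_repeats=2, seed=0, feature=FeatureSpec(n_components=2))
        crossvalidate_channel(X, y, cfg, normalizer=spy)
        assert seen
        for tr, te in seen:
            assert not tr & te

    def test_fold_plan_reproducible_and_balanced(self):
        y = np.array(["A"] * 25 + ["B"] * 18)
        cfg = CvConfig(k=3, n_repeats=5, seed=4)
        p1 = make_fold_plan(y, cfg)
        p2 = make_fold_plan(y, cfg)
        assert len(p1) == 5
        for (s1, f1), (s2, f2) in zip(p1, p2):
            np.testing.assert_array_equal(s1, s2)
            np.testing.assert_array_equal(f1, f2)
            assert (y[s1] == "B").sum() == (y[s1] == "A").sum() == 18
        # repeats draw different balancing subsets
        assert any(not np.array_equal(p1[0][0], p1[r][0]) for r in range(1, 5))
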
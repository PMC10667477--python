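"""Classifier benchmark machinery: fitting, balanced accuracy, CV
designs and channel importance, against hand-rolled oracles."""

import numpy as np
import pandas as pd
import pytest

from shopeeg.modeling import (
    MODEL_FAMILIES,
    ModelSpec,
    PurchaseDecoder,
    balanced_accuracy,
    channel_importance,
    cross_validate,
    fit_predict,
)


def feature_frame(X, y, subjects=None, episodes=None):
    df = pd.DataFrame(X, columns=[f"ch_{i}" for i in range(X.shape[1])])
    df["label"] = y
    if subjects is not None:
        df["subject_id"] = subjects
    if episodes is not None:
        df["episode_id"] = episodes
    return df


def blobs(rng, n_per_class=40, n_features=6, separation=8.0, classes=("buy", "no_buy")):
    X, y = [], []
    for k, cls in enumerate(classes):
        X.append(rng.normal(size=(n_per_class, n_features)) + separation * k)
        y += [cls] * n_per_class
    return np.vstack(X), np.array(y)


class TestFitPredict:
    @pytest.mark.parametrize("family", MODEL_FAMILIES)
    def test_separable_blobs_perfect_accuracy(self, family, rng):
        X, y = blobs(rng)
        train = feature_frame(X[::2], y[::2])
        test = feature_frame(X[1::2], y[1::2])
        pred, converged = fit_predict(ModelSpec(family=family, seed=0), train, test)
        assert balanced_accuracy(y[1::2], pred) == 1.0

    def test_knn_k1_memorizes_training_set(self, rng):
        X, y = blobs(rng, separation=0.1)
        table = feature_frame(X, y)
        pred, _ = fit_predict(ModelSpec(family="knn", knn_k=1), table, table)
        assert balanced_accuracy(y, pred) == 1.0

    def test_shuffled_labels_three_class_at_chance(self, rng):
        n = 150
        X = rng.normal(size=(3 * n, 8))
        y = rng.permutation(np.repeat(["buy", "cart", "no_buy"], n))
        train = feature_frame(X[: 2 * n], y[: 2 * n])
        test = feature_frame(X[2 * n:], y[2 * n:])
        pred, _ = fit_predict(ModelSpec(family="random_forest", seed=3), train, test)
        acc = balanced_accuracy(y[2 * n:], pred)
        band = 1.96 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(acc - 1 / 3) <= band

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        table = feature_frame(X, np.array(["buy"] * 10))
        with pytest.raises(ValueError, match="single class"):
            fit_predict(ModelSpec(family="lda"), table, table)


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        assert balanced_accuracy(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_one_class_never_recalled_gives_half(self):
        y_true = ["a"] * 5 + ["b"] * 5
        y_pred = ["a"] * 10
        assert balanced_accuracy(y_true, y_pred) == 0.5

    def test_matches_hand_computed_macro_recall(self, rng):
        classes = np.array(["a", "b", "c"])
        y_true = classes[rng.integers(0, 3, size=300)]
        y_pred = classes[rng.integers(0, 3, size=300)]
        recalls = [
            np.mean(y_pred[y_true == c] == c) for c in classes if np.any(y_true == c)
        ]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(np.mean(recalls))


class TestCrossValidation:
    def _subject_table(self, rng, n_subjects=7, per_subject=20):
        X, y = blobs(rng, n_per_class=n_subjects * per_subject // 2)
        subjects = np.repeat([f"S{i}" for i in range(n_subjects)], per_subject)
        rng.shuffle(subjects)
        episodes = np.array([f"{s}/e{i}" for i, s in enumerate(subjects)])
        return feature_frame(X, y, subjects, episodes)

    def test_loso_has_one_fold_per_subject(self, rng):
        table = self._subject_table(rng)
        res = cross_validate(ModelSpec(family="lda"), table, "loso")
        assert len(res.folds) == 7
        assert res.scheme == "loso"

    def test_loso_never_mixes_a_subject_across_train_and_test(self, rng):
        table = self._subject_table(rng)
        dec = PurchaseDecoder(table, ModelSpec(family="lda"))
        subjects = table["subject_id"].to_numpy()
        for name, tr, te in dec._folds("loso"):
            assert set(subjects[tr]).isdisjoint(set(subjects[te]))
            assert set(subjects[te]) == {name}

    def test_kfold5_has_five_disjoint_covering_folds(self, rng):
        table = self._subject_table(rng)
        dec = PurchaseDecoder(table, ModelSpec(family="lda"))
        seen = []
        for _, _, te in dec._folds("kfold5"):
            seen.extend(te)
        assert sorted(seen) == list(range(len(table)))

    def test_fixed_seed_reproducible(self, rng):
        table = self._subject_table(rng)
        spec = ModelSpec(family="random_forest", seed=9)
        a = cross_validate(spec, table, "kfold5")
        b = cross_validate(spec, table, "kfold5")
        np.testing.assert_array_equal(a.fold_scores, b.fold_scores)

    def test_loso_single_subject_rejected(self, rng):
        X, y = blobs(rng, n_per_class=10)
        table = feature_frame(X, y, subjects=np.repeat("S1", 20))
        with pytest.raises(ValueError, match="at least 2 subjects"):
            cross_validate(ModelSpec(family="lda"), table, "loso")

    def test_pooled_equals_balanced_accuracy_of_all_oof_predictions(self, rng):
        """The pooled statistic equals macro recall computed from the
        summed confusion matrix."""
        table = self._subject_table(rng)
        res = cross_validate(ModelSpec(family="knn"), table, "loso")
        cm = res.confusion
        recalls = np.diag(cm) / cm.sum(axis=1)
        assert res.pooled == pytest.approx(np.mean(recalls))


class TestChannelImportance:
    def _planted_table(self, rng, n=400, n_channels=12, informative=5):
        X = rng.normal(size=(n, n_channels))
        y = np.where(rng.random(n) < 0.5, "buy", "no_buy")
        X[:, informative] += np.where(y == "buy", 2.0, -2.0)
        return feature_frame(X, y), informative

    def test_planted_channel_ranks_first_impurity_and_permutation(self, rng):
        table, informative = self._planted_table(rng)
        results = PurchaseDecoder(table, ModelSpec(family="random_forest", seed=2)).fit()
        imp = results.channel_importance("impurity")
        assert imp.ranking()[0] == str(informative)
        perm = results.channel_importance("permutation", table=table)
        assert perm.ranking()[0] == str(informative)

    def test_impurity_scores_normalized(self, rng):
        table, _ = self._planted_table(rng)
        results = PurchaseDecoder(table, ModelSpec(family="random_forest", seed=2)).fit()
        imp = results.channel_importance("impurity")
        assert imp.scores.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp.scores >= 0).all()

    def test_noise_channel_permutation_score_near_zero(self, rng):
        table, informative = self._planted_table(rng)
        results = PurchaseDecoder(table, ModelSpec(family="random_forest", seed=2)).fit()
        perm = results.channel_importance("permutation", table=table, n_repeats=20)
        noise_idx = (informative + 1) % 12
        assert abs(perm.scores[noise_idx]) < 2 * max(perm.sd[noise_idx], 1e-12) + 1e-3

    def test_non_forest_model_rejected(self, rng):
        table, _ = self._planted_table(rng)
        results = PurchaseDecoder(table, ModelSpec(family="lda")).fit()
        with pytest.raises(ValueError, match="random forest"):
            channel_importance(results)


class TestResultsObjects:
    def test_summary_reports_scheme_and_convergence(self, rng):
        X, y = blobs(rng, n_per_class=30)
        subjects = np.tile([f"S{i}" for i in range(3)], 20)
        table = feature_frame(X, y, subjects=subjects)
        res = cross_validate(ModelSpec(family="logistic", seed=1), table, "loso")
        text = res.summary()
        assert "loso" in text and "balanced accuracy" in text

    def test_decoder_results_predict_roundtrip(self, rng):
        X, y = blobs(rng)
        table = feature_frame(X, y)
        fitted = PurchaseDecoder(table, ModelSpec(family="lda")).fit()
        assert fitted.score(table) == 1.0
        assert "lda" in fitted.summary()

    def test_svm_iteration_cap_flags_nonconvergence(self, rng):
        X, y = blobs(rng, n_per_class=100, separation=0.3)
        table = feature_frame(X, y)
        res = PurchaseDecoder(table, ModelSpec(family="svm", svm_max_iter=2)).fit()
        assert res.converged is False
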
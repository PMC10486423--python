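"""Hold-out evaluation: splitting, metric identities, classifier contract."""

import numpy as np
import pytest
from sklearn.metrics import accuracy_score, f1_score

from lesionselect import (
    CLASSIFIER_PRESETS,
    ConfusionCounts,
    LabelVector,
    SelectionMask,
    SelectorConfig,
    compare_conditions,
    evaluate,
    holdout_split,
    make_classifier,
    metrics_from_counts,
)
from lesionselect.fusion import fuse
from lesionselect.gwo import GWOConfig
from lesionselect.harness import counts_from_predictions


def _ph2_like_labels():
    return LabelVector(labels=("benign",) * 160 + ("melanoma",) * 40)


class TestHoldoutSplit:
    def test_ph2_like_sizes(self):
        train, test = holdout_split(_ph2_like_labels(), 0.7, seed=0)
        assert (len(train), len(test)) == (140, 60)

    def test_disjoint_exhaustive_stratified(self):
        labels = _ph2_like_labels()
        train, test = holdout_split(labels, 0.7, seed=4)
        assert len(np.intersect1d(train, test)) == 0
        assert len(train) + len(test) == 200
        y = labels.as_array()
        for c, n_c in (("benign", 160), ("melanoma", 40)):
            frac = np.sum(y[train] == c) / n_c
            assert abs(frac - 0.7) <= 1.0 / n_c  # within one sample of 70%

    def test_seeded_repeat_identical(self):
        labels = _ph2_like_labels()
        a = holdout_split(labels, 0.7, seed=9)
        b = holdout_split(labels, 0.7, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_small_class_rejected(self):
        labels = LabelVector(labels=("a", "a", "a", "b"))
        with pytest.raises(ValueError, match="fewer than 2"):
            holdout_split(labels, 0.7, seed=0)


class TestMetrics:
    def test_hand_arithmetic_panel(self):
        m = metrics_from_counts(ConfusionCounts(TP=9, FN=1, TN=8, FP=2))
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["f1"] == pytest.approx(18 / 21)

    def test_complement_identities_exact(self):
        m = metrics_from_counts(ConfusionCounts(TP=25, FN=5, TN=48, FP=3))
        assert m["fnr"] + m["sensitivity"] == 1.0
        assert m["fpr"] + m["specificity"] == 1.0

    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(TP=12, FN=0, TN=28, FP=0))
        assert (m["accuracy"], m["f1"], m["fnr"], m["fpr"]) == (1.0, 1.0, 0.0, 0.0)

    def test_zero_denominator_reported_as_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = metrics_from_counts(ConfusionCounts(TP=0, FN=0, TN=10, FP=2))
        assert np.isnan(m["sensitivity"]) and np.isnan(m["fnr"])

    def test_matches_sklearn_on_random_predictions(self, rng):
        y_true = rng.choice(["benign", "melanoma"], size=80, p=[0.7, 0.3])
        y_pred = rng.choice(["benign", "melanoma"], size=80, p=[0.6, 0.4])
        counts = counts_from_predictions(y_true, y_pred, "melanoma")
        m = metrics_from_counts(counts)
        assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
        assert m["f1"] == pytest.approx(
            f1_score(y_true, y_pred, pos_label="melanoma")
        )


class TestClassifierContract:
    @pytest.mark.parametrize("preset", sorted(CLASSIFIER_PRESETS))
    def test_each_preset_fits_and_predicts(self, preset, tiny_synthetic):
        dataset, _ = tiny_synthetic
        X = np.asarray(fuse(dataset.blocks).values)
        y = dataset.labels.as_array()
        model = make_classifier(preset, seed=0)
        model.fit(X, y)
        pred = model.predict(X)
        assert pred.shape == y.shape
        assert set(pred) <= set(y)

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            make_classifier("mystery-model")


class TestEvaluate:
    def test_separable_data_fine_knn_perfect(self):
        rng = np.random.default_rng(0)
        n = 40
        X = np.vstack([rng.normal(-5, 0.2, (n, 4)), rng.normal(5, 0.2, (n, 4))])
        labels = LabelVector(labels=("benign",) * n + ("melanoma",) * n)
        report = evaluate(X, labels, spec="fine-knn", seed=1)
        assert report.metrics["accuracy"] == 1.0

    def test_all_ones_mask_equals_no_mask(self, tiny_synthetic):
        dataset, _ = tiny_synthetic
        fused = fuse(dataset.blocks)
        ones = SelectionMask(bits=np.ones(fused.d_fused, dtype=int))
        r_none = evaluate(fused, dataset.labels, mask=None, spec="fine-knn", seed=3)
        r_ones = evaluate(fused, dataset.labels, mask=ones, spec="fine-knn", seed=3)
        assert r_none.counts == r_ones.counts
        assert r_none.metrics == r_ones.metrics

    def test_seeded_repeat_identical(self, tiny_synthetic):
        dataset, _ = tiny_synthetic
        fused = fuse(dataset.blocks)
        r1 = evaluate(fused, dataset.labels, spec="medium-knn", seed=5)
        r2 = evaluate(fused, dataset.labels, spec="medium-knn", seed=5)
        assert r1.counts == r2.counts


class TestCompareConditions:
    def test_row_count_and_identity_mask(self, tiny_synthetic):
        dataset, _ = tiny_synthetic
        fused = fuse(dataset.blocks)
        ones = SelectionMask(bits=np.ones(fused.d_fused, dtype=int))
        table, summary = compare_conditions(
            fused, dataset.labels, ones, ["fine-knn", "medium-knn", "linear-svm"],
            seeds=[1, 2, 3, 4, 5],
        )
        assert len(table) == 30  # 3 classifiers × 2 conditions × 5 seeds
        pivot = table.pivot_table(
            index=["classifier", "seed"], columns="condition", values="accuracy_pct"
        )
        np.testing.assert_allclose(
            pivot["fused-only"], pivot["fused+selected"]
        )  # identity mask ⇒ identical accuracy

    def test_no_test_leakage_canary(self, tiny_synthetic):
        """Shuffling test-row labels must not change the learned mask or the
        test-set predictions (all fitting is train-rows-only)."""
        dataset, _ = tiny_synthetic
        fused = fuse(dataset.blocks)
        X = np.asarray(fused.values)
        labels = dataset.labels
        seed = 2
        train_idx, test_idx = holdout_split(labels, 0.7, seed)

        shuffled = np.array(labels.labels, dtype=object)
        rng = np.random.default_rng(0)
        shuffled[test_idx] = rng.permutation(shuffled[test_idx])
        labels_shuffled = LabelVector(
            labels=tuple(shuffled), classes=labels.classes,
            positive_class=labels.positive_class,
        )

        cfg = SelectorConfig(
            gwo=GWOConfig(n_wolves=8, n_iterations=10, seed=seed),
            fitness_mode="hybrid",
        )
        masks = {}
        preds = {}
        for tag, lv in (("orig", labels), ("shuf", labels_shuffled)):
            from dataclasses import replace
            from lesionselect import select

            sub = LabelVector(
                labels=tuple(np.asarray(lv.labels)[train_idx]),
                classes=lv.classes, positive_class=lv.positive_class,
            )
            res = select(X[train_idx], cfg, labels=sub)
            masks[tag] = res.mask.bits
            model = make_classifier("fine-knn")
            cols = res.mask.support
            model.fit(X[np.ix_(train_idx, cols)], np.asarray(lv.labels)[train_idx])
            preds[tag] = model.predict(X[np.ix_(test_idx, cols)])
        np.testing.assert_array_equal(masks["orig"], masks["shuf"])
        np.testing.assert_array_equal(preds["orig"], preds["shuf"])
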
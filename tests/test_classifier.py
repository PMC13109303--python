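import numpy as np
import pytest

from xrfseed import DegenerateInputError, PixelSampleTable
from xrfseed.classifier import (
    MODEL_ORDER,
    ModelMetrics,
    evaluate_and_select,
    extract_features,
    predict_seed_mask,
    split_dataset,
    train_models,
)
from xrfseed.synth import generate_pixel_dataset


class TestExtractFeatures:
    def test_hexcone_reference_pixels(self):
        img = np.array([[[255, 0, 0], [128, 128, 128]]], np.uint8)
        feats = extract_features(img).features
        np.testing.assert_allclose(feats[0], [1, 0, 0, 0, 1, 1], atol=1e-6)
        r, g, b, h, s, v = feats[1]
        assert s == 0.0
        assert v == pytest.approx(128 / 255)

    def test_one_row_per_pixel_and_mask_restriction(self, rng):
        img = rng.integers(0, 256, size=(7, 9, 3)).astype(np.uint8)
        assert len(extract_features(img)) == 63
        mask = np.zeros((7, 9), bool)
        mask[0, 0] = mask[3, 4] = True
        assert len(extract_features(img, mask)) == 2


class TestSplitDataset:
    def test_printed_8_2_split_counts(self):
        table = generate_pixel_dataset(n_records=4416, rng_seed=0)
        train, test = split_dataset(table, 0.8, rng_seed=0)
        assert (len(train), len(test)) == (3532, 884)

    def test_small_n(self):
        table = generate_pixel_dataset(n_records=10, rng_seed=0)
        train, test = split_dataset(table, 0.8, rng_seed=0)
        assert (len(train), len(test)) == (8, 2)

    def test_deterministic_partition(self):
        table = generate_pixel_dataset(n_records=100, rng_seed=0)
        a = split_dataset(table, 0.8, rng_seed=5)
        b = split_dataset(table, 0.8, rng_seed=5)
        assert np.array_equal(a[0].features, b[0].features)
        assert np.array_equal(a[1].labels, b[1].labels)

    def test_partition_property(self):
        table = generate_pixel_dataset(n_records=101, rng_seed=3)
        train, test = split_dataset(table, 0.8, rng_seed=1)
        combined = np.vstack([train.features, test.features])
        assert len(combined) == 101
        # every original row appears exactly once
        orig = table.features[np.lexsort(table.features.T)]
        got = combined[np.lexsort(combined.T)]
        assert np.array_equal(orig, got)

    def test_single_class_rejected(self):
        table = PixelSampleTable(np.random.rand(10, 6), np.ones(10, bool))
        with pytest.raises(DegenerateInputError):
            split_dataset(table, 0.8, 0)


class TestMetrics:
    def test_perfect_prediction(self):
        m = ModelMetrics.from_counts(tp=50, fp=0, fn=0, tn=50)
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_hand_computed_confusion_matrix(self):
        m = ModelMetrics.from_counts(tp=40, fp=10, fn=20, tn=30)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(8 / 11)
        assert m.accuracy == pytest.approx(0.7)

    def test_all_negative_predictor_flagged(self):
        m = ModelMetrics.from_counts(tp=0, fp=0, fn=50, tn=50)
        assert m.recall == 0.0 and m.f1 == 0.0
        assert "precision" in m.undefined


class TestTrainAndSelect:
    def test_all_models_near_perfect_on_separable_data(self, separable_models):
        _, report, _ = separable_models
        for name in MODEL_ORDER:
            assert report.per_model[name].accuracy >= 0.99

    def test_metrics_match_brute_force_counting(self, separable_models):
        models, report, test = separable_models
        for name in MODEL_ORDER:
            pred = np.asarray(models[name].predict(test.features)).astype(bool)
            tp = sum(bool(p) and bool(t) for p, t in zip(pred, test.labels))
            fp = sum(bool(p) and not t for p, t in zip(pred, test.labels))
            fn = sum(not p and bool(t) for p, t in zip(pred, test.labels))
            tn = sum(not p and not t for p, t in zip(pred, test.labels))
            m = report.per_model[name]
            assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
            assert m.accuracy == pytest.approx((tp + tn) / len(test.labels))

    def test_selection_maximises_f1(self, separable_models):
        _, report, _ = separable_models
        best = max(m.f1 for m in report.per_model.values())
        assert report.per_model[report.selected_model].f1 == best

    def test_chance_level_on_inseparable_data(self):
        table = generate_pixel_dataset(n_records=1000, separability=0.0, rng_seed=4)
        train, test = split_dataset(table, 0.8, rng_seed=4)
        models = train_models(train, rng_seed=4)
        report = evaluate_and_select(models, test)
        for m in report.per_model.values():
            assert 0.4 <= m.accuracy <= 0.6

    def test_f1_monotone_in_separability(self):
        scores = []
        for sep in (0.0, 2.0, 5.0, 10.0):
            table = generate_pixel_dataset(n_records=1000, separability=sep, rng_seed=9)
            train, test = split_dataset(table, 0.8, rng_seed=9)
            models = train_models(train, rng_seed=9)
            report = evaluate_and_select(models, test)
            scores.append(report.per_model[report.selected_model].f1)
        assert scores == sorted(scores)

    def test_svm_separates_linearly_separable_points(self):
        feats = np.zeros((8, 6))
        feats[:4, 0] = [0.1, 0.12, 0.15, 0.11]
        feats[4:, 0] = [0.9, 0.88, 0.85, 0.91]
        feats[:, 1:] = 0.5
        labels = np.array([False] * 4 + [True] * 4)
        table = PixelSampleTable(feats, labels)
        models = train_models(table, rng_seed=0)
        pred = models["svm"].predict(feats).astype(bool)
        assert np.array_equal(pred, labels)

    def test_constant_features_rejected(self):
        table = PixelSampleTable(
            np.full((10, 6), 0.5), np.array([True] * 5 + [False] * 5)
        )
        with pytest.raises(DegenerateInputError):
            train_models(table)


class TestPredictSeedMask:
    def test_near_perfect_mask_on_noiseless_fixture(self, default_layout, separable_models):
        rgb, _, gt = default_layout
        from xrfseed.synth import pixel_table_from_layout

        table = pixel_table_from_layout(rgb, gt, rng_seed=0)
        train, _ = split_dataset(table, 0.8, 0)
        models = train_models(train, 0)
        mask = predict_seed_mask(models["xgboost"], rgb)
        truth = gt.seed_labels > 0
        assert (mask == truth).mean() >= 0.99

    def test_empty_restriction_gives_empty_mask(self, default_layout, separable_models):
        rgb, _, _ = default_layout
        models, _, _ = separable_models
        mask = predict_seed_mask(models["knn"], rgb, np.zeros(rgb.shape[:2], bool))
        assert not mask.any()

    def test_deterministic(self, default_layout, separable_models):
        rgb, _, _ = default_layout
        models, report, _ = separable_models
        model = models[report.selected_model]
        sub = rgb[:60, :60]
        assert np.array_equal(predict_seed_mask(model, sub), predict_seed_mask(model, sub))
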
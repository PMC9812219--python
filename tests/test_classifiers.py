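"""Target classification: features, baselines, CNNs, importance, scores."""

import dataclasses

import numpy as np
import pytest

import cryotarget as ct
from cryotarget.features import (
    FEATURE_NAMES,
    FEATURE_NAMES_5,
    feature_matrix,
    permutation_importance,
    square_features,
    train_square_baselines,
    unet_score_classifier,
)
from cryotarget.lattice import HoleCrop
from cryotarget.nn.classifiers import (
    HoleCNN,
    HoleCNNConfig,
    SquareCNNConfig,
    hole_cnn_forward,
    load_classifier,
    save_classifier,
    train_hole_cnn,
    train_square_cnn,
)


class TestSquareFeatures:
    def test_constant_crop_conventions(self):
        f = square_features(np.full((10, 10), 2.5))
        assert f.variance == 0.0
        assert f.skew == 0.0 and f.kurtosis == 0.0
        assert f.area == 100

    def test_moments_against_hand_computation(self):
        # pixels {1,2,3,6}: mean 3, var 3.5, skew 4.5/3.5^1.5, kurt -1
        f = square_features(np.array([[1.0, 2.0], [3.0, 6.0]]))
        assert f.mean_intensity == pytest.approx(3.0)
        assert f.variance == pytest.approx(3.5)
        assert f.skew == pytest.approx(4.5 / 3.5 ** 1.5, abs=1e-6)
        assert f.kurtosis == pytest.approx(-1.0, abs=1e-6)
        assert f.min_intensity == 1.0 and f.max_intensity == 6.0

    def test_csv_roundtrip(self, tmp_path):
        from cryotarget.features import features_from_csv, features_to_csv

        rng = np.random.default_rng(3)
        feats = [square_features(rng.normal(size=(8, 8))) for _ in range(5)]
        p = tmp_path / "features.csv"
        features_to_csv(p, feats)
        back = features_from_csv(p)
        for a, b in zip(feats, back):
            assert np.allclose(a.as_array(), b.as_array())

    def test_transposition_invariance(self):
        rng = np.random.default_rng(0)
        crop = rng.normal(size=(6, 9))
        a, b = square_features(crop), square_features(crop.T)
        for name in FEATURE_NAMES:
            assert getattr(a, name) == pytest.approx(getattr(b, name))


def _synthetic_feature_set(n, seed, label_fn):
    """Random feature rows with labels from a stated rule."""
    rng = np.random.default_rng(seed)
    feats = []
    for _ in range(n):
        side = rng.integers(8, 32)
        level = rng.uniform(-1, 1)
        crop = rng.normal(level, 1.0, (side, side))
        feats.append(square_features(crop))
    labels = np.array([label_fn(f) for f in feats])
    return feats, labels


class TestBaselines:
    def test_separable_labels_learned(self):
        feats, labels = _synthetic_feature_set(
            400, 1, lambda f: f.area > 400)
        lr, rf = train_square_baselines(feats[:300], labels[:300], seed=0)
        X = feature_matrix(feats[300:])
        from cryotarget.evaluate import ranking_metrics

        for model in (lr, rf):
            auc, _, acc = ranking_metrics(model.predict_proba(X)[:, 1],
                                          labels[300:])
            assert acc >= 0.95

    def test_permuted_labels_near_chance(self):
        feats, labels = _synthetic_feature_set(400, 2, lambda f: f.area > 400)
        rng = np.random.default_rng(3)
        shuffled = rng.permutation(labels[:300])
        lr, rf = train_square_baselines(feats[:300], shuffled, seed=0)
        from cryotarget.evaluate import ranking_metrics

        X = feature_matrix(feats[300:])
        auc, _, _ = ranking_metrics(rf.predict_proba(X)[:, 1], labels[300:])
        assert abs(auc - 0.5) < 0.1

    def test_single_class_rejected(self):
        feats, _ = _synthetic_feature_set(20, 4, lambda f: True)
        with pytest.raises(ValueError):
            train_square_baselines(feats, np.ones(20, bool), seed=0)

    def test_deterministic_given_seed(self):
        feats, labels = _synthetic_feature_set(120, 5, lambda f: f.area > 380)
        X = feature_matrix(feats)
        _, rf1 = train_square_baselines(feats, labels, seed=7)
        _, rf2 = train_square_baselines(feats, labels, seed=7)
        assert np.array_equal(rf1.predict_proba(X), rf2.predict_proba(X))

    def test_five_feature_variant_constructible(self):
        feats, labels = _synthetic_feature_set(100, 6, lambda f: f.area > 380)
        lr, rf = train_square_baselines(feats, labels, seed=0,
                                        feature_set="five")
        assert rf.n_features_in_ == len(FEATURE_NAMES_5) == 5


class TestPermutationImportance:
    def test_constant_feature_zero_importance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        X[:, 1] = 5.0
        y = (X[:, 0] > 0).astype(int)
        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        rep = permutation_importance(rf, X, y, n_repeats=5, seed=0,
                                     feature_set="five")
        # report carries one entry per feature column
        assert len(rep.importances_mean) == 3
        assert rep.importances_mean[1] == pytest.approx(0.0, abs=1e-12)

    def test_area_dependence_ranked_top(self):
        feats, labels = _synthetic_feature_set(400, 7, lambda f: f.area > 400)
        _, rf = train_square_baselines(feats, labels, seed=0)
        rep = permutation_importance(rf, feats, labels, n_repeats=10, seed=0)
        assert rep.top_features(1) == ["area"]

    def test_reproducible_under_seed(self):
        feats, labels = _synthetic_feature_set(150, 8, lambda f: f.area > 380)
        _, rf = train_square_baselines(feats, labels, seed=0)
        a = permutation_importance(rf, feats, labels, n_repeats=5, seed=3)
        b = permutation_importance(rf, feats, labels, n_repeats=5, seed=3)
        assert np.array_equal(a.importances_mean, b.importances_mean)


class TestSquareCNN:
    def test_learns_intact_vs_broken(self):
        # crops from broken-square scenes: intact should outrank broken
        spec = ct.GridSceneSpec(256, 256, 64, 40, 15.0, 4, 40,
                                broken_fraction=0.5, seed=0)
        crops, labels = [], []
        for s in range(10):
            scene = ct.generate_grid_scene(
                dataclasses.replace(spec, seed=s))
            fit = ct.fit_poisson_mixture(scene.image)
            mask = ct.segment_squares(scene.image, fit)
            polys = ct.extract_polygons(mask)
            boxset = ct.find_optimal_angle(polys)
            cs = ct.crop_squares(scene.image, boxset)
            from cryotarget.evaluate import match_boxes

            mr = match_boxes([c.source_box for c in cs], scene.true_boxes)
            for rec in mr.assignments:
                crops.append(cs[rec["pred"]])
                labels.append(bool(scene.selected_labels[rec["true"]]))
        labels = np.array(labels)
        split = int(0.7 * len(crops))
        cfg = SquareCNNConfig(input_side=32, channels=(4, 8), epochs=20,
                              lr=3e-3, seed=0)
        model = train_square_cnn(crops[:split], labels[:split], cfg)
        scores = np.array([model.score(c) for c in crops[split:]])
        held = labels[split:]
        assert held.any() and (~held).any()
        assert ((scores >= 0) & (scores <= 1)).all()
        assert scores[held].mean() > scores[~held].mean()

    def test_deterministic_scores(self):
        rng = np.random.default_rng(1)
        crops = [rng.normal(size=(20, 20)) for _ in range(20)]
        labels = np.arange(20) % 2 == 0
        cfg = SquareCNNConfig(input_side=16, channels=(4,), epochs=2, seed=3)
        m1 = train_square_cnn(crops, labels, cfg)
        m2 = train_square_cnn(crops, labels, cfg)
        assert m1.score(crops[0]) == m2.score(crops[0])


class TestHoleCNN:
    def test_average_pool_size_invariant_on_uniform_crops(self):
        cfg = HoleCNNConfig(mode="average_pool", channels=(4, 8), seed=0)
        model = HoleCNN(cfg)
        a = model.score(np.full((32, 32), 0.7))
        b = model.score(np.full((64, 64), 0.7))
        assert a == pytest.approx(b, abs=1e-3)

    def test_average_pool_translation_tolerance(self):
        cfg = HoleCNNConfig(mode="average_pool", channels=(4, 8), seed=1)
        model = HoleCNN(cfg)

        def crop_with_blob(r, c):
            crop = np.zeros((64, 64))
            crop[r:r + 5, c:c + 5] = 1.0
            return crop

        s1 = model.score(crop_with_blob(20, 20))
        s2 = model.score(crop_with_blob(35, 28))
        assert abs(s1 - s2) < 1e-3

    def test_padded_rejects_oversized_crop(self):
        model = HoleCNN(HoleCNNConfig(mode="padded", pad_side=32, seed=0))
        with pytest.raises(ValueError):
            model.score(np.zeros((48, 48)))

    def test_too_small_crop_rejected(self):
        model = HoleCNN(HoleCNNConfig(mode="average_pool", channels=(4, 8, 8)))
        with pytest.raises(ValueError):
            model.score(np.zeros((3, 3)))

    def test_variants_share_hyperparameters(self):
        padded = HoleCNNConfig(mode="padded")
        pooled = HoleCNNConfig(mode="average_pool")
        assert padded.hyperparameters() == pooled.hyperparameters()

    def test_learns_clean_vs_contaminated(self):
        rng = np.random.default_rng(2)
        crops, labels = [], []
        for i in range(120):
            crop = rng.normal(0, 0.1, (24, 24))
            rr, cc = np.mgrid[0:24, 0:24]
            crop[(rr - 12) ** 2 + (cc - 12) ** 2 <= 49] += 1.0
            clean = i % 2 == 0
            if not clean:
                r0, c0 = rng.integers(4, 20, 2)
                crop[(rr - r0) ** 2 + (cc - c0) ** 2 <= 16] = -1.5
            crops.append(crop)
            labels.append(clean)
        labels = np.array(labels)
        cfg = HoleCNNConfig(mode="average_pool", channels=(4, 8), epochs=6,
                            lr=3e-3, seed=0)
        model = train_hole_cnn(crops[:80], labels[:80], cfg)
        scores = np.array([hole_cnn_forward(model, c) for c in crops[80:]])
        from cryotarget.evaluate import ranking_metrics

        auc, _, _ = ranking_metrics(scores, labels[80:])
        assert auc >= 0.8

    def test_checkpoint_roundtrip(self, tmp_path):
        model = HoleCNN(HoleCNNConfig(mode="average_pool", channels=(4,), seed=9))
        p = tmp_path / "clf.npz"
        save_classifier(p, model)
        loaded = load_classifier(p)
        crop = np.random.default_rng(0).normal(size=(16, 16))
        assert model.score(crop) == loaded.score(crop)


class TestUnetScoreClassifier:
    def _crops(self, scores):
        return [HoleCrop(pixels=np.zeros((4, 4)),
                         normalized_pixels=np.zeros((4, 4)),
                         center=np.array([float(i), 0.0]), unet_score=s)
                for i, s in enumerate(scores)]

    def test_all_zero_scores(self):
        targets = unet_score_classifier(self._crops([0.0, 0.0, 0.0]))
        assert all(t.score == 0.0 for t in targets)

    def test_ranking_matches_raw_sums(self):
        raw = [3.0, 11.0, 7.0, 0.5]
        targets = unet_score_classifier(self._crops(raw))
        got = [t.location[0] for t in targets]
        expected = list(np.argsort(-np.array(raw), kind="stable").astype(float))
        assert got == expected
        assert targets[0].score == 1.0  # rescaled by per-image max
        assert [t.rank for t in targets] == [1, 2, 3, 4]
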
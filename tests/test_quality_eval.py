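"""Quality metric: HOG/LBP features, calibrated SVM, binned KL divergence."""

import numpy as np
import pytest
from scipy.special import rel_entr

import capgan as cg
from capgan.quality_eval import BinnedDistribution, FeatureParams, _binned

from _oracles import kl_reference


class TestHog:
    def test_constant_image_zero_descriptor(self):
        assert np.allclose(cg.hog_features(np.full((32, 32), 80.0)), 0.0)

    def test_fixed_length_for_fixed_geometry(self, rng):
        lengths = {cg.hog_features(rng.uniform(0, 255, size=(64, 64))).shape[0]
                   for _ in range(5)}
        assert len(lengths) == 1

    def test_vertical_edge_dominates_one_orientation(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 200.0  # vertical edge -> horizontal gradient
        desc = cg.hog_features(img).reshape(-1, 9)
        mass = desc.sum(axis=0)
        assert mass.argmax() == 0  # gradient along +x falls in the first bin

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            cg.hog_features(np.zeros((4, 4)))


class TestLbp:
    def test_histogram_sums_to_one(self, rng):
        h = cg.lbp_features(rng.integers(0, 255, size=(32, 32)))
        assert np.isclose(h.sum(), 1.0)

    def test_monotone_intensity_invariance(self, rng):
        img = rng.integers(40, 180, size=(32, 32)).astype(float)
        assert np.allclose(cg.lbp_features(img), cg.lbp_features(img + 10.0))

    def test_constant_image_flat_pattern_dominates(self):
        s = 32
        h = cg.lbp_features(np.full((s, s), 100))
        # every interior pixel carries the all-ones "flat" pattern (bin P);
        # only border pixels, whose neighbourhoods leave the image, differ
        assert h.argmax() == 8
        assert h.max() >= (s - 2) ** 2 / s ** 2


class TestCascade:
    def test_lengths_add_and_order_fixed(self, rng):
        img = rng.integers(0, 255, size=(64, 64))
        h, l = cg.hog_features(img), cg.lbp_features(img)
        c = cg.cascade(h, l)
        assert len(c) == len(h) + len(l)
        assert np.array_equal(c[:len(h)], h) and np.array_equal(c[len(h):], l)
        assert np.array_equal(c, cg.cascade(h, l))


class TestClassifier:
    def test_separable_blobs_high_accuracy(self, rng):
        X = np.concatenate([rng.normal(0, 1, size=(60, 5)), rng.normal(6, 1, size=(60, 5))])
        y = np.array([0] * 60 + [1] * 60)
        model = cg.train_eval_classifier(X, y, seed=0)
        assert model.score(X, y) >= 0.95

    def test_probabilities_normalised(self, rng):
        X = np.concatenate([rng.normal(0, 1, size=(30, 4)), rng.normal(3, 1, size=(30, 4))])
        y = np.array([0] * 30 + [1] * 30)
        model = cg.train_eval_classifier(X, y, seed=0)
        probs = model.predict_proba(X)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 4))
        y = (X[:, 0] > 0).astype(int)
        m1 = cg.train_eval_classifier(X, y, seed=1)
        m2 = cg.train_eval_classifier(X, y, seed=1)
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            cg.train_eval_classifier(rng.normal(size=(10, 3)), np.zeros(10))


class TestBinnedDistribution:
    def test_normalisation_enforced(self):
        with pytest.raises(ValueError):
            BinnedDistribution(np.linspace(0, 1, 4), np.array([0.5, 0.2, 0.2]))

    def test_smoothed_histogram_sums_to_one(self, rng):
        d = _binned(rng.uniform(0, 1, size=200), n_bins=10, smoothing=None)
        assert np.isclose(d.probabilities.sum(), 1.0)
        assert np.all(d.probabilities > 0)  # smoothing floor

    def test_duplication_invariance(self, rng):
        p = rng.uniform(0, 1, size=100)
        d1 = _binned(p, 10, None)
        d2 = _binned(np.concatenate([p, p]), 10, None)
        assert np.allclose(d1.probabilities, d2.probabilities)


class TestKlDivergence:
    def _dist(self, probs):
        probs = np.asarray(probs, float)
        return BinnedDistribution(np.linspace(0, 1, len(probs) + 1), probs)

    def test_self_divergence_zero(self):
        d = self._dist([0.2, 0.3, 0.5])
        assert cg.kl_divergence(d, d) == 0.0

    def test_hand_computed_log2(self):
        assert np.isclose(cg.kl_divergence(self._dist([1.0, 0.0]), self._dist([0.5, 0.5])),
                          np.log(2.0), atol=1e-12)

    def test_hand_computed_mixed(self):
        got = cg.kl_divergence(self._dist([0.5, 0.5]), self._dist([0.25, 0.75]))
        expected = 0.5 * np.log(2.0) + 0.5 * np.log(2.0 / 3.0)
        assert np.isclose(got, expected, atol=1e-12)
        assert np.isclose(got, 0.1438, atol=5e-5)

    def test_nonnegative_and_matches_scipy(self, rng):
        for _ in range(300):
            k = rng.integers(2, 12)
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            d = cg.kl_divergence(self._dist(p), self._dist(q))
            assert d >= 0
            assert np.isclose(d, rel_entr(p, q).sum(), atol=1e-12)
            assert np.isclose(d, kl_reference(p, q), atol=1e-12)

    def test_asymmetry(self):
        P, Q = self._dist([0.9, 0.1]), self._dist([0.5, 0.5])
        assert cg.kl_divergence(P, Q) != cg.kl_divergence(Q, P)

    def test_binning_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cg.kl_divergence(self._dist([0.5, 0.5]), self._dist([0.2, 0.3, 0.5]))


@pytest.fixture(scope="module")
def classifier(phantoms16):
    images, _ = phantoms16
    return cg.train_realism_classifier(images, seed=0), images


class TestEvaluateGenerated:

    def test_identical_sets_score_zero(self, classifier):
        model, images = classifier
        params = cg.FeatureParams(hog_cell=4)
        assert cg.evaluate_generated(images, images, model, 10, params) == 0.0

    def test_order_invariance(self, classifier, rng):
        model, images = classifier
        params = cg.FeatureParams(hog_cell=4)
        fake = cg.make_unstructured_negatives(images, seed=5)
        k1 = cg.evaluate_generated(images, fake, model, 10, params)
        k2 = cg.evaluate_generated(images, fake[rng.permutation(len(fake))], model, 10, params)
        assert np.isclose(k1, k2, atol=1e-12)

    def test_noise_scores_worse_than_held_out_real(self, classifier):
        model, images = classifier
        params = cg.FeatureParams(hog_cell=4)
        spec = cg.PhantomSpec(image_size=16, n_shells=3,
                              intensity_levels=(200, 130, 80), seed=43)
        held_out, _ = cg.generate_phantoms(64, spec)
        noise = np.random.default_rng(3).integers(0, 256, size=images.shape).astype(np.uint8)
        kl_real = cg.evaluate_generated(images, held_out, model, 10, params)
        kl_noise = cg.evaluate_generated(images, noise, model, 10, params)
        assert kl_noise > kl_real
        assert kl_real < 0.05

    def test_count_mismatch_rejected(self, classifier):
        model, images = classifier
        with pytest.raises(ValueError, match="counts differ"):
            cg.evaluate_generated(images, images[:-1], model)


class TestPersistence:
    def test_classifier_round_trip(self, tmp_path, rng):
        X = np.concatenate([rng.normal(0, 1, size=(30, 4)), rng.normal(3, 1, size=(30, 4))])
        y = np.array([0] * 30 + [1] * 30)
        model = cg.train_eval_classifier(X, y, seed=0)
        params = FeatureParams(hog_cell=4)
        path = tmp_path / "clf.joblib"
        cg.save_classifier(model, path, params)
        loaded, loaded_params = cg.load_classifier(path)
        assert loaded_params == params
        assert np.array_equal(loaded.predict_proba(X), model.predict_proba(X))
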
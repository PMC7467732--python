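"""Shape dataset, softmax classifier contract, attacks, transferability, preprocessing."""

import numpy as np
import pytest

from advagree.attacks import (
    ArchConfig,
    AttackConfig,
    AttackResult,
    ClassifierHandle,
    EAConfig,
    PreprocessSpec,
    class_templates,
    direct_encoding_ea_attack,
    ensemble_transfer_filter,
    iterative_gradient_attack,
    make_shape_dataset,
    preprocess_centre_crop_normalize,
    train_classifier,
)


def linear_handle(W, b, shape):
    """Hand-built softmax ClassifierHandle with known weights (analytic oracle)."""
    from scipy.special import softmax

    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)

    def predict_proba(img):
        return softmax(W @ np.asarray(img, dtype=float).reshape(-1) + b)

    def input_gradient(img, t):
        p = predict_proba(img)
        return (W[t] - p @ W).reshape(shape)

    return ClassifierHandle(
        n_classes=len(W), predict_proba=predict_proba,
        input_gradient=input_gradient, name="linear", input_shape=shape,
    )


class TestShapeDataset:
    def test_sizes_and_uniform_label_histogram(self, rng):
        data = make_shape_dataset(10, 100, 32, 0.1, rng)
        assert data.images.shape == (1000, 32, 32)
        assert np.bincount(data.labels).tolist() == [100] * 10
        assert data.images.min() >= 0 and data.images.max() <= 1

    def test_noise_free_classes_separable_by_nearest_centroid(self, rng):
        data = make_shape_dataset(6, 10, 16, 0.0, rng)
        _, tpls = class_templates(6, 16)
        flat_t = tpls.reshape(6, -1)
        pred = np.argmin(
            ((data.images.reshape(len(data.labels), -1)[:, None, :] - flat_t[None]) ** 2).sum(-1),
            axis=1,
        )
        assert np.array_equal(pred, data.labels)

    def test_fixed_seed_regenerates_byte_identical(self):
        d1 = make_shape_dataset(5, 20, 16, 0.2, np.random.default_rng(3))
        d2 = make_shape_dataset(5, 20, 16, 0.2, np.random.default_rng(3))
        assert np.array_equal(d1.images, d2.images)
        assert np.array_equal(d1.labels, d2.labels)

    def test_too_many_classes_rejected(self, rng):
        with pytest.raises(ValueError, match="pattern families"):
            make_shape_dataset(99, 10, 16, 0.0, rng)


class TestTrainClassifier:
    def test_probabilities_sum_to_one_on_random_inputs(self, shape_classifier, rng):
        for _ in range(100):
            p = shape_classifier.predict_proba(rng.random((32, 32)))
            assert p.shape == (10,)
            assert abs(p.sum() - 1.0) < 1e-6
            assert np.all(p >= 0)

    def test_held_out_accuracy(self, shape_classifier):
        fresh = make_shape_dataset(10, 30, 32, 0.15, np.random.default_rng(991))
        acc = np.mean(
            [shape_classifier.predict(im) == y for im, y in zip(fresh.images, fresh.labels)]
        )
        assert acc >= 0.95

    def test_noise_free_training_is_perfect(self, rng):
        data = make_shape_dataset(4, 15, 16, 0.0, rng)
        clf = train_classifier(data, rng=rng)
        acc = np.mean([clf.predict(im) == y for im, y in zip(data.images, data.labels)])
        assert acc == 1.0

    def test_input_gradient_matches_finite_differences(self, shape_classifier, rng):
        x = rng.random((32, 32))
        target = 4
        g = shape_classifier.input_gradient(x, target)
        assert g.shape == (32, 32)
        eps = 1e-5
        for i, j in [(1, 2), (15, 16), (30, 5)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            fd = (
                np.log(shape_classifier.predict_proba(xp)[target])
                - np.log(shape_classifier.predict_proba(xm)[target])
            ) / (2 * eps)
            assert abs(fd - g[i, j]) / max(abs(fd), 1e-8) < 1e-3

    def test_binary_classifier_contract(self, rng):
        data = make_shape_dataset(2, 15, 16, 0.1, rng)
        clf = train_classifier(data, rng=rng)
        p = clf.predict_proba(data.images[0])
        assert p.shape == (2,)
        assert abs(p.sum() - 1.0) < 1e-9

    def test_too_few_images_per_class_rejected(self, rng):
        data = make_shape_dataset(3, 12, 16, 0.1, rng)
        data.labels[:] = 0
        data.labels[:5] = 1
        data.labels[5:10] = 2
        with pytest.raises(ValueError, match=">= 10"):
            train_classifier(data, rng=rng)


class TestIterativeGradientAttack:
    def test_two_class_linear_oracle(self):
        # 4-pixel logistic model: step direction must equal sign(w1 - w0) and the
        # closed-form iterate clip(x0 + k*step*sign(w1-w0)) reaches >0.99
        w = np.array([2.0, -8.0, 12.0, -4.0])  # saturated logit 14 => conf ~ 1
        clf = linear_handle(np.vstack([-w / 2, w / 2]), [0.0, 0.0], (4,))
        cfg = AttackConfig(step_size=0.05, max_iterations=400)
        rng_seed = 21
        res = iterative_gradient_attack(clf, 1, cfg, np.random.default_rng(rng_seed))
        assert res.success and res.final_confidence > 0.99
        x0 = np.random.default_rng(rng_seed).uniform(0, 1, 4)
        manual = np.clip(x0 + res.iterations_used * cfg.step_size * np.sign(w), 0, 1)
        assert np.allclose(res.image, manual)

    def test_budget_exhaustion_returns_image_with_success_false(self):
        # zero weights: confidence stuck at 0.5 < threshold
        clf = linear_handle(np.zeros((2, 4)), [0.0, 0.0], (4,))
        res = iterative_gradient_attack(
            clf, 0, AttackConfig(max_iterations=5), np.random.default_rng(0)
        )
        assert not res.success
        assert res.iterations_used == 5
        assert res.image.shape == (4,)

    def test_final_confidence_is_fresh_forward_pass(self, shape_classifier):
        res = iterative_gradient_attack(
            shape_classifier, 2, AttackConfig(max_iterations=300),
            np.random.default_rng(4),
        )
        assert res.final_confidence == pytest.approx(
            float(shape_classifier.predict_proba(res.image)[2])
        )
        assert res.image.min() >= 0 and res.image.max() <= 1

    def test_out_of_range_target_rejected(self, shape_classifier):
        with pytest.raises(ValueError, match="out of range"):
            iterative_gradient_attack(shape_classifier, 10, AttackConfig())

    def test_success_rate_on_shape_classifier(self, shape_classifier):
        # the fooling-image regime: nearly every target reaches >=0.99 in 500 steps
        results = [
            iterative_gradient_attack(
                shape_classifier, t, AttackConfig(), np.random.default_rng(600 + t)
            )
            for t in range(10)
        ]
        assert sum(r.success for r in results) >= 9


class TestDirectEncodingEA:
    def test_best_fitness_monotone_nondecreasing(self, shape_classifier):
        res = direct_encoding_ea_attack(
            shape_classifier, 3, EAConfig(max_generations=40), np.random.default_rng(9)
        )
        assert all(b >= a - 1e-12 for a, b in zip(res.history, res.history[1:]))
        assert res.method == "ea_direct"
        assert res.image.min() >= 0 and res.image.max() <= 1

    def test_one_pixel_brute_force_oracle(self):
        # 1-pixel 2-class linear model: exhaustive search over the 1/255 grid
        # says the optimum saturates at pixel = 1; the EA must find it
        w = np.array([4.0])
        clf = linear_handle(np.vstack([-w, w]), [0.0, 0.0], (1,))
        grid = np.linspace(0, 1, 256)
        best_pixel = grid[np.argmax([clf.predict_proba(np.array([v]))[1] for v in grid])]
        assert best_pixel == 1.0
        res = direct_encoding_ea_attack(
            clf, 1,
            EAConfig(population_size=8, mutation_rate=1.0, mutation_sd=0.3,
                     max_generations=300, confidence_threshold=1.0),
            np.random.default_rng(2),
        )
        assert abs(float(res.image[0]) - best_pixel) < 1 / 255

    def test_zero_mutation_rate_rejected(self):
        with pytest.raises(ValueError, match="mutation_rate"):
            EAConfig(mutation_rate=0.0)

    def test_ea_images_are_noise_like(self, shape_classifier, shape_data):
        # EA fooling images correlate less with class templates than real members do
        res = direct_encoding_ea_attack(
            shape_classifier, 0, EAConfig(max_generations=60), np.random.default_rng(11)
        )
        _, tpls = class_templates(10, 32)

        def mean_abs_corr(img):
            v = img.reshape(-1)
            return np.mean(
                [abs(np.corrcoef(v, t.reshape(-1))[0, 1]) for t in tpls]
            )

        real = shape_data.images[shape_data.labels == 0][:10]
        real_corr = np.mean([mean_abs_corr(im) for im in real])
        assert mean_abs_corr(res.image) < real_corr


class TestEnsembleTransferFilter:
    @staticmethod
    def _const_handle(label, conf=0.95, n_classes=3):
        p = np.full(n_classes, (1 - conf) / (n_classes - 1))
        p[label] = conf

        def predict_proba(img):
            return p

        return ClassifierHandle(n_classes=n_classes, predict_proba=predict_proba,
                                input_gradient=lambda i, t: np.zeros_like(i),
                                name=f"const{label}", input_shape=(2,))

    @staticmethod
    def _cand(target):
        return AttackResult(image=np.zeros(2), target_class=target,
                            final_confidence=0.99, iterations_used=1,
                            success=True, method="gradient")

    def test_single_dissenter_drops_candidate_at_full_k_min(self):
        clfs = [self._const_handle(0), self._const_handle(0), self._const_handle(1)]
        res = ensemble_transfer_filter([self._cand(0)], clfs, k_min=3)
        assert res.retained == []
        assert res.agreement_counts == [2]

    def test_identical_ensemble_reduces_to_single_classifier(self):
        clfs = [self._const_handle(1)] * 10
        cands = [self._cand(0), self._cand(1)]
        res = ensemble_transfer_filter(cands, clfs, k_min=10)
        assert [c.target_class for c in res.retained] == [1]
        assert res.agreement_counts == [0, 10]
        assert res.median_confidence == pytest.approx(0.95)

    def test_hand_enumerated_argmax_table(self):
        # 3 classifiers voting (0,0,1), candidates targeting 0,1,2,0,1 with k_min=2:
        # agreement counts (2,1,0,2,1) -> candidates 0 and 3 retained
        clfs = [self._const_handle(0), self._const_handle(0), self._const_handle(1)]
        cands = [self._cand(t) for t in (0, 1, 2, 0, 1)]
        res = ensemble_transfer_filter(cands, clfs, k_min=2)
        assert res.agreement_counts == [2, 1, 0, 2, 1]
        assert [id(c) for c in res.retained] == [id(cands[0]), id(cands[3])]

    def test_idempotent_and_order_independent(self):
        clfs = [self._const_handle(0), self._const_handle(1)]
        cands = [self._cand(t) for t in (0, 1, 0)]
        first = ensemble_transfer_filter(cands, clfs, k_min=1)
        again = ensemble_transfer_filter(first.retained, clfs, k_min=1)
        assert [id(c) for c in again.retained] == [id(c) for c in first.retained]
        rev = ensemble_transfer_filter(cands[::-1], clfs, k_min=1)
        assert sorted(rev.agreement_counts) == sorted(first.agreement_counts)
        assert rev.median_confidence == pytest.approx(first.median_confidence)

    def test_conf_min_tightens_agreement(self):
        clfs = [self._const_handle(0, conf=0.90)]
        res = ensemble_transfer_filter([self._cand(0)], clfs, k_min=1, conf_min=0.95)
        assert res.retained == []

    def test_empty_classifier_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_transfer_filter([self._cand(0)], [], k_min=0)

    def test_cross_training_transfer_rate_reported(self, shape_classifier):
        # fraction of single-net fooling images passing k_min = n-1 on an
        # independently trained ensemble: recorded, and necessarily <= 1
        ensemble = [
            train_classifier(
                make_shape_dataset(10, 30, 32, 0.15, np.random.default_rng(70 + k)),
                rng=np.random.default_rng(80 + k),
            )
            for k in range(3)
        ]
        cands = [
            iterative_gradient_attack(
                shape_classifier, t, AttackConfig(), np.random.default_rng(900 + t)
            )
            for t in range(5)
        ]
        res = ensemble_transfer_filter(cands, ensemble, k_min=2)
        rate = len(res.retained) / len(cands)
        assert 0.0 <= rate <= 1.0


class TestPreprocess:
    def test_channel_mean_maps_to_zero(self):
        spec = PreprocessSpec(crop_size=8)
        img = np.zeros((10, 10, 3))
        img[..., 0] = 0.485
        out = preprocess_centre_crop_normalize(img, spec)
        assert out.shape == (8, 8, 3)
        assert np.allclose(out[..., 0], 0.0)

    def test_exact_size_crop_is_identity_before_normalisation(self):
        spec = PreprocessSpec(crop_size=4, channel_means=(0.0,) * 3, channel_stds=(1.0,) * 3)
        img = np.random.default_rng(0).random((4, 4, 3))
        assert np.array_equal(preprocess_centre_crop_normalize(img, spec), img)

    def test_odd_margin_window_breaks_ties_top_left(self):
        # 6x6 input, crop 4: rows/cols 1..4 (0-based) retained
        spec = PreprocessSpec(crop_size=4, channel_means=(0.0,) * 3, channel_stds=(1.0,) * 3)
        img = np.arange(36, dtype=float).reshape(6, 6) / 36
        out = preprocess_centre_crop_normalize(img[..., None].repeat(3, axis=2), spec)
        assert np.array_equal(out[..., 0], img[1:5, 1:5])

    def test_grayscale_uses_first_channel_stats(self):
        spec = PreprocessSpec(crop_size=2, channel_means=(0.5, 0.0, 0.0),
                              channel_stds=(0.25, 1.0, 1.0))
        out = preprocess_centre_crop_normalize(np.full((2, 2), 0.75), spec)
        assert np.allclose(out, 1.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller than crop"):
            preprocess_centre_crop_normalize(np.zeros((3, 3)), PreprocessSpec(crop_size=4))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            PreprocessSpec(channel_stds=(0.0, 1.0, 1.0))
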
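import json

import numpy as np
import pytest

from ahpfsam.fsam import (
    FSAMModel,
    FuzzyRule,
    TrainConfig,
    classify,
    fcm_initialize,
    fsam_output,
    fuzzy_c_means,
    gradient_step,
    joint_firing,
    predict_batch,
    sinc,
    sinc_derivative,
    train_supervised,
)
from ahpfsam.fsam import _gradients


def random_model(rng, n_rules=3, dim=2):
    return FSAMModel.from_arrays(
        rng.normal(size=(n_rules, dim)),
        rng.uniform(0.5, 2.0, size=(n_rules, dim)),
        rng.normal(size=n_rules),
        rng.uniform(0.5, 2.0, n_rules),
        rng.uniform(0.5, 2.0, n_rules),
    )


class TestSinc:
    def test_removable_singularity(self):
        assert sinc(0.0) == 1.0
        assert sinc(1e-12) == pytest.approx(1.0, abs=1e-12)

    def test_known_values(self):
        assert sinc(np.pi) == pytest.approx(0.0, abs=1e-12)
        assert sinc(np.pi / 2) == pytest.approx(2 / np.pi, rel=1e-12)

    def test_derivative_matches_finite_difference(self):
        for u in (-2.3, -1e-7, 0.0, 0.4, 3.1):
            h = 1e-6
            fd = (sinc(u + h) - sinc(u - h)) / (2 * h)
            assert sinc_derivative(u) == pytest.approx(fd, abs=1e-8)


class TestFiringAndOutput:
    def test_firing_is_one_at_center(self):
        rule = FuzzyRule(np.array([1.0, -2.0]), np.array([0.5, 1.5]), 0.3)
        assert joint_firing(rule, np.array([1.0, -2.0])) == pytest.approx(1.0)

    def test_zero_factor_annihilates_product(self):
        rule = FuzzyRule(np.array([0.0, 0.0]), np.array([1.0, 1.0]), 0.3)
        x = np.array([np.pi, 0.3])  # first factor sinc(pi) = 0
        assert joint_firing(rule, x) == pytest.approx(0.0, abs=1e-12)

    def test_factorization_matches_1d_product(self):
        rule = FuzzyRule(np.array([0.5, -1.0]), np.array([1.2, 0.7]), 0.0)
        x = np.array([1.3, 0.4])
        expected = sinc((1.3 - 0.5) / 1.2) * sinc((0.4 + 1.0) / 0.7)
        assert joint_firing(rule, x) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        rule = FuzzyRule(np.array([0.0]), np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            joint_firing(rule, np.array([0.0, 1.0]))

    def test_single_rule_returns_its_centroid(self):
        model = FSAMModel(
            (FuzzyRule(np.array([0.0]), np.array([1.0]), 0.7),)
        )
        for x in (-1.2, 0.0, 0.5, 2.0):
            assert fsam_output(model, np.array([x])) == pytest.approx(0.7)

    def test_symmetric_two_rule_average(self):
        rules = (
            FuzzyRule(np.array([-1.0]), np.array([1.0]), 0.0),
            FuzzyRule(np.array([1.0]), np.array([1.0]), 1.0),
        )
        model = FSAMModel(rules)
        # x = 0 is equidistant: a_1 = a_2, so F = (c1 + c2)/2
        assert fsam_output(model, np.array([0.0])) == pytest.approx(0.5)

    def test_three_rule_hand_evaluation(self):
        rules = (
            FuzzyRule(np.array([0.0]), np.array([1.0]), 1.0, 1.0, 1.0),
            FuzzyRule(np.array([1.0]), np.array([2.0]), 2.0, 0.5, 2.0),
            FuzzyRule(np.array([-1.0]), np.array([1.5]), -1.0, 1.0, 1.0),
        )
        model = FSAMModel(rules)
        x = np.array([0.5])
        a = np.array([sinc(0.5), sinc(-0.25), sinc(1.0)])
        g = np.array([1.0 * a[0] * 1.0, 2.0 * a[1] * 0.5, 1.0 * a[2] * 1.0])
        expected = (g @ np.array([1.0, 2.0, -1.0])) / g.sum()
        assert fsam_output(model, x) == pytest.approx(expected, rel=1e-12)

    def test_convex_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        model = random_model(rng)
        for _ in range(20):
            _, p = fsam_output(model, rng.normal(size=2), return_weights=True)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_output_within_centroid_hull_for_positive_firings(self):
        rng = np.random.default_rng(6)
        model = random_model(rng, n_rules=4, dim=1)
        c = [r.centroid for r in model.rules]
        for _ in range(50):
            x = rng.normal(size=1) * 0.2  # stay near centers: main lobes
            firings = [joint_firing(r, x) for r in model.rules]
            if all(f >= 0 for f in firings):
                f = fsam_output(model, x)
                assert min(c) - 1e-9 <= f <= max(c) + 1e-9

    def test_batch_prediction_matches_single(self):
        rng = np.random.default_rng(12)
        model = random_model(rng)
        X = rng.normal(size=(10, 2))
        batch = predict_batch(model, X)
        single = [fsam_output(model, x) for x in X]
        np.testing.assert_allclose(batch, single, rtol=1e-12)


class TestSerialization:
    def test_json_round_trip(self):
        rng = np.random.default_rng(2)
        model = random_model(rng)
        doc = json.loads(json.dumps(model.to_dict()))
        back = FSAMModel.from_dict(doc)
        assert back.n_rules == model.n_rules
        x = rng.normal(size=2)
        assert fsam_output(back, x) == pytest.approx(fsam_output(model, x))

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            FSAMModel.from_dict({"schema": "other/9", "rules": []})


class TestFCM:
    def test_one_cluster_center_is_the_mean(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(30, 3))
        centers, u = fuzzy_c_means(data, 1, seed=0)
        np.testing.assert_allclose(centers[0], data.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(u, 1.0)

    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 0.1, size=(25, 2))
        b = rng.normal(5.0, 0.1, size=(25, 2))
        X = np.vstack([a, b])
        y = np.array([0.0] * 25 + [1.0] * 25)
        model = fcm_initialize(X, y, n_clusters=2, seed=1)
        centroids = sorted(r.centroid for r in model.rules)
        assert centroids[0] == pytest.approx(0.0, abs=0.05)
        assert centroids[1] == pytest.approx(1.0, abs=0.05)

    def test_single_cluster_centroid_is_output_mean(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 2))
        y = rng.uniform(size=20)
        model = fcm_initialize(X, y, n_clusters=1, seed=0)
        assert model.n_rules == 1
        assert model.rules[0].centroid == pytest.approx(y.mean(), abs=1e-6)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(15, 2)), rng.uniform(size=15)
        m1 = fcm_initialize(X, y, 3, seed=42)
        m2 = fcm_initialize(X, y, 3, seed=42)
        for r1, r2 in zip(m1.rules, m2.rules):
            np.testing.assert_array_equal(r1.centers, r2.centers)
            np.testing.assert_array_equal(r1.widths, r2.widths)
            assert r1.centroid == r2.centroid

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError, match="cluster count"):
            fuzzy_c_means(np.zeros((4, 2)), 5)

    def test_widths_are_floored(self):
        X = np.zeros((10, 2))  # degenerate: zero spread
        y = np.linspace(0, 1, 10)
        model = fcm_initialize(X, y, 2, seed=0)
        for r in model.rules:
            assert (r.widths > 0).all()


class TestGradients:
    def test_centroid_gradient_is_residual_times_weight(self):
        rng = np.random.default_rng(7)
        m_ = rng.normal(size=(3, 2))
        d_ = rng.uniform(0.5, 2, (3, 2))
        c_ = rng.normal(size=3)
        v_ = rng.uniform(0.5, 2, 3)
        w_ = rng.uniform(0.5, 2, 3)
        x, y = rng.normal(size=2), 0.3
        model = FSAMModel.from_arrays(m_, d_, c_, v_, w_)
        f, p = fsam_output(model, x, return_weights=True)
        g = _gradients(m_, d_, c_, v_, w_, x, y)
        np.testing.assert_allclose(g["c"], (f - y) * p, rtol=1e-9)

    def test_all_partials_match_central_differences(self):
        """100 random non-degenerate draws, rel error < 1e-4.

        Components below the finite-difference noise floor (~1e-5 for
        E ~ 1 and h = 1e-6) are compared with that floor as denominator.
        """
        rng = np.random.default_rng(0)
        h = 1e-6
        checked = 0
        while checked < 100:
            m_ = rng.normal(size=(3, 2))
            d_ = rng.uniform(0.5, 2, (3, 2))
            c_ = rng.normal(size=3)
            v_ = rng.uniform(0.5, 2, 3)
            w_ = rng.uniform(0.5, 2, 3)
            x, y = rng.normal(size=2), float(rng.normal())
            g = _gradients(m_, d_, c_, v_, w_, x, y)
            if g is None:
                continue
            base = {"m": m_, "d": d_, "c": c_, "v": v_, "w": w_}

            def err(params):
                model = FSAMModel.from_arrays(
                    params["m"], params["d"], params["c"],
                    params["v"], params["w"],
                )
                return 0.5 * (y - fsam_output(model, x)) ** 2

            for key, arr in base.items():
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    p = {k: v.copy() for k, v in base.items()}
                    p[key][idx] += h
                    ep = err(p)
                    p[key][idx] -= 2 * h
                    em = err(p)
                    fd = (ep - em) / (2 * h)
                    an = g[key][idx]
                    rel = abs(fd - an) / max(abs(fd), abs(an), 1e-5)
                    assert rel < 1e-4, (key, idx, an, fd)
            checked += 1

    def test_perfect_prediction_gives_zero_gradient(self):
        model = FSAMModel(
            (FuzzyRule(np.array([0.0]), np.array([1.0]), 0.7),)
        )
        cfg = TrainConfig(learning_rate=0.1, momentum=0.0, epochs=1)
        new_model, _ = gradient_step(model, np.array([0.2]), 0.7, cfg)
        np.testing.assert_array_equal(
            new_model.rules[0].centers, model.rules[0].centers
        )
        assert new_model.rules[0].centroid == model.rules[0].centroid

    def test_momentum_zero_equals_plain_gradient_descent(self):
        rng = np.random.default_rng(9)
        model = random_model(rng)
        x, y = rng.normal(size=2), 0.8
        cfg = TrainConfig(learning_rate=0.05, momentum=0.0, epochs=1)
        stepped, _ = gradient_step(model, x, y, cfg)

        m_, d_, c_, v_, w_ = model.as_arrays()
        g = _gradients(m_, d_, c_, v_, w_, x, y)
        manual = FSAMModel.from_arrays(
            m_ - 0.05 * g["m"], np.maximum(d_ - 0.05 * g["d"], 1e-3),
            c_ - 0.05 * g["c"], v_ - 0.05 * g["v"], w_ - 0.05 * g["w"],
        )
        for r1, r2 in zip(stepped.rules, manual.rules):
            np.testing.assert_array_equal(r1.centers, r2.centers)
            np.testing.assert_array_equal(r1.widths, r2.widths)
            assert r1.centroid == r2.centroid
            assert r1.volume == r2.volume
            assert r1.weight == r2.weight


class TestTraining:
    def test_constant_target_converges(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 1))
        y = np.full(20, 0.4)
        model = fcm_initialize(X, y, 1, seed=0)
        cfg = TrainConfig(learning_rate=0.05, momentum=0.5, epochs=50, seed=0)
        trained, trace = train_supervised(model, X, y, cfg)
        assert trace[-1] < 1e-6

    def test_best_model_memory(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(float)
        model = fcm_initialize(X, y, 3, seed=1)
        cfg = TrainConfig(learning_rate=0.02, momentum=0.9, epochs=30, seed=2)
        trained, trace = train_supervised(model, X, y, cfg)
        final_mse = float(np.mean((predict_batch(trained, X) - y) ** 2))
        initial_mse = float(np.mean((predict_batch(model, X) - y) ** 2))
        assert final_mse <= initial_mse + 1e-12
        assert final_mse == pytest.approx(min(min(trace), initial_mse), abs=1e-12)

    def test_same_seed_identical_trace(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(15, 2))
        y = rng.uniform(size=15)
        model = fcm_initialize(X, y, 2, seed=3)
        cfg = TrainConfig(epochs=10, seed=5)
        _, t1 = train_supervised(model, X, y, cfg)
        _, t2 = train_supervised(model, X, y, cfg)
        assert t1 == t2


class TestClassify:
    def test_threshold_rule(self):
        model = FSAMModel(
            (FuzzyRule(np.array([0.0]), np.array([1.0]), 0.9),)
        )
        label, score = classify(model, np.array([0.0]))
        assert (label, score) == (1, pytest.approx(0.9))

    def test_boundary_goes_to_positive_class(self):
        model = FSAMModel(
            (FuzzyRule(np.array([0.0]), np.array([1.0]), 0.5),)
        )
        assert classify(model, np.array([0.0]))[0] == 1

    def test_below_threshold_is_negative(self):
        model = FSAMModel(
            (FuzzyRule(np.array([0.0]), np.array([1.0]), 0.1),)
        )
        assert classify(model, np.array([0.3]))[0] == 0
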
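"""Kernel discriminant: bandwidths, posteriors, predictions, serialisation."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from modeshift import (
    ClassifierConfig,
    DiscriminantModel,
    KNNModel,
    fit,
    from_json,
    to_json,
)
from modeshift.errors import ConfigError, DataError


def kde_log_density_oracle(x, train, h):
    """Naive O(m) product-Gaussian kernel density sum in plain Python."""
    m, d = train.shape
    total = 0.0
    for row in train:
        prod = 1.0
        for k in range(d):
            z = (x[k] - row[k]) / h[k]
            prod *= math.exp(-0.5 * z * z) / (h[k] * math.sqrt(2 * math.pi))
        total += prod
    return math.log(total / m)


class TestFit:
    def test_equal_priors_two_classes(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        model = fit(X, ["walk", "walk", "bike", "bike"], ("p95",))
        assert model.classes == ("walk", "bike")
        assert np.allclose(model.priors, [0.5, 0.5])

    def test_proportional_priors(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        model = fit(
            X,
            ["walk"] * 3 + ["bike"],
            ("p95",),
            ClassifierConfig(priors="proportional"),
        )
        assert np.allclose(model.priors, [0.75, 0.25])

    def test_silverman_bandwidth_scales_with_features(self):
        rng = np.random.default_rng(8)
        X = rng.normal(5, 2, size=(40, 2))
        y = ["walk"] * 20 + ["bike"] * 20
        base = fit(X, y, ("mean", "sd"))
        scaled = fit(3.0 * X, y, ("mean", "sd"))
        assert np.allclose(scaled.bandwidths, 3.0 * base.bandwidths, rtol=1e-12)

    def test_single_row_class_gets_floor_bandwidth(self):
        X = np.array([[0.0], [5.0], [10.0]])
        model = fit(X, ["walk", "bike", "train"], ("p95",))
        global_sd = np.std(X, ddof=1)
        assert np.allclose(model.bandwidths, 1e-6 * global_sd)

    def test_empty_combination_rejected(self):
        with pytest.raises(ConfigError):
            fit(np.zeros((4, 1)), ["a", "a", "b", "b"], ())

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            fit(np.zeros((3, 1)), ["walk"] * 3, ("p95",))


class TestPosterior:
    def test_separated_classes(self):
        X = np.array([[0.0], [0.5], [100.0], [100.5]])
        model = fit(X, ["walk", "walk", "bike", "bike"], ("p95",))
        post = model.posterior(np.array([0.0]))
        assert post[model.classes.index("walk")] > 0.99
        assert model.predict(np.array([0.0])) == "walk"

    def test_identical_training_sets_symmetric(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        model = fit(X, ["walk", "walk", "bike", "bike"], ("p95",))
        post = model.posterior(np.array([1.4]))
        assert np.allclose(post, [0.5, 0.5])
        # exact tie goes to the first class in the fixed order
        assert model.predict(np.array([1.4])) == "walk"

    def test_scores_normalised_nonnegative(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 3))
        y = rng.choice(["walk", "bike", "bus"], 30).tolist()
        model = fit(X, y, ("mean", "sd", "rcm"))
        scores = model.posterior(rng.normal(size=(15, 3)))
        assert np.all(scores >= 0)
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(24, 2))
        y = (["walk"] * 12 + ["bike"] * 12)
        model_a = fit(X, y, ("mean", "sd"))
        perm = rng.permutation(24)
        model_b = fit(X[perm], [y[i] for i in perm], ("mean", "sd"))
        q = rng.normal(size=(10, 2))
        assert np.allclose(model_a.posterior(q), model_b.posterior(q), atol=1e-12)

    def test_matches_analytic_bayes_for_gaussians(self):
        """With two large Gaussian samples the KDE posterior approaches
        the closed-form Bayes posterior."""
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 10000)
        b = rng.normal(3, 1, 10000)
        X = np.concatenate([a, b])[:, None]
        y = ["walk"] * 10000 + ["bike"] * 10000
        model = fit(X, y, ("p95",))
        wi = model.classes.index("walk")
        for x in (0.5, 1.5, 2.5):
            analytic = norm.pdf(x, 0, 1) / (norm.pdf(x, 0, 1) + norm.pdf(x, 3, 1))
            assert model.posterior(np.array([x]))[wi] == pytest.approx(
                analytic, abs=0.02
            )

    def test_monotone_switch_at_midpoint(self):
        X = np.array([[0.0], [1.0]])
        model = fit(X, ["walk", "bike"], ("p95",))
        grid = np.linspace(-0.2, 1.2, 141)
        preds = model.predict(grid[:, None])
        switches = sum(preds[i] != preds[i - 1] for i in range(1, len(preds)))
        assert switches == 1
        assert preds[0] == "walk" and preds[-1] == "bike"

    def test_dimension_mismatch(self):
        model = fit(np.zeros((4, 2)), ["a", "a", "b", "b"], ("mean", "sd"))
        with pytest.raises(DataError):
            model.posterior(np.zeros(3))


class TestOracleEquivalence:
    def test_log_density_matches_naive_sum(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(25, 2)) * [2.0, 0.5] + [3.0, 1.0]
        y = ["walk"] * 10 + ["bike"] * 8 + ["bus"] * 7
        model = fit(X, y, ("mean", "sd"))
        queries = rng.normal(size=(12, 2)) * [2.0, 0.5] + [3.0, 1.0]
        ours = model.log_likelihood(queries)
        for qi, q in enumerate(queries):
            for ci in range(len(model.classes)):
                expected = kde_log_density_oracle(
                    q, model.train[ci], model.bandwidths[ci]
                )
                assert ours[qi, ci] == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_predictions_match_brute_force_1d(self):
        rng = np.random.default_rng(32)
        X = np.concatenate([rng.normal(0, 1, 100), rng.normal(4, 1, 100)])[:, None]
        y = ["walk"] * 100 + ["bus"] * 100
        model = fit(X, y, ("p95",))
        queries = rng.uniform(-2, 6, 200)[:, None]
        preds = model.predict(queries)
        for q, pred in zip(queries, preds):
            scores = [
                math.log(0.5) + kde_log_density_oracle(q, model.train[ci], model.bandwidths[ci])
                for ci in range(2)
            ]
            expected = model.classes[int(np.argmax(scores))]
            assert pred == expected

    def test_agrees_with_sklearn_kernel_density(self):
        """Cross-check the per-class log density against scikit-learn
        (features pre-scaled by the per-dimension bandwidths)."""
        from sklearn.neighbors import KernelDensity

        rng = np.random.default_rng(33)
        X = rng.normal(size=(40, 2)) * [1.5, 0.3]
        y = ["walk"] * 22 + ["bike"] * 18
        model = fit(X, y, ("mean", "sd"))
        queries = rng.normal(size=(9, 2)) * [1.5, 0.3]
        ours = model.log_likelihood(queries)
        for ci in range(2):
            h = model.bandwidths[ci]
            kd = KernelDensity(kernel="gaussian", bandwidth=1.0)
            kd.fit(model.train[ci] / h)
            expected = kd.score_samples(queries / h) - np.sum(np.log(h))
            assert np.allclose(ours[:, ci], expected, rtol=1e-9, atol=1e-9)


class TestKnnVariant:
    def test_separable_classification(self):
        rng = np.random.default_rng(41)
        X = np.concatenate([rng.normal(0, 0.5, (30, 1)), rng.normal(10, 0.5, (30, 1))])
        y = ["walk"] * 30 + ["bus"] * 30
        model = fit(X, y, ("p95",), ClassifierConfig(variant="knn", knn_k=5))
        assert isinstance(model, KNNModel)
        assert model.predict(np.array([0.2])) == "walk"
        assert model.predict(np.array([9.8])) == "bus"
        post = model.posterior(np.array([[0.2], [9.8]]))
        assert np.allclose(post.sum(axis=1), 1.0)


class TestSerialisation:
    def test_kde_json_round_trip_exact(self):
        rng = np.random.default_rng(51)
        X = rng.normal(size=(20, 3))
        y = ["walk"] * 7 + ["bike"] * 6 + ["car"] * 7
        model = fit(X, y, ("mean", "sd", "rcm"))
        back = from_json(to_json(model))
        assert isinstance(back, DiscriminantModel)
        assert back.classes == model.classes
        assert np.array_equal(back.priors, model.priors)
        assert np.array_equal(back.bandwidths, model.bandwidths)
        for a, b in zip(back.train, model.train):
            assert np.array_equal(a, b)
        q = rng.normal(size=(5, 3))
        assert np.array_equal(back.posterior(q), model.posterior(q))

    def test_knn_json_round_trip(self):
        X = np.arange(10, dtype=float)[:, None]
        y = ["walk"] * 5 + ["bike"] * 5
        model = fit(X, y, ("p95",), ClassifierConfig(variant="knn"))
        back = from_json(to_json(model))
        assert isinstance(back, KNNModel)
        grid = np.linspace(-1, 10, 23)[:, None]
        assert list(back.predict(grid)) == list(model.predict(grid))
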
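"""Loss oracles, the split protocol, zone routing and both model families."""

import numpy as np
import pytest

from maizemap import _gru
from maizemap.classifiers import (
    GRUCenterLossClassifier,
    NetworkConfig,
    SplitSpec,
    ZoneRandomForestClassifier,
    center_loss,
    combined_loss,
    cross_entropy_loss,
    predict_pixels,
    route_zone,
    split_samples,
    train_random_forest,
    train_recurrent,
    update_centers,
)
from maizemap.preprocessing import SequenceFeaturizer
from maizemap.synthetic import generate_sample_set, make_scenario


def brute_force_ce(probs, onehot):
    total = 0.0
    n, c = probs.shape
    for i in range(n):
        for j in range(c):
            if onehot[i][j]:
                total -= np.log(probs[i][j])
    return total / n


def brute_force_center(features, y, centers):
    total = 0.0
    for i, yi in enumerate(y):
        d = np.asarray(features[i]) - np.asarray(centers[yi])
        total += 0.5 * float(d @ d)
    return total


class TestLosses:
    def test_perfect_prediction_is_zero(self):
        p = np.eye(3)
        assert cross_entropy_loss(p, np.eye(3, dtype=int)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log3(self):
        p = np.full((1, 3), 1 / 3)
        y = np.array([[1, 0, 0]])
        assert cross_entropy_loss(p, y) == pytest.approx(np.log(3), abs=1e-12)

    def test_two_sample_hand_value(self):
        p = np.array([[0.5, 0.3, 0.2], [0.25, 0.5, 0.25]])
        y = np.array([[1, 0, 0], [1, 0, 0]])
        expected = (np.log(2) + np.log(4)) / 2
        assert cross_entropy_loss(p, y) == pytest.approx(expected, abs=1e-12)

    def test_against_brute_force(self, rng):
        p = rng.dirichlet(np.ones(3), size=20)
        y_idx = rng.integers(0, 3, 20)
        onehot = np.eye(3, dtype=int)[y_idx]
        assert cross_entropy_loss(p, onehot) == pytest.approx(
            brute_force_ce(p, onehot), abs=1e-10
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.full((2, 3), 1 / 3), np.eye(3, dtype=int))

    def test_monotone_in_true_class_probability(self):
        y = np.array([[1, 0, 0]])
        prev = np.inf
        for pt in np.linspace(0.1, 0.9, 9):
            rest = (1 - pt) / 2
            ce = cross_entropy_loss(np.array([[pt, rest, rest]]), y)
            assert ce < prev
            prev = ce


class TestCenterLoss:
    def test_features_at_centers_give_zero(self, rng):
        centers = rng.normal(size=(3, 4))
        y = np.array([0, 1, 2, 1])
        assert center_loss(centers[y], y, centers) == 0.0

    def test_hand_values(self):
        centers = np.zeros((2, 2))
        f = np.array([[2.0, 0.0]])  # distance 2
        assert center_loss(f, [0], centers) == pytest.approx(2.0)
        f2 = np.array([[1.0, 0.0], [0.0, 2.0]])  # distances 1 and 2
        assert center_loss(f2, [0, 1], centers) == pytest.approx(2.5)

    def test_against_brute_force(self, rng):
        f = rng.normal(size=(15, 6))
        y = rng.integers(0, 3, 15)
        centers = rng.normal(size=(3, 6))
        assert center_loss(f, y, centers) == pytest.approx(
            brute_force_center(f, y, centers), abs=1e-10
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            center_loss(np.zeros((1, 2)), [5], np.zeros((3, 2)))

    def test_combined_weighting(self):
        assert combined_loss(1.0, 100.0, w1=1.0, w2=0.001) == pytest.approx(1.1)
        assert combined_loss(0.7, 0.0) == pytest.approx(0.7)
        assert combined_loss(0.7, 1e9, w1=1.0, w2=0.0) == pytest.approx(0.7)


class TestCenterUpdates:
    def test_full_rate_jumps_to_batch_mean(self):
        centers = np.zeros((2, 2))
        f = np.array([[1.0, 1.0], [3.0, 3.0]])
        out = update_centers(centers, f, [0, 0], rate=1.0)
        assert np.allclose(out[0], [2.0, 2.0])

    def test_half_rate_convex_combination(self):
        out = update_centers(np.zeros((1, 1)), np.array([[2.0]]), [0], rate=0.5)
        assert out[0, 0] == pytest.approx(1.0)

    def test_absent_class_unchanged(self):
        centers = np.array([[1.0], [5.0]])
        out = update_centers(centers, np.array([[3.0]]), [0], rate=0.5)
        assert out[1, 0] == 5.0


class TestSplit:
    def make_records(self, per_class):
        from maizemap.types import SampleRecord

        recs = []
        for cls, n in per_class.items():
            for i in range(n):
                recs.append(SampleRecord(f"{cls}{i}", 0, 0, "a", 2019, cls, "I"))
        return recs

    def test_exact_fractions_at_100(self):
        recs = self.make_records({"maize": 50, "non_maize_crop": 50})
        tr, va, te = split_samples(recs, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (70, 10, 20)

    def test_per_stratum_rounding_30_each(self):
        recs = self.make_records(
            {"maize": 30, "non_maize_crop": 30, "non_cropland": 30}
        )
        tr, va, te = split_samples(recs, SplitSpec(seed=1))
        for cls in ("maize", "non_maize_crop", "non_cropland"):
            counts = [sum(r.class_label == cls for r in part)
                      for part in (tr, va, te)]
            assert counts == [21, 3, 6]

    def test_disjoint_union_and_determinism(self):
        recs = self.make_records({"maize": 17, "non_maize_crop": 23})
        a = split_samples(recs, SplitSpec(seed=5))
        b = split_samples(recs, SplitSpec(seed=5))
        assert a == b
        ids = [r.id for part in a for r in part]
        assert sorted(ids) == sorted(r.id for r in recs)
        assert len(set(ids)) == len(ids)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            split_samples([], SplitSpec())

    def test_single_class_stratified_rejected(self):
        recs = self.make_records({"maize": 20})
        with pytest.raises(ValueError):
            split_samples(recs, SplitSpec())


class TestRouting:
    @pytest.mark.parametrize(
        "zone, kind",
        [("a", "recurrent_net"), ("b", "random_forest"),
         ("c", "random_forest"), ("d", "random_forest"),
         ("e", "random_forest"), ("south", "random_forest")],
    )
    def test_route(self, zone, kind):
        assert route_zone(zone) == kind

    def test_unknown_zone(self):
        with pytest.raises(ValueError):
            route_zone("x")


@pytest.fixture(scope="module")
def fitted_models(small_sample_set_module):
    records = small_sample_set_module
    gru = train_recurrent(records, NetworkConfig(seed=3, max_epochs=25))
    scen_b = make_scenario("b", 2020, 60, seed=8)
    rf = train_random_forest(generate_sample_set(scen_b), "b", seed=3)
    return gru, rf


@pytest.fixture(scope="module")
def small_sample_set_module():
    return generate_sample_set(make_scenario("a", 2019, 60, seed=7))


class TestTraining:
    def test_recurrent_recovers_separable_classes(self, fitted_models):
        gru, _ = fitted_models
        assert gru.model_kind == "recurrent_net"
        assert gru.metadata["test_oa"] >= 0.95
        assert len(gru.metadata["history"]["val_oa"]) == 25

    def test_best_epoch_maximizes_validation_oa(self, fitted_models):
        gru, _ = fitted_models
        hist = gru.metadata["history"]["val_oa"]
        best = gru.metadata["best_epoch"]
        assert hist[best] == max(hist)
        assert best == hist.index(max(hist))  # earliest on ties

    def test_forest_recovers_separable_classes(self, fitted_models):
        _, rf = fitted_models
        assert rf.metadata["test_oa"] >= 0.95
        assert rf.metadata["n_trees"] == 200
        assert rf.metadata["forest_params"]["n_estimators"] == 200

    def test_training_reproducible_with_fixed_seed(self, small_sample_set_module):
        runs = [
            train_recurrent(small_sample_set_module,
                            NetworkConfig(seed=11, max_epochs=5))
            for _ in range(2)
        ]
        assert runs[0].metadata["history"] == runs[1].metadata["history"]

    def test_zone_mismatch_listed(self, small_sample_set_module):
        with pytest.raises(ValueError, match="'a'"):
            train_random_forest(small_sample_set_module, "d")

    def test_south_pools_adjacent_zones(self):
        recs = generate_sample_set(make_scenario("b", 2020, 12, seed=1))
        recs += generate_sample_set(make_scenario("c", 2020, 12, seed=2))
        model = train_random_forest(recs, "south", seed=0)
        assert model.zone_id == "south"
        assert model.metadata["test_oa"] is not None

    def test_single_class_training_rejected(self):
        X = np.zeros((20, 7, 10))
        y = np.array(["maize"] * 20)
        with pytest.raises(ValueError):
            GRUCenterLossClassifier(max_epochs=1).fit(X, y)
        with pytest.raises(ValueError):
            ZoneRandomForestClassifier().fit(X, y)

    def test_zero_epoch_budget_rejected(self):
        X = np.zeros((20, 7, 10))
        y = np.array(["maize"] * 10 + ["non_cropland"] * 10)
        with pytest.raises(ValueError):
            GRUCenterLossClassifier(max_epochs=0).fit(X, y)


class TestPrediction:
    def test_outputs_deterministic_and_normalized(self, fitted_models,
                                                  small_sample_set_module):
        X = SequenceFeaturizer(flatten=False).transform(
            [s for _, s in small_sample_set_module[:20]]
        )
        for model in fitted_models:
            l1, p1 = predict_pixels(model, X)
            l2, p2 = predict_pixels(model, X)
            assert np.array_equal(l1, l2) and np.array_equal(p1, p2)
            assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)
            assert set(l1) <= {"maize", "non_maize_crop", "non_cropland"}

    def test_overfit_capable_model_memorizes_training_data(
        self, fitted_models, small_sample_set_module
    ):
        gru, _ = fitted_models
        X = SequenceFeaturizer(flatten=False).transform(
            [s for _, s in small_sample_set_module]
        )
        y = np.array([r.class_label for r, _ in small_sample_set_module])
        assert np.mean(gru.model.predict(X) == y) >= 0.99

    def test_shape_mismatch_rejected(self, fitted_models):
        with pytest.raises(ValueError):
            predict_pixels(fitted_models[0], np.zeros((3, 5, 10)))


class TestGradients:
    def test_backward_matches_numerical_gradient(self, rng):
        params = _gru.init_params(4, 5, 3, 2, rng)
        X = rng.normal(size=(5, 3, 4))
        y = rng.integers(0, 3, 5)
        centers = rng.normal(size=(3, 5))
        cache = _gru.forward(params, X)
        grads = _gru.backward(params, cache, y, centers, 1.0, 0.01)

        def loss():
            c = _gru.forward(params, X)
            ce, cen = _gru.losses(c, y, centers)
            return 1.0 * ce + 0.01 * cen

        eps = 1e-6
        for k in params:
            flat = params[k].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[i]
                assert num == pytest.approx(ana, abs=2e-5, rel=1e-3)

    def test_probabilities_rows_sum_to_one(self, rng):
        params = _gru.init_params(10, 8, 3, 2, rng)
        cache = _gru.forward(params, rng.normal(size=(6, 7, 10)))
        assert np.allclose(cache["probs"].sum(axis=1), 1.0, atol=1e-9)
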
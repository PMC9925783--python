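"""Decoder families: auROC, thresholds, linear filters, NNC, evaluation."""

import numpy as np
import pytest

from glomix import decoders as dec
from glomix.mixtures import Mixture


def pair_count_auroc(scores, go_mask):
    """Exhaustive all-pairs auROC oracle (ties count one half)."""
    pos = [s for s, g in zip(scores, go_mask) if g]
    neg = [s for s, g in zip(scores, go_mask) if not g]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_mixtures(valences):
    return [Mixture("t", "c", f"bg_{i}", v, "test")
            for i, v in enumerate(valences)]


class TestCentering:
    def test_identical_rows_center_to_zero(self):
        train = np.tile([-1.0, -2.0, 0.5], (6, 1))
        ctrain, _, means = dec.center_patterns(train)
        assert np.allclose(ctrain, 0.0)
        assert np.allclose(means, [-1.0, -2.0, 0.5])

    def test_column_means_zero_and_round_trip(self, rng):
        train = rng.standard_normal((10, 7))
        test = rng.standard_normal((4, 7))
        ctrain, ctest, means = dec.center_patterns(train, test)
        assert np.allclose(ctrain.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(ctest + means, test)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            dec.center_patterns(np.empty((0, 5)))


class TestDiscriminability:
    def test_matches_all_pairs_counting(self, rng):
        for _ in range(15):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            go = rng.random(n) < 0.5
            if go.all() or not go.any():
                continue
            auroc, _ = dec.glomerulus_discriminability(scores, go)
            assert np.isclose(auroc, pair_count_auroc(scores, go))

    def test_transform_and_extremes(self):
        resp = np.array([-3.0, -2.5, -1.0, -0.5])
        go = [True, True, False, False]
        auroc, disc = dec.glomerulus_discriminability(resp, go)
        assert auroc == 0.0 and disc == 1.0  # perfectly separated, inverted
        auroc_f, disc_f = dec.glomerulus_discriminability(resp,
                                                          [not g for g in go])
        assert auroc_f == 1.0 and disc_f == 1.0

    def test_invariance_under_monotone_transform(self, rng):
        scores = rng.standard_normal(20)
        go = rng.random(20) < 0.5
        a1, d1 = dec.glomerulus_discriminability(scores, go)
        a2, d2 = dec.glomerulus_discriminability(np.exp(scores), go)
        assert np.isclose(a1, a2) and np.isclose(d1, d2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dec.glomerulus_discriminability([1.0, 2.0], [True, True])


class TestBestGlomerulus:
    def test_perfect_separator_is_chosen_and_classifies_training(self, rng):
        train = 0.1 * rng.standard_normal((8, 5))
        labels = ["go"] * 4 + ["nogo"] * 4
        train[:4, 3] = -2.0  # go mixtures: strong activation on ROI 3
        train[4:, 3] = -1.0
        clf = dec.fit_best_glomerulus(train, labels)
        assert clf.roi == 3
        assert clf.training_auroc in (0.0, 1.0)
        pred = clf.predict_batch(train)
        assert np.array_equal(pred, labels)

    def test_youden_threshold_matches_brute_force(self, rng):
        train = rng.standard_normal((20, 1))
        labels = ["go" if rng.random() < 0.5 else "nogo" for _ in range(20)]
        if len(set(labels)) < 2 or labels.count("go") < 2 \
                or labels.count("nogo") < 2:
            labels = ["go"] * 10 + ["nogo"] * 10
        clf = dec.fit_best_glomerulus(train, labels)
        go = np.array([lab == "go" for lab in labels])
        x = clf.orientation * train[:, 0]
        # brute force: sweep all candidate cuts, maximize TPR - FPR
        best = max(((x > c) & go).sum() / go.sum()
                   - ((x > c) & ~go).sum() / (~go).sum()
                   for c in np.concatenate([x - 1e-9, [x.max() + 1]]))
        got_pred = clf.predict_batch(train) == "go"
        got = (got_pred & go).sum() / go.sum() \
            - (got_pred & ~go).sum() / (~go).sum()
        assert np.isclose(got, best)

    def test_requires_two_per_class(self):
        with pytest.raises(ValueError):
            dec.fit_best_glomerulus(np.zeros((3, 2)), ["go", "nogo", "nogo"])


class TestLinearDecoders:
    @pytest.mark.parametrize("family", ["svm", "logistic"])
    def test_separable_toy_reaches_full_training_accuracy(self, family):
        train = np.array([[-2.0, 0.0], [-1.8, -0.1], [0.0, -2.0],
                          [-0.1, -1.9]])
        labels = ["go", "go", "nogo", "nogo"]
        d = dec.train_linear(train, labels, family=family, lam=0.0)
        assert np.array_equal(d.predict_batch(train), labels)

    @pytest.mark.parametrize("family", ["svm", "logistic"])
    def test_full_shrinkage_at_large_lambda(self, family, rng):
        train = rng.standard_normal((12, 20))
        labels = ["go"] * 6 + ["nogo"] * 6
        d = dec.train_linear(train, labels, family=family, lam=50.0)
        assert d.n_active == 0
        # prediction falls back to the bias sign
        expected = "go" if d.bias > 0 else "nogo"
        assert all(p == expected for p in d.predict_batch(train))

    def test_logistic_boundary_at_symmetric_midpoint(self):
        """1-D symmetric two-point classes: the decision boundary sits at
        the midpoint (closed-form oracle)."""
        train = np.array([[-1.0], [1.0]] * 8)
        labels = ["nogo", "go"] * 8
        d = dec.train_linear(train, labels, family="logistic", lam=0.01)
        assert d.predict_batch([[0.5]])[0] == "go"
        assert d.predict_batch([[-0.5]])[0] == "nogo"
        assert abs(d.decision_values(np.array([[0.0]]))[0]) < 0.2

    def test_decision_value_matches_hand_arithmetic(self):
        d = dec.LinearDecoder(weights=np.array([0.5, -1.0, 2.0]), bias=0.25,
                              family="svm", lam=0.0)
        pattern = np.array([[-1.0, -2.0, -0.5]])
        assert np.isclose(d.decision_values(pattern)[0],
                          0.5 * -1 + -1 * -2 + 2 * -0.5 + 0.25)

    def test_zero_weights_bias_sign_and_tie_break(self):
        go_always = dec.LinearDecoder(np.zeros(3), 1.0, "svm", 0.0)
        assert go_always.predict_batch(np.zeros((2, 3)))[0] == "go"
        tie = dec.LinearDecoder(np.zeros(3), 0.0, "svm", 0.0)
        assert tie.predict_batch(np.zeros((1, 3)))[0] == "nogo"

    def test_length_mismatch_and_bad_lambda(self):
        d = dec.LinearDecoder(np.zeros(3), 0.0, "svm", 0.0)
        with pytest.raises(ValueError):
            d.decision_values(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            dec.train_linear(np.zeros((4, 2)), ["go", "go", "nogo", "nogo"],
                             lam=-1.0)

    def test_sparsity_monotone_on_identifiable_instance(self):
        """Nonzero-weight count is non-increasing along the 21-value
        sparsity grid when feature strengths are graded."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 30))
        strengths = np.zeros(30)
        strengths[:10] = np.geomspace(3.0, 0.3, 10)
        labels = np.where(X @ strengths + 0.5 * rng.standard_normal(60) > 0,
                          "go", "nogo")
        for family in ("svm", "logistic"):
            counts = [dec.train_linear(X, labels, family=family, lam=l).n_active
                      for l in np.linspace(0, 1, 21)]
            assert all(a >= b for a, b in zip(counts, counts[1:])), counts


class TestNNC:
    def test_template_match_returns_its_valence(self, rng):
        train = rng.standard_normal((6, 12)) - 1
        labels = ["go", "nogo"] * 3
        d = dec.train_nnc(train, labels)
        for i in range(6):
            assert d.predict_batch(train[i:i + 1])[0] == labels[i]

    def test_selectivity_half_includes_all_rois(self, rng):
        train = rng.standard_normal((8, 15))
        d = dec.train_nnc(train, ["go"] * 4 + ["nogo"] * 4,
                          selectivity_threshold=0.5)
        assert d.n_active == 15

    def test_argmax_matches_explicit_loop(self, rng):
        train = rng.standard_normal((10, 8))
        labels = ["go", "nogo"] * 5
        d = dec.train_nnc(train, labels)
        for _ in range(5):
            p = rng.standard_normal(8)
            dots = [sum(train[t, i] * p[i] for i in range(8))
                    for t in range(10)]
            assert d.predict_batch(p[None, :])[0] == labels[int(np.argmax(dots))]

    def test_empty_filter_rejected(self):
        # identical go/nogo responses: every ROI at discriminability 0.5
        train = np.tile([-1.0, -2.0], (4, 1))
        with pytest.raises(ValueError):
            dec.train_nnc(train, ["go", "nogo", "go", "nogo"],
                          selectivity_threshold=0.9)


class TestEvaluate:
    def test_noiseless_training_set_scores_one(self, rng):
        train = rng.standard_normal((8, 10)) - 1
        labels = ["go"] * 4 + ["nogo"] * 4
        d = dec.train_linear(train, labels, family="svm")
        res = dec.evaluate(d, make_mixtures(labels), train, noise_cv=0.0,
                           n_instantiations=10, seed=0)
        assert res.fraction_correct == 1.0

    def test_shuffled_labels_score_at_chance(self, rng):
        """Random valences are unpredictable: every decoder family lands
        at 50% within binomial error."""
        train = rng.standard_normal((8, 10)) - 1
        d = dec.train_nnc(train, ["go"] * 4 + ["nogo"] * 4)
        test = rng.standard_normal((150, 10)) - 1
        valences = np.where(rng.random(150) < 0.5, "go", "nogo")
        res = dec.evaluate(d, make_mixtures(valences), test, noise_cv=0.25,
                           n_instantiations=10, seed=1)
        assert abs(res.fraction_correct - 0.5) < 0.13  # ~3 sigma, n=150

    def test_per_background_breakdown_and_determinism(self, rng):
        train = rng.standard_normal((4, 6)) - 1
        labels = ["go", "go", "nogo", "nogo"]
        d = dec.train_linear(train, labels, family="logistic")
        mixtures = make_mixtures(labels)
        r1 = dec.evaluate(d, mixtures, train, 0.3, 20, seed=5)
        r2 = dec.evaluate(d, mixtures, train, 0.3, 20, seed=5)
        assert r1.fraction_correct == r2.fraction_correct
        assert len(r1.per_background) == 4
        with pytest.raises(ValueError):
            dec.evaluate(d, mixtures, train, 0.3, 0, seed=1)
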
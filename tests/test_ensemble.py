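"""Member classifiers and voting rules against independent oracles."""

import math

import numpy as np
import pytest

from cardioseg import (
    EnsembleConfig,
    GaussianNBModel,
    ensemble_predict,
    fit_boosted,
    fit_ensemble,
    fit_forest,
    fit_gaussian_nb,
    forest_predict,
    load_ensemble,
    nb_pdf,
    nb_posterior,
    save_ensemble,
    vote_hard,
    vote_soft,
    vote_weighted,
)
from cardioseg.ensemble import features_per_split


class TestNbPdf:
    def test_value_at_the_mode(self):
        assert nb_pdf(0.0, 0.0, 1.0) == pytest.approx(
            1.0 / math.sqrt(2.0 * math.pi)
        )

    def test_symmetry_about_the_mean(self):
        assert nb_pdf(2.5, 1.0, 0.7) == pytest.approx(nb_pdf(-0.5, 1.0, 0.7))

    def test_integrates_to_one(self):
        x = np.linspace(-12, 12, 200001)
        area = np.trapezoid(nb_pdf(x, 0.3, 1.7), x)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            nb_pdf(0.0, 0.0, 0.0)


class TestGaussianNB:
    def test_population_sd_by_hand(self):
        rows = np.array([[0.0], [2.0], [10.0], [12.0]])
        labels = np.array([0, 0, 1, 1])
        model = fit_gaussian_nb(rows, labels)
        assert model.class_means[0, 0] == pytest.approx(1.0)
        assert model.class_sds[0, 0] == pytest.approx(1.0)  # divisor n

    def test_priors_are_class_frequencies(self, rng):
        rows = rng.normal(size=(10, 2))
        labels = np.array([0] * 6 + [1] * 4)
        model = fit_gaussian_nb(rows, labels)
        assert np.allclose(model.class_priors, [0.6, 0.4])

    def test_constant_feature_clamped_to_floor(self):
        rows = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 5.0], [1.0, 6.0]])
        model = fit_gaussian_nb(rows, np.array([0, 0, 1, 1]), sd_floor=1e-6)
        assert model.class_sds[0, 0] == 1e-6

    def test_single_class_frame_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            fit_gaussian_nb(rng.normal(size=(4, 2)), np.zeros(4, int))

    def test_separated_classes_give_confident_posterior(self):
        model = GaussianNBModel(
            class_order=np.array([0, 1]),
            class_priors=np.array([0.5, 0.5]),
            class_means=np.array([[0.0], [10.0]]),
            class_sds=np.array([[1.0], [1.0]]),
        )
        post = nb_posterior(model, np.array([0.0]))
        assert post[0] > 0.999

    def test_midpoint_of_symmetric_classes_is_even(self):
        model = GaussianNBModel(
            class_order=np.array([0, 1]),
            class_priors=np.array([0.5, 0.5]),
            class_means=np.array([[0.0], [4.0]]),
            class_sds=np.array([[1.0], [1.0]]),
        )
        assert np.allclose(nb_posterior(model, np.array([2.0])), [0.5, 0.5])

    def test_matches_direct_product_oracle(self, rng):
        # direct (non-log) product of prior x densities, then normalize
        for _ in range(100):
            k, c = 3, 4
            model = GaussianNBModel(
                class_order=np.arange(k),
                class_priors=np.full(k, 1.0 / k),
                class_means=rng.normal(0, 2, (k, c)),
                class_sds=rng.uniform(0.5, 2.0, (k, c)),
            )
            row = rng.normal(0, 2, c)
            direct = model.class_priors * np.array([
                np.prod(nb_pdf(row, model.class_means[j], model.class_sds[j]))
                for j in range(k)
            ])
            direct /= direct.sum()
            assert np.allclose(nb_posterior(model, row), direct, atol=1e-9)

    def test_posteriors_are_distributions(self, rng, blob_frame):
        rows, labels = blob_frame
        model = fit_gaussian_nb(rows, labels)
        post = nb_posterior(model, rows)
        assert post.min() >= 0.0
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_agrees_with_reference_implementation(self, blob_frame):
        from sklearn.naive_bayes import GaussianNB

        rows, labels = blob_frame
        model = fit_gaussian_nb(rows, labels, sd_floor=1e-9)
        ref = GaussianNB(var_smoothing=0.0).fit(rows, labels)
        assert np.allclose(
            nb_posterior(model, rows), ref.predict_proba(rows), atol=1e-6
        )

    def test_feature_count_mismatch_rejected(self, blob_frame):
        rows, labels = blob_frame
        model = fit_gaussian_nb(rows, labels)
        with pytest.raises(ValueError, match="features"):
            nb_posterior(model, np.zeros(3))


class TestRandomForest:
    def test_features_per_split_rule(self):
        assert features_per_split(64) == 7  # floor(log2 64) + 1

    def test_single_tree_separates_a_threshold_dataset(self):
        rows = np.linspace(0, 1, 40).reshape(-1, 1)
        labels = (rows[:, 0] > 0.5).astype(int)
        model = fit_forest(rows, labels, n_trees=1, seed=0)
        pred = model.class_order[forest_predict(model, rows).argmax(axis=1)]
        assert np.array_equal(pred, labels)

    def test_same_seed_reproduces_predictions(self, blob_frame, rng):
        rows, labels = blob_frame
        held_out = rng.normal(0, 4, size=(30, rows.shape[1]))
        a = forest_predict(fit_forest(rows, labels, 10, seed=3), held_out)
        b = forest_predict(fit_forest(rows, labels, 10, seed=3), held_out)
        assert np.array_equal(a, b)

    def test_probabilities_average_per_tree_responses(self, blob_frame):
        rows, labels = blob_frame
        model = fit_forest(rows, labels, n_trees=3, seed=1)
        per_tree = np.stack([
            t.predict_proba(rows) for t in model.clf.estimators_
        ])
        assert np.allclose(
            forest_predict(model, rows), per_tree.mean(axis=0)
        )

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_forest(np.zeros((0, 4)), np.zeros(0, int))


class TestBoostedTrees:
    def test_training_loss_non_increasing_over_rounds(self, blob_frame):
        rows, labels = blob_frame
        model = fit_boosted(rows, labels, n_rounds=8, learning_rate=0.3)
        losses = model.staged_logloss(rows, labels)
        assert np.all(np.diff(losses) <= 1e-12)

    def test_single_leaf_weight_closed_form(self):
        # constant feature -> no split; labels all 1 from base score 0.5:
        # g_i = p - y = -1/2, h_i = p(1-p) = 1/4, leaf = -G/(H + lambda)
        n, lam = 8, 1.0
        model = fit_boosted(
            np.zeros((n, 1)),
            np.ones(n, int),
            n_rounds=1,
            learning_rate=1.0,
            lambda_reg=lam,
            base_score=0.5,
        )
        margin = model.predict_margin(np.zeros((1, 1)))
        expected = (n / 2.0) / (n / 4.0 + lam)
        assert margin[0] == pytest.approx(expected, rel=1e-6)

    def test_huge_lambda_pins_predictions_to_base_score(self, blob_frame):
        rows, labels = blob_frame
        model = fit_boosted(
            rows, (labels > 0).astype(int), n_rounds=4, lambda_reg=1e12
        )
        probs = model.predict_proba(rows)
        assert np.allclose(probs[:, 1], 0.5, atol=1e-6)

    def test_negative_penalties_rejected(self, blob_frame):
        rows, labels = blob_frame
        with pytest.raises(ValueError, match="penalt"):
            fit_boosted(rows, labels, lambda_reg=-1.0)

    def test_multiclass_probabilities_are_distributions(self, blob_frame):
        rows, labels = blob_frame
        model = fit_boosted(rows, labels, n_rounds=5)
        probs = model.predict_proba(rows)
        assert probs.shape == (len(rows), 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def hard_oracle(member_labels, classes):
    counts = [list(member_labels).count(c) for c in classes]
    return classes[int(np.argmax(counts))]


def weighted_oracle(member_labels, weights, classes):
    sums = [
        sum(w for lbl, w in zip(member_labels, weights) if lbl == c)
        for c in classes
    ]
    return classes[int(np.argmax(sums))]


class TestVoting:
    CLASSES = np.array([0, 1, 2])

    def test_majority_wins(self):
        assert vote_hard([0, 0, 1], self.CLASSES) == 0

    def test_tie_breaks_to_lowest_class_index(self):
        assert vote_hard([1, 0], np.array([0, 1])) == 0
        assert vote_hard([2, 1, 0], self.CLASSES) == 0

    def test_hard_matches_counting_oracle_exhaustively(self):
        for a in self.CLASSES:
            for b in self.CLASSES:
                for c in self.CLASSES:
                    got = vote_hard([a, b, c], self.CLASSES)
                    assert got == hard_oracle([a, b, c], self.CLASSES)

    def test_weighted_overrides_majority(self):
        got = vote_weighted([0, 1, 1], [0.6, 0.2, 0.2], self.CLASSES)
        assert got == 0

    def test_uniform_weights_reduce_to_hard(self, rng):
        for _ in range(200):
            labels = rng.integers(0, 3, 3)
            assert vote_weighted(
                labels, [1.0, 1.0, 1.0], self.CLASSES
            ) == vote_hard(labels, self.CLASSES)

    def test_weighted_matches_oracle_on_random_cases(self, rng):
        for _ in range(1000):
            labels = rng.integers(0, 3, 4)
            weights = rng.uniform(0.1, 1.0, 4)
            got = vote_weighted(labels, weights, self.CLASSES)
            assert got == weighted_oracle(labels, weights, self.CLASSES)

    def test_zero_weight_member_never_changes_outcome(self, rng):
        for _ in range(100):
            labels = rng.integers(0, 3, 3)
            weights = rng.uniform(0.1, 1.0, 3)
            with_zero = vote_weighted(
                np.append(labels, rng.integers(0, 3)),
                np.append(weights, 0.0),
                self.CLASSES,
            )
            assert with_zero == vote_weighted(labels, weights, self.CLASSES)

    def test_soft_average_and_tie_break(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8], [0.4, 0.6]])
        cls, combined = vote_soft(probs, np.ones(3))
        assert np.allclose(combined, [0.5, 0.5])
        assert cls == 0

    def test_soft_single_member_is_identity(self):
        cls, combined = vote_soft(np.array([[0.3, 0.7]]), np.array([2.0]))
        assert cls == 1
        assert np.allclose(combined, [0.3, 0.7])

    def test_soft_outputs_valid_distribution(self, rng):
        for _ in range(50):
            probs = rng.dirichlet(np.ones(4), size=(3, 5)).transpose(0, 1, 2)
            cls, combined = vote_soft(probs, rng.uniform(0.1, 1, 3))
            assert np.allclose(combined.sum(axis=1), 1.0)

    def test_soft_invariant_to_weight_rescaling(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(3, 8))
        w = rng.uniform(0.1, 1.0, 3)
        c1, p1 = vote_soft(probs, w)
        c2, p2 = vote_soft(probs, 7.3 * w)
        assert np.array_equal(c1, c2)
        assert np.allclose(p1, p2)

    def test_malformed_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            vote_soft(np.array([[0.5, 0.2]]), np.ones(1))


class TestEnsemble:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained(blob_frame):
        rows, labels = blob_frame
        config = EnsembleConfig(n_trees=10, n_rounds=10)
        return fit_ensemble(rows, labels, config), rows, labels

    def test_training_accuracy_on_separable_blobs(self, trained):
        model, rows, labels = trained
        classes, _ = ensemble_predict(model, rows)
        ens_acc = (classes == labels).mean()
        assert ens_acc >= 0.95
        # ensemble at least as good as its weakest member
        from cardioseg.ensemble import member_probabilities

        member = member_probabilities(model, rows)
        member_accs = [
            (model.class_order[m.argmax(axis=1)] == labels).mean()
            for m in member
        ]
        assert ens_acc >= min(member_accs)

    def test_soft_vote_is_compositional(self, trained):
        from cardioseg.ensemble import member_probabilities

        model, rows, _ = trained
        classes, combined = ensemble_predict(model, rows[:20])
        c2, p2 = vote_soft(
            member_probabilities(model, rows[:20]),
            model.voting.weights,
            class_order=model.class_order,
        )
        assert np.array_equal(classes, c2)
        assert np.allclose(combined, p2)

    def test_deterministic_given_seeds(self, blob_frame):
        rows, labels = blob_frame
        config = EnsembleConfig(n_trees=5, n_rounds=5)
        a = ensemble_predict(fit_ensemble(rows, labels, config), rows)[0]
        b = ensemble_predict(fit_ensemble(rows, labels, config), rows)[0]
        assert np.array_equal(a, b)

    def test_row_count_preserved_and_all_classes_scored(self, trained):
        model, rows, _ = trained
        classes, probs = ensemble_predict(model, rows[:13])
        assert classes.shape == (13,)
        assert probs.shape == (13, 3)

    def test_archive_round_trip(self, trained, tmp_path):
        model, rows, _ = trained
        path = tmp_path / "ensemble.joblib"
        save_ensemble(model, path)
        restored = load_ensemble(path)
        a = ensemble_predict(model, rows[:50])
        b = ensemble_predict(restored, rows[:50])
        assert np.array_equal(a[0], b[0])
        assert np.allclose(a[1], b[1])

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            fit_ensemble(rng.normal(size=(10, 3)), np.zeros(10, int))
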
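"""Feature discretization, ridge-logistic training, LOOV, ROC."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from cfcna import (CohortConfig, FeatureMatrix, SyntheticCohort,
                   balanced_subsample, binary_grouping, coefficient_report,
                   discretize_features, loov_evaluate, predict, roc_curve_auc,
                   train_model)
from cfcna.genome import BinGrid, Segment, SegmentSet


@pytest.fixture(scope="module")
def weak_cohort():
    """Moderately separable cohort for fast LOOV tests."""
    return SyntheticCohort(CohortConfig(seed=13, scale=0.02, n_controls=30))


@pytest.fixture(scope="module")
def weak_features(weak_cohort):
    states, labels, _ = weak_cohort.training_table(
        n_per_class=10, penetrance=0.9, tumor_fraction_range=(0.3, 0.8))
    return discretize_features(states, weak_cohort.grid, labels=labels)


class TestDiscretize:
    def test_gain_segment_marks_plus_one(self):
        grid = BinGrid.from_chromosomes([("1", 2_000_000)], bin_width=100_000)
        segs = SegmentSet("s", [
            Segment("1", 0, 9, 0.0, 1_000_000, 10, z_score=1.0, call="neutral"),
            Segment("1", 10, 19, 0.3, 1_000_000, 10, z_score=5.0, call="gain"),
        ])
        fm = discretize_features([segs], grid)
        assert np.all(fm.X[0, :10] == 0)
        assert np.all(fm.X[0, 10:] == 1)

    def test_all_neutral_sample_is_zero_row_and_flagged_flat(self):
        grid = BinGrid.from_chromosomes([("1", 1_000_000)], bin_width=100_000)
        segs = SegmentSet("s", [Segment("1", 0, 9, 0.0, 1_000_000, 10,
                                        z_score=0.0, call="neutral")])
        fm = discretize_features([segs], grid)
        assert not fm.X.any()
        assert fm.flat_rows()[0]

    @pytest.mark.parametrize("value,expected", [
        (0.25, 1), (0.1, 1), (0.09, 0), (-0.09, 0), (-0.1, -1), (-0.4, -1),
    ])
    def test_continuous_threshold_rule(self, value, expected):
        grid = BinGrid.from_chromosomes([("1", 300_000)], bin_width=100_000)
        fm = discretize_features(np.full((1, 3), value), grid, threshold=0.1)
        assert np.all(fm.X == expected)

    def test_masked_bins_dropped_consistently(self, tiny_grid):
        states = np.random.default_rng(0).normal(0, 0.3, (4, tiny_grid.n_bins))
        fm = discretize_features(states, tiny_grid)
        assert fm.X.shape[1] == int(tiny_grid.usable.sum())

    def test_uncovered_usable_bin_warns_and_stays_neutral(self):
        grid = BinGrid.from_chromosomes([("1", 1_000_000)], bin_width=100_000)
        segs = SegmentSet("s", [Segment("1", 0, 4, 0.3, 500_000, 5,
                                        z_score=4.0, call="gain")])
        with pytest.warns(UserWarning, match="covered by no segment"):
            fm = discretize_features([segs], grid)
        assert np.all(fm.X[0, 5:] == 0)


class TestBalancedSubsample:
    def test_downsamples_to_smallest_class(self, rng):
        labels = np.repeat(["LUAD", "LUSC", "SCLC"], [424, 351, 68])
        idx = balanced_subsample(labels, seed=0)
        assert idx.size == 204
        _, counts = np.unique(labels[idx], return_counts=True)
        assert np.all(counts == 68)

    def test_reproducible_and_without_replacement(self):
        labels = np.repeat(["a", "b"], [30, 50])
        i1 = balanced_subsample(labels, seed=5)
        i2 = balanced_subsample(labels, seed=5)
        assert np.array_equal(i1, i2)
        assert np.unique(i1).size == i1.size

    def test_already_balanced_keeps_everything(self):
        labels = np.repeat(["a", "b"], 20)
        idx = balanced_subsample(labels, seed=1)
        assert idx.size == 40


class TestRidgeReduction:
    def test_gram_reduced_fit_matches_direct_sklearn(self, rng):
        """The eigenbasis reduction solves the same convex problem as a
        direct fit on the raw features."""
        X = rng.choice([-1.0, 0.0, 1.0], size=(40, 15))
        y = rng.choice(["a", "b", "c"], 40)
        model = train_model(X, y, C=1.0)
        direct = LogisticRegression(C=1.0, solver="lbfgs",
                                    max_iter=5000, tol=1e-8).fit(X, y)
        p_red = model.predict_proba(X)
        p_dir = direct.predict_proba(X)
        assert np.allclose(p_red, p_dir, atol=1e-4)
        assert np.allclose(model.coef_centered(), direct.coef_ -
                           direct.coef_.mean(axis=0), atol=1e-3)

    def test_stronger_penalty_never_grows_coefficients(self, weak_features):
        norms = []
        for C in (1e-3, 1e-1, 1e1, 1e3):
            m = train_model(weak_features, C=C)
            norms.append(np.linalg.norm(m.coef))
        assert all(a <= b + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_separable_training_data_fits_perfectly(self, weak_features):
        m = train_model(weak_features, C=100.0)
        pred = predict(m, weak_features)
        acc = np.mean(pred["predicted"].to_numpy() == weak_features.labels)
        assert acc == 1.0

    def test_all_zero_features_give_uniform_probabilities(self):
        X = np.zeros((30, 8))
        y = np.repeat(["a", "b", "c"], 10)
        m = train_model(X, y, C=1.0)
        p = m.predict_proba(X)
        assert np.allclose(p, 1 / 3, atol=1e-6)
        assert np.allclose(m.coef, 0, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_model(np.zeros((10, 3)), np.repeat("a", 10))


class TestRocAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0], 1.0),     # perfect ranking
        ([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.0),     # reversed
        ([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0], 0.75),    # pair counting
    ])
    def test_worked_examples(self, scores, labels, expected):
        assert roc_curve_auc(scores, labels) == pytest.approx(expected)

    def test_ties_use_midrank(self):
        assert roc_curve_auc([0.5, 0.5], [1, 0]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_curve_auc([0.1, 0.2], [1, 1])


class TestLoov:
    def test_strong_fingerprints_classify_nearly_perfectly(self, weak_features):
        rep = loov_evaluate(weak_features, seed=0)
        assert rep.mauc >= 0.95
        assert abs(rep.proba.sum(axis=1) - 1).max() < 1e-9

    def test_permuted_labels_drop_to_chance(self, weak_features):
        rng = np.random.default_rng(3)
        fm = FeatureMatrix(weak_features.X,
                           rng.permutation(weak_features.labels),
                           weak_features.sample_ids,
                           weak_features.bin_indices)
        rep = loov_evaluate(fm, seed=0)
        assert abs(rep.mauc - 0.5) < 0.25  # wide band at n=30

    def test_identical_rerun_gives_identical_report(self, weak_features):
        r1 = loov_evaluate(weak_features, seed=4)
        r2 = loov_evaluate(weak_features, seed=4)
        assert np.array_equal(r1.proba, r2.proba)
        assert r1.mauc == r2.mauc

    def test_holdout_only_feature_cannot_leak(self, weak_features):
        """A label-revealing column present only at prediction time must
        not raise mAUC: training never sees informative values there."""
        X = weak_features.X
        classes = {c: k for k, c in enumerate(np.unique(weak_features.labels))}
        reveal = np.array([classes[c] - 1 for c in weak_features.labels])
        X_train = np.hstack([X, np.zeros((X.shape[0], 1), dtype=np.int8)])
        X_hold = np.hstack([X, reveal[:, None]]).astype(float)
        base = loov_evaluate(weak_features, seed=0)
        fm = FeatureMatrix(X_train, weak_features.labels,
                           weak_features.sample_ids,
                           np.arange(X_train.shape[1]))
        inj = loov_evaluate(fm, seed=0, holdout_X=X_hold)
        assert inj.mauc <= base.mauc + 0.02


class TestPredictAndReports:
    def test_training_row_repredicted_as_its_class(self, weak_features):
        m = train_model(weak_features, C=10.0)
        pred = predict(m, weak_features)
        assert (pred["predicted"].to_numpy() == weak_features.labels).all()

    def test_flat_row_flagged_and_predicts_prior_class(self, weak_features):
        m = train_model(weak_features, C=1.0)
        flat = FeatureMatrix(np.zeros((1, weak_features.X.shape[1]),
                                      dtype=np.int8),
                             None, ["flat"], weak_features.bin_indices)
        pred = predict(m, flat)
        assert pred["no_detectable_aberrations"][0]
        prior = m.classes[np.argmax(m.intercept)]
        assert pred["predicted"][0] == prior

    def test_bin_mismatch_rejected(self, weak_features):
        m = train_model(weak_features, C=1.0)
        with pytest.raises(ValueError):
            predict(m, np.zeros((2, 5)))

    def test_binary_grouping_uses_sclc_probability_exactly(self, weak_features):
        rep = loov_evaluate(weak_features, seed=0)
        bg = binary_grouping(rep.labels, rep.proba, rep.classes)
        k = list(rep.classes).index("SCLC")
        assert np.array_equal(bg["score"], rep.proba[:, k])
        assert bg["auc"] >= 0.9

    def test_coefficient_report_finds_the_planted_arm(self, weak_cohort,
                                                      weak_features):
        m = train_model(weak_features, C=1.0)
        per_bin, per_arm = coefficient_report(m, weak_cohort.grid, top_k=10)
        sclc_arms = per_arm[per_arm["class"] == "SCLC"]
        top = sclc_arms.reindex(
            sclc_arms["coef"].abs().sort_values(ascending=False).index
        )["arm"].head(4).tolist()
        # 3p loss (penetrance 0.9) is the strongest SCLC discriminator
        assert "3p" in top or "1p" in top
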
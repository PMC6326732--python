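"""Split-half protocols, the five classifiers, and confusion-matrix conventions."""

import numpy as np
import pandas as pd
import pytest

from cyclicity import CohortSpec, cohort_features, gen_cohort
from cyclicity.classify import (
    CLASSIFIERS,
    ClassificationProtocol,
    fit_predict,
    monte_carlo_classification,
    report,
    split_half,
    weighted_overall,
)
from cyclicity.core import DataError
from cyclicity.features import CohortFeatures

from conftest import make_feature_table


def gaussian_cohort(rng, n_a=12, n_b=12, n_feat=20, effect=0.0, runs=4):
    """Subject-structured Gaussian features with an optional group mean shift."""
    rows, X = [], []
    for g, gname, n in ((0, "a", n_a), (1, "b", n_b)):
        for s in range(n):
            center = rng.standard_normal(n_feat) * 0.3
            for r in range(runs):
                x = center + rng.standard_normal(n_feat)
                if g:
                    x[:3] += effect
                rows.append({"subject": f"{gname}{s:02d}", "group": gname,
                             "session": 1 + r // 2, "run": 1 + r % 2})
                X.append(x)
    pairs = [(f"p{i}", f"q{i}") for i in range(n_feat)]
    return CohortFeatures(pd.DataFrame(rows), np.array(X), pairs)


class TestSplitHalf:
    def test_study_sized_groups_split_subject_level(self):
        rng = np.random.default_rng(0)
        feats = gaussian_cohort(rng, n_a=15, n_b=32)
        train, test = split_half(feats, seed=1)
        tr = train.subject_group()
        assert (tr == "a").sum() == 7 and (tr == "b").sum() == 16
        assert len(train.meta) == 23 * 4 and len(test.meta) == 24 * 4
        assert not set(train.subjects) & set(test.subjects)

    def test_balancing_equalizes_training_groups(self):
        feats = gaussian_cohort(np.random.default_rng(1), n_a=6, n_b=14)
        train, _ = split_half(feats, balance=True, seed=2)
        counts = train.subject_group().value_counts()
        assert counts["a"] == counts["b"] == 3

    def test_same_seed_same_split(self):
        feats = gaussian_cohort(np.random.default_rng(2), n_a=5, n_b=5)
        t1, _ = split_half(feats, seed=3)
        t2, _ = split_half(feats, seed=3)
        assert t1.subjects == t2.subjects

    def test_tiny_group_rejected(self):
        feats = gaussian_cohort(np.random.default_rng(3), n_a=1, n_b=4)
        with pytest.raises(DataError):
            split_half(feats, seed=0)


class TestFitPredict:
    @pytest.mark.parametrize("classifier", CLASSIFIERS)
    def test_separable_cohort_classified_by_all_methods(self, classifier):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            feats = gaussian_cohort(rng, n_a=20, n_b=20, n_feat=8, effect=3.0)
            proto = ClassificationProtocol(feature_mode="raw", classifier=classifier)
            train, test = split_half(feats, seed=seed)
            pred = fit_predict(proto, train, test, seed=seed)
            accs.append(np.mean(pred == test.meta["group"].to_numpy()))
        assert np.mean(accs) >= 0.95

    def test_lda_behaves_like_nearest_class_mean(self):
        # equal within-class scatter puts the LDA boundary at the midpoint
        # of the class means (2.05 here)
        X = np.array([[0.0], [0.1], [4.0], [4.1]])
        feats = make_feature_table(X, ["a", "a", "b", "b"])
        test = make_feature_table(np.array([[1.9], [2.2]]), ["a", "b"])
        proto = ClassificationProtocol(feature_mode="raw", classifier="lda")
        pred = fit_predict(proto, feats, test)
        assert pred.tolist() == ["a", "b"]

    def test_pca_reduction_fitted_on_training_only(self):
        rng = np.random.default_rng(4)
        feats = gaussian_cohort(rng, effect=3.0, n_feat=30)
        proto = ClassificationProtocol(feature_mode="pca10", classifier="lda")
        train, test = split_half(feats, seed=5)
        pred = fit_predict(proto, train, test, seed=5)
        assert len(pred) == len(test.meta)


class TestReport:
    def test_weighted_accuracy_convention_linear_svm(self):
        # printed per-class rates and 15/32 group sizes reproduce the
        # published overall accuracy
        assert weighted_overall(np.array([26.73, 80.63]), [15, 32]) == pytest.approx(
            63.43, abs=0.01
        )

    def test_weighted_accuracy_convention_plsda(self):
        assert weighted_overall(np.array([50.47, 74.80]), [15, 32]) == pytest.approx(
            67.03, abs=0.01
        )

    def test_perfect_predictions(self):
        rep = report(np.array([[10, 0], [0, 20]]), [5, 10])
        assert np.array_equal(rep.matrix, np.array([[100.0, 0.0], [0.0, 100.0]]))
        assert rep.overall_accuracy == 100.0

    def test_rows_normalize_to_percentages(self):
        rep = report(np.array([[3, 1], [2, 6]]), [4, 8])
        assert np.allclose(rep.matrix.sum(axis=1), 100.0)

    def test_empty_row_rejected(self):
        with pytest.raises(DataError):
            report(np.array([[0, 0], [1, 1]]), [1, 1])


class TestMonteCarlo:
    def test_null_cohorts_balanced_near_chance(self):
        # exchangeable groups: accuracy at 50% on average.  A single cohort
        # carries a finite-sample conditional bias, so the null is averaged
        # over independent cohorts (one split trial each)
        accs = []
        for seed in range(40):
            feats = gaussian_cohort(np.random.default_rng(600 + seed), effect=0.0)
            proto = ClassificationProtocol(
                feature_mode="pca10", classifier="lda", n_trials=1, seed=seed
            )
            rep = monte_carlo_classification(proto, feats)
            c = rep.per_trial_counts[0]
            accs.append(np.trace(c) / c.sum())
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < max(3 * se, 0.05)

    def test_unbalanced_null_shows_majority_bias(self):
        spec = CohortSpec(
            n_group_a=8, n_group_b=20, n_channels=10, n_samples=150, n_periods=5,
            ordering_jitter_a=0.3, ordering_jitter_b=0.3, seed=13,
        )
        feats = cohort_features(gen_cohort(spec))
        proto = ClassificationProtocol(
            feature_mode="pca10", classifier="linear_svm", n_trials=30, seed=8
        )
        rep = monte_carlo_classification(proto, feats)
        minority, majority = np.diag(rep.matrix)
        assert majority > minority + 10.0

    def test_deterministic_given_seed(self):
        feats = gaussian_cohort(np.random.default_rng(9), n_a=6, n_b=6)
        proto = ClassificationProtocol(
            feature_mode="pca10", classifier="lda", n_trials=5, seed=11
        )
        r1 = monte_carlo_classification(proto, feats)
        r2 = monte_carlo_classification(proto, feats)
        assert np.array_equal(r1.matrix, r2.matrix)
        assert r1.trial_seeds == r2.trial_seeds

    def test_label_permutation_drops_effect_to_chance(self):
        rng = np.random.default_rng(10)
        feats = gaussian_cohort(rng, effect=2.0, n_a=8, n_b=8)
        # permute group labels at the subject level
        sg = feats.subject_group()
        perm = rng.permutation(sg.to_numpy())
        permuted_groups = dict(zip(sg.index, perm))
        meta = feats.meta.copy()
        meta["group"] = meta["subject"].map(permuted_groups)
        shuffled = CohortFeatures(meta, feats.X, feats.pair_index)
        proto = ClassificationProtocol(
            feature_mode="pca10", classifier="lda", n_trials=40, seed=12
        )
        rep = monte_carlo_classification(proto, shuffled)
        accs = [np.trace(c) / c.sum() for c in rep.per_trial_counts]
        assert abs(np.mean(accs) - 0.5) < 0.10


class TestFeatureModeOrdering:
    def test_wilks_stable_beats_pca_when_signal_off_principal_axes(self):
        # dominant shared variance concentrated on specific (non-
        # discriminative) pairs drowns PCA-10, while Wilks stability
        # selection targets the weak localized contrast directly
        def cohort(seed, n_sub=12, n_pairs=120, runs=4):
            rng = np.random.default_rng(seed)
            U = np.zeros((4, n_pairs))
            dom = rng.choice(np.arange(10, n_pairs), size=30, replace=False)
            U[:, dom] = rng.standard_normal((4, 30)) * 6.0
            rows, X = [], []
            for g, gname in ((0, "a"), (1, "b")):
                for s in range(n_sub):
                    z = rng.standard_normal(4)
                    for r in range(runs):
                        x = z @ U + rng.standard_normal(n_pairs)
                        if g:
                            x[:3] += 1.2
                        rows.append({"subject": f"{gname}{s}", "group": gname,
                                     "session": 1 + r // 2, "run": 1 + r % 2})
                        X.append(x)
            pairs = [(f"p{i}", f"q{i}") for i in range(n_pairs)]
            return CohortFeatures(pd.DataFrame(rows), np.array(X), pairs)

        diffs = []
        for seed in range(5):
            cf = cohort(seed)
            wilks = monte_carlo_classification(
                ClassificationProtocol(
                    feature_mode="wilks_top10_stable", classifier="plsda",
                    n_trials=12, stability_trials=100, seed=seed,
                ),
                cf,
            ).overall_accuracy
            pca = monte_carlo_classification(
                ClassificationProtocol(
                    feature_mode="pca10", classifier="plsda", n_trials=12, seed=seed
                ),
                cf,
            ).overall_accuracy
            diffs.append(wilks - pca)
        assert np.mean(diffs) > 5.0
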
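"""VRS binarization, ROC/AUC against a pair-counting oracle, Youden
cutoff selection, feature importances, and the cross-validated grader."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctatrophy.grading import (
    HyperSearchSpec,
    binarize_vrs,
    evaluate_cv,
    feature_importance,
    fit_grader,
    roc_and_auc,
    youden_cutoff,
)


def auc_by_pair_counting(scores, labels):
    """Independent oracle: concordant pairs / all pos-neg pairs, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestBinarizeVrs:
    @pytest.mark.parametrize("region,score,expected", [
        ("FA", 0, False), ("FA", 1, False), ("FA", 2, True), ("FA", 3, True),
        ("PA", 0, False), ("PA", 1, False), ("PA", 2, True), ("PA", 3, True),
        ("MTAR", 0, False), ("MTAR", 1, False), ("MTAR", 2, True),
        ("MTAR", 3, True), ("MTAR", 4, True),
        ("MTAL", 0, False), ("MTAL", 1, False), ("MTAL", 2, True),
        ("MTAL", 3, True), ("MTAL", 4, True),
    ])
    def test_clinical_rule_on_every_valid_score(self, region, score, expected):
        assert binarize_vrs(score, region) is expected

    def test_out_of_scale_score_named_in_error(self):
        with pytest.raises(ValueError, match="FA"):
            binarize_vrs(4, "FA")
        with pytest.raises(ValueError, match="MTAL"):
            binarize_vrs(5, "MTAL")

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            binarize_vrs(1, "occipital")

    @pytest.mark.parametrize("region", ["FA", "PA", "MTAR", "MTAL"])
    def test_monotone_in_score(self, region):
        from ctatrophy.grading import REGION_SCALE_MAX
        vals = [binarize_vrs(s, region) for s in range(REGION_SCALE_MAX[region] + 1)]
        assert vals == sorted(vals)


class TestRocAndAuc:
    def test_four_subject_hand_example(self):
        # pairs: (0.35 vs 0.1) win, (0.35 vs 0.4) loss, (0.8 vs both) wins
        _, auc = roc_and_auc([0.1, 0.4, 0.35, 0.8], [False, False, True, True])
        assert auc == pytest.approx(0.75)

    def test_perfect_ranking(self):
        _, auc = roc_and_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_and_auc([0.5] * 6, [True, False, True, False, True, False])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([0.1, 0.9], [True, True])

    def test_roc_rates_are_monotone(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.uniform(size=40) < 0.5
        labels[:2] = [True, False]
        pts, _ = roc_and_auc(scores, labels)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**30 - 1), st.integers(4, 50))
    def test_matches_pair_counting_oracle(self, seed, n):
        r = np.random.default_rng(seed)
        scores = np.round(r.uniform(size=n), 2)  # coarse grid forces ties
        labels = r.uniform(size=n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        _, auc = roc_and_auc(scores, labels)
        assert auc == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)


class TestYoudenCutoff:
    def test_perfect_classifier_reaches_j_one(self):
        pts, _ = roc_and_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        cutoff, sens, spec, acc, j = youden_cutoff(pts, 2, 2)
        assert (sens, spec, acc, j) == (1.0, 1.0, 1.0, 1.0)

    def test_j_equals_sens_plus_spec_minus_one(self):
        # operating point printed for frontal atrophy grading
        pts = np.array([[0.0, 0.0, np.inf], [1 - 0.6727, 0.9362, 0.4], [1.0, 1.0, 0.0]])
        _, sens, spec, _, j = youden_cutoff(pts, 47, 110)
        assert j == pytest.approx(0.6089, abs=1e-4)
        assert j == sens + spec - 1.0

    def test_tie_breaks_toward_higher_sensitivity(self):
        pts = np.array([
            [0.0, 0.0, np.inf],
            [0.2, 0.8, 0.7],   # J = 0.6, sens 0.8
            [0.3, 0.9, 0.5],   # J = 0.6, sens 0.9  <- preferred
            [1.0, 1.0, 0.0],
        ])
        cutoff, sens, spec, _, _ = youden_cutoff(pts, 10, 10)
        assert (sens, spec) == (0.9, 0.7)
        assert cutoff == 0.5

    def test_accuracy_uses_class_counts(self):
        pts = np.array([[0.1, 0.9, 0.5]])
        _, sens, spec, acc, _ = youden_cutoff(pts, 30, 70)
        assert acc == pytest.approx((0.9 * 30 + 0.9 * 70) / 100)

    def test_empty_roc_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff(np.empty((0, 3)), 1, 1)


class TestFeatureImportance:
    def test_equal_magnitudes_share_uniformly(self):
        imp = feature_importance([0.3, -0.3, 0.3, -0.3, 0.3, -0.3, 0.3, -0.3])
        assert imp == pytest.approx([0.125] * 8)

    def test_single_nonzero_takes_all(self):
        imp = feature_importance([0, 0, 0, 2.5, 0, 0, 0, 0])
        assert imp[3] == 1.0 and imp.sum() == 1.0

    def test_published_frontal_magnitudes_are_sum_normalized(self):
        printed = [0.148, 0.182, 0.181, 0.0680, 0.104, 0.124, 0.146, 0.0477]
        imp = feature_importance(printed)
        assert imp.sum() == pytest.approx(1.0)
        # printed values sum to ~1.0007, i.e. they are already normalized
        assert np.abs(imp - np.array(printed)).max() < 2e-3

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            feature_importance([0.0] * 8)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**30 - 1))
    def test_normalization_on_random_coefficients(self, seed):
        c = np.random.default_rng(seed).normal(size=8)
        if np.all(c == 0):
            c[0] = 1.0
        imp = feature_importance(c)
        assert imp.sum() == pytest.approx(1.0)
        assert np.all((imp >= 0) & (imp <= 1))


def _separable_data(n=60, seed=0):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, 8))
    y = X[:, 2] + 0.01 * r.normal(size=n) > 0
    return X, y


class TestFitGrader:
    def test_separable_feature_gives_training_auc_one(self):
        X, y = _separable_data()
        g = fit_grader(X, y, HyperSearchSpec(n_draws=10, seed=0))
        _, auc = roc_and_auc(g.predict_proba(X), y)
        assert auc == 1.0

    def test_same_seed_reproduces_choice_and_coefficients(self):
        X, y = _separable_data(seed=3)
        spec = HyperSearchSpec(n_draws=8, seed=5)
        a, b = fit_grader(X, y, spec), fit_grader(X, y, spec)
        assert a.chosen_hyperparams == b.chosen_hyperparams
        assert np.array_equal(a.coefficients, b.coefficients)

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 8))
        with pytest.raises(ValueError, match="per class"):
            fit_grader(X, np.ones(20, bool), HyperSearchSpec(n_draws=2))

    def test_constant_feature_dropped_with_warning(self):
        X, y = _separable_data(seed=1)
        X[:, 5] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            g = fit_grader(X, y, HyperSearchSpec(n_draws=4, seed=2))
        assert g.coefficients[5] == 0.0


class TestEvaluateCv:
    def test_permuted_labels_destroy_auc(self):
        r = np.random.default_rng(7)
        X = r.normal(size=(200, 8))
        y = r.permutation(np.repeat([True, False], 100))
        res = evaluate_cv(X, y, HyperSearchSpec(n_draws=6, seed=7))
        assert 0.35 <= res.auc <= 0.65

    def test_minimal_six_subject_cohort_completes(self):
        r = np.random.default_rng(1)
        X = r.normal(size=(6, 8))
        y = np.array([True, False, True, False, True, False])
        res = evaluate_cv(X, y, HyperSearchSpec(n_draws=3, seed=1))
        assert 0.0 <= res.auc <= 1.0
        assert res.youden_j == pytest.approx(res.sens + res.spec - 1.0)
        assert res.importance.sum() == pytest.approx(1.0)

    def test_j_identity_holds_on_random_cohorts(self):
        for seed in range(3):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 8))
            y = X[:, 0] + r.normal(size=40) > 0
            if y.sum() < 2 or (~y).sum() < 2:
                continue
            res = evaluate_cv(X, y, HyperSearchSpec(n_draws=4, seed=seed))
            assert res.youden_j == res.sens + res.spec - 1.0

    def test_result_serializes_to_json_dict(self):
        X, y = _separable_data(seed=9)
        res = evaluate_cv(X, y, HyperSearchSpec(n_draws=3, seed=9), region="FA")
        d = res.to_dict()
        assert d["region"] == "FA"
        assert set(d["importance"]) == {
            "GMR3D", "WMR3D", "GMWMR3D", "Ven3D", "GMR2D", "WMR2D", "GMWMR2D", "Ven2D",
        }
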
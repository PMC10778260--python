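"""ROC sweep, AUC, Youden cutoff, bootstrap CI and confusion statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctresp import (
    CohortRecord,
    Response,
    auc,
    binarize_assessment,
    bootstrap_auc_ci,
    calibrate,
    confusion_stats,
    mann_whitney_auc,
    optimal_cutoff,
    roc_curve,
)
from cbctresp.calibration import classify_cohort


def cohort(controlled_scores, progression_scores):
    recs = [
        CohortRecord(f"c{i}", s, Response.CONTROLLED)
        for i, s in enumerate(controlled_scores)
    ]
    recs += [
        CohortRecord(f"p{i}", s, Response.PROGRESSION)
        for i, s in enumerate(progression_scores)
    ]
    return recs


def random_cohort(rng, n=10):
    scores = rng.uniform(0.3, 1.7, size=n)
    labels = [Response.CONTROLLED] * (n // 2) + [Response.PROGRESSION] * (n - n // 2)
    order = rng.permutation(n)
    return [
        CohortRecord(str(i), float(scores[i]), labels[order[i]]) for i in range(n)
    ]


class TestBinarize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("response", Response.CONTROLLED),
            ("stable", Response.CONTROLLED),
            ("progression", Response.PROGRESSION),
        ],
    )
    def test_collapse(self, raw, expected):
        assert binarize_assessment(raw) is expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            binarize_assessment("regression?")


class TestConfusionStats:
    def test_perfect_classifier(self):
        cs = confusion_stats(10, 0, 0, 10)
        assert (cs.accuracy, cs.sensitivity, cs.specificity, cs.ppv, cs.npv) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_cohort_counts_reproduce_reported_fractions(self):
        # the unique (tp, fn, fp, tn) split of 134 cases with 10 progressions
        cs = confusion_stats(117, 7, 1, 9)
        assert round(cs.accuracy, 2) == 0.94
        assert round(cs.sensitivity, 2) == 0.94
        assert round(cs.specificity, 2) == 0.90
        assert round(cs.ppv, 2) == 0.99
        assert round(cs.npv, 2) == 0.56

    def test_undefined_ratio_is_absent_not_zero(self):
        cs = confusion_stats(0, 0, 5, 5)
        assert cs.sensitivity is None
        assert cs.specificity == 0.5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            confusion_stats(0, 0, 0, 0)


class TestROCCurve:
    def test_separable_cohort_reaches_perfect_point(self):
        roc = roc_curve(cohort([0.5, 0.6], [1.5, 1.6]))
        j = roc.sens + roc.spec - 1.0
        assert j.max() == pytest.approx(1.0)

    def test_sweep_matches_brute_force_counts(self):
        rng = np.random.default_rng(7)
        recs = random_cohort(rng, n=10)
        roc = roc_curve(recs)
        pos = [r.score for r in recs if r.label is Response.CONTROLLED]
        neg = [r.score for r in recs if r.label is Response.PROGRESSION]
        for c, s, p in zip(roc.cutoffs, roc.sens, roc.spec):
            # exhaustive tabulation oracle at each cutoff
            assert s == pytest.approx(sum(x <= c for x in pos) / len(pos))
            assert p == pytest.approx(sum(x > c for x in neg) / len(neg))

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            roc_curve(cohort([1.0, 1.0], [1.0]))

    def test_single_class_rejected(self):
        recs = [CohortRecord("a", 0.5, Response.CONTROLLED)]
        with pytest.raises(ValueError, match="both"):
            roc_curve(recs)


class TestAUC:
    def test_perfect_separation(self):
        assert auc(roc_curve(cohort([0.5, 0.6], [1.5, 1.6]))) == pytest.approx(1.0)

    def test_trapezoid_equals_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            recs = random_cohort(rng, n=8)
            assert auc(roc_curve(recs)) == pytest.approx(
                mann_whitney_auc(recs), abs=1e-9
            )

    def test_trapezoid_equals_pairwise_with_ties(self):
        recs = cohort([0.5, 0.9, 0.9, 1.1], [0.9, 1.1, 1.3])
        assert auc(roc_curve(recs)) == pytest.approx(mann_whitney_auc(recs), abs=1e-9)

    def test_matches_sklearn_oracle(self):
        # independent reference: scikit-learn on the equivalent orientation
        # (controlled = positive class ranked by NEGATED score)
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(10):
            recs = random_cohort(rng, n=12)
            y = [1 if r.label is Response.CONTROLLED else 0 for r in recs]
            s = [-r.score for r in recs]
            assert auc(roc_curve(recs)) == pytest.approx(roc_auc_score(y, s), abs=1e-9)

    def test_null_mean_near_half(self):
        # permuted labels: mean AUC over many cohorts concentrates at 0.5
        rng = np.random.default_rng(11)
        aucs = [mann_whitney_auc(random_cohort(rng, n=10)) for _ in range(500)]
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 1e-12

    def test_score_negation_complements(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0.2, 2.0, size=12)
        labels = [Response.CONTROLLED] * 6 + [Response.PROGRESSION] * 6
        fwd = [CohortRecord(str(i), s, l) for i, (s, l) in enumerate(zip(scores, labels))]
        rev = [
            CohortRecord(str(i), 3.0 - s, l)
            for i, (s, l) in enumerate(zip(scores, labels))
        ]
        assert auc(roc_curve(fwd)) + auc(roc_curve(rev)) == pytest.approx(1.0)


class TestOptimalCutoff:
    def test_separable_midpoint(self):
        roc = roc_curve(cohort([0.5, 0.6], [1.5, 1.6]))
        assert optimal_cutoff(roc) == pytest.approx(1.05)

    def test_matches_exhaustive_j(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            recs = random_cohort(rng, n=10)
            roc = roc_curve(recs)
            j = roc.sens + roc.spec - 1.0
            best_j = j.max()
            cut = optimal_cutoff(roc)
            i = int(np.argmin(np.abs(roc.cutoffs - cut)))
            assert j[i] == pytest.approx(best_j)
            # tie-break: no smaller cutoff attains the same J
            smaller = roc.cutoffs < cut - 1e-12
            assert not np.any(j[smaller] >= best_j - 1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        """exp() on all scores maps the Youden cutoff through the transform."""
        rng = np.random.default_rng(seed)
        recs = random_cohort(rng, n=10)
        cut = optimal_cutoff(roc_curve(recs))
        warped = [CohortRecord(r.patient_id, float(np.exp(r.score)), r.label) for r in recs]
        warped_cut = optimal_cutoff(roc_curve(warped))
        # same records fall on each side of the cutoff before and after
        for r, w in zip(recs, warped):
            assert (r.score <= cut) == (w.score <= warped_cut)


class TestBootstrapCI:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        recs = random_cohort(rng, n=14)
        assert bootstrap_auc_ci(recs, reps=200, seed=5) == bootstrap_auc_ci(
            recs, reps=200, seed=5
        )

    def test_separable_upper_bound_is_one(self):
        recs = cohort([0.5, 0.6, 0.7], [1.5, 1.6])
        lo, hi = bootstrap_auc_ci(recs, reps=200, seed=0)
        assert hi == 1.0

    def test_wider_level_never_shrinks(self):
        rng = np.random.default_rng(4)
        recs = random_cohort(rng, n=14)
        lo90, hi90 = bootstrap_auc_ci(recs, reps=400, seed=1, level=0.90)
        lo99, hi99 = bootstrap_auc_ci(recs, reps=400, seed=1, level=0.99)
        assert lo99 <= lo90 and hi99 >= hi90

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_auc_ci(cohort([0.5], [1.5]), reps=10)


class TestCalibrate:
    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(8)
        recs = random_cohort(rng, n=16)
        roc = calibrate(recs, bootstrap_reps=200, seed=0)
        lo, hi = roc.auc_ci
        assert lo <= roc.auc <= hi

    def test_confusion_consistent_with_reclassification(self):
        rng = np.random.default_rng(12)
        recs = random_cohort(rng, n=16)
        roc = calibrate(recs, bootstrap_reps=200, seed=0)
        direct = classify_cohort(recs, roc.optimal_cutoff)
        assert roc.confusion_at_optimal.as_dict() == direct.as_dict()
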
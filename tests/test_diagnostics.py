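import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ppixdx import (
    ConfusionMatrix,
    CutoffClassifier,
    auc_ci_bootstrap,
    calibrate,
    classify,
    closest_topleft_cutoff,
    confusion_from_rates,
    mann_whitney,
    metrics,
    roc_curve,
    youden_cutoff,
)
from ppixdx.exceptions import (
    DataError,
    SingleClassError,
    UndefinedMetricError,
    ValidationError,
)


def random_table(rng, n_pos=None, n_neg=None, ties=True):
    n_pos = n_pos or rng.integers(2, 20)
    n_neg = n_neg or rng.integers(2, 20)
    pool = rng.integers(0, 12, size=n_pos + n_neg) if ties else rng.normal(
        size=n_pos + n_neg
    )
    scores = pool.astype(float)
    labels = np.array([1] * n_pos + [0] * n_neg)
    return scores, labels


def pairwise_auc(scores, labels):
    """Independent oracle: (pairs with pos > neg + half ties) / (n1 n2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([3, 4], [1, 2])
        assert res.u == 4.0  # n1 * n2

    def test_identical_groups_give_half(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u == 4.5
        assert res.p_value == pytest.approx(1.0)

    def test_pairwise_count_example(self):
        assert mann_whitney([5, 6, 7], [1, 2, 8]).u == 6.0

    def test_small_samples_use_exact_enumeration(self):
        res = mann_whitney([3, 4, 9], [1, 2, 8])
        assert res.method == "exact"
        ref = stats.mannwhitneyu([3, 4, 9], [1, 2, 8], alternative="two-sided",
                                 method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_p_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 1, 30)
        y = rng.normal(0.0, 1, 25)
        res = mann_whitney(x, y)
        assert res.method == "normal"
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.u == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_handled_in_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 5, 20).astype(float)
        y = rng.integers(1, 6, 20).astype(float)
        res = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            mann_whitney([], [1.0])


class TestRocCurve:
    def test_complete_separation_auc_one(self):
        roc = roc_curve([5, 6, 1, 2], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_uninformative_scores_auc_half(self):
        roc = roc_curve([2.0, 1.0, 3.0], [1, 0, 0])
        assert roc.auc == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_auc_equals_mann_whitney_u_over_pairs(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_table(rng)
        roc = roc_curve(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = mann_whitney(pos, neg).u
        assert roc.auc == pytest.approx(u / (pos.size * neg.size), abs=1e-12)
        assert roc.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_label_flip_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_table(rng)
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, 1 - labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_curve([1.0, 2.0], [1, 1])

    def test_operating_points_monotone(self):
        rng = np.random.default_rng(5)
        scores, labels = random_table(rng)
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.sensitivities) >= 0)
        assert np.all(np.diff(roc.one_minus_specificities) >= 0)


class TestYoudenCutoff:
    def test_complete_separation_returns_gap_midpoint(self):
        roc = roc_curve([10, 20, 1, 2], [1, 1, 0, 0])
        assert youden_cutoff(roc) == pytest.approx(6.0)  # (2 + 10) / 2

    def test_single_positive_above_negatives(self):
        roc = roc_curve([10, 1, 2, 3], [1, 0, 0, 0])
        cutoff = youden_cutoff(roc)
        assert 3.0 < cutoff <= 10.0
        cm = classify([10, 1, 2, 3], [1, 0, 0, 0], cutoff)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 3)

    def test_tie_broken_toward_higher_specificity(self):
        # J = 0.5 both at threshold 4 (sens .5, spec 1) and threshold 2
        # (sens 1, spec .5): the higher-specificity threshold wins.
        scores = [2.0, 4.0, 1.0, 3.0]
        labels = [1, 1, 0, 0]
        roc = roc_curve(scores, labels)
        cutoff = youden_cutoff(roc)
        assert cutoff == pytest.approx(3.5)
        cm = classify(scores, labels, cutoff)
        assert cm.fp == 0

    def test_closest_topleft_alternative_rule(self):
        roc = roc_curve([10, 20, 1, 2], [1, 1, 0, 0])
        assert closest_topleft_cutoff(roc) == pytest.approx(6.0)

    def test_calibrate_embeds_cutoff(self):
        roc = calibrate([10, 20, 1, 2], [1, 1, 0, 0], rule="youden")
        assert roc.cutoff == pytest.approx(6.0)
        assert roc.cutoff_rule == "youden"
        with pytest.raises(ValidationError):
            calibrate([1, 2], [1, 0], rule="nope")


class TestClassifyAndMetrics:
    def test_all_below_cutoff(self):
        cm = classify([1, 2, 3], [1, 0, 1], cutoff=10.0)
        assert (cm.tp, cm.fp) == (0, 0) and (cm.fn, cm.tn) == (2, 1)

    def test_minus_infinity_cutoff(self):
        cm = classify([1, 2, 3], [1, 0, 1], cutoff=-np.inf)
        assert (cm.fn, cm.tn) == (0, 0)

    def test_tie_goes_to_positive(self):
        cm = classify([5.0], [0], cutoff=5.0)
        assert cm.fp == 1

    def test_hand_enumerated_toy_table(self):
        scores = [0.1, 0.4, 0.6, 0.8, 0.9]
        labels = [0, 0, 1, 0, 1]
        cm = classify(scores, labels, cutoff=0.5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 0, 2)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((16, 6, 3, 186), (84.2, 96.9, 95.7)),
            ((16, 7, 3, 185), (84.2, 96.4, 95.3)),
            ((15, 9, 4, 183), (78.9, 95.3, 93.8)),
        ],
    )
    def test_metric_triples_from_published_device_counts(self, counts, expected):
        tp, fp, fn, tn = counts
        assert metrics(ConfusionMatrix(tp, fp, fn, tn)) == expected

    def test_rounding_is_half_up(self):
        # 1/16 = 6.25 % -> 6.3 with half-up (6.2 under banker's rounding)
        sens, _, _ = metrics(ConfusionMatrix(tp=1, fp=0, fn=15, tn=4))
        assert sens == 6.3

    def test_undefined_metric_named(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            metrics(ConfusionMatrix(0, 1, 0, 5))
        with pytest.raises(UndefinedMetricError, match="specificity"):
            metrics(ConfusionMatrix(1, 0, 5, 0))

    def test_metrics_permutation_invariant(self):
        rng = np.random.default_rng(6)
        scores, labels = random_table(rng)
        perm = rng.permutation(scores.size)
        a = classify(scores, labels, 5.0)
        b = classify(scores[perm], labels[perm], 5.0)
        assert a == b

    def test_confusion_from_published_rates(self):
        cm = confusion_from_rates(41, 282, 78.0, 96.8)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (32, 9, 9, 273)


class TestBootstrapCI:
    def test_complete_separation_interval_is_degenerate(self):
        lo, hi = auc_ci_bootstrap([5, 6, 1, 2], [1, 1, 0, 0], n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_interval_contains_point_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_table(rng, n_pos=15, n_neg=15, ties=False)
        auc = roc_curve(scores, labels).auc
        lo, hi = auc_ci_bootstrap(scores, labels, n_boot=400, seed=seed)
        assert lo - 0.02 <= auc <= hi + 0.02

    def test_interval_narrows_with_sample_size(self):
        rng = np.random.default_rng(7)

        def width(n):
            scores = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
            labels = np.array([1] * n + [0] * n)
            lo, hi = auc_ci_bootstrap(scores, labels, n_boot=300, seed=1)
            return hi - lo

        assert width(400) < width(50)


class TestCutoffClassifier:
    def test_fit_predict_on_separated_scores(self):
        X = np.array([[10.0], [20.0], [1.0], [2.0]])
        y = np.array(["metastatic", "metastatic", "benign", "benign"])
        clf = CutoffClassifier(pos_label="metastatic").fit(X, y)
        assert clf.auc_ == 1.0
        assert 2.0 < clf.cutoff_ < 10.0
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_sklearn_clone_and_pipeline(self, noiseless_separated_cohort):
        from sklearn.base import clone
        from sklearn.pipeline import Pipeline

        from ppixdx import DifferentialScorer

        _config, records, _truth = noiseless_separated_cohort
        labels = np.array([r.label for r in records])
        pipe = Pipeline(
            [
                ("score", DifferentialScorer()),
                ("classify", CutoffClassifier(pos_label="metastatic")),
            ]
        )
        clone(pipe)  # parameters round-trip
        pipe.fit(records, labels)
        assert pipe.score(records, labels) == 1.0

    def test_unknown_pos_label_rejected(self):
        with pytest.raises(ValidationError, match="pos_label"):
            CutoffClassifier(pos_label="x").fit([[1.0], [2.0]], ["a", "b"])
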
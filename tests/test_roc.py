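"""ROC machinery: pair counting, Youden scan, DeLong, LOOCV, power."""

import numpy as np
import pytest

from frorfot.roc import (
    accuracy_class,
    auc_mann_whitney,
    compare_aucs_paired,
    hanley_mcneil_n,
    loocv_threshold_roc,
    roc_analysis,
)


def brute_force_auc(scores, labels):
    """Oracle: exhaustive concordant-pair counting with ties credited 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels, orientation):
    """Oracle: exhaustive scan of J over observed thresholds."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = (-np.inf, None, None, None)
    for t in np.unique(scores):
        if orientation == "higher":
            se, sp = (pos > t).mean(), (neg <= t).mean()
        else:
            se, sp = (pos <= t).mean(), (neg > t).mean()
        j = se + sp - 1
        # ties toward higher specificity
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and sp > best[3]):
            best = (j, t, se, sp)
    return best


class TestAUC:
    def test_small_example_three_of_four_pairs_concordant(self):
        res = roc_analysis(np.array([3.0, 5.0, 1.0, 4.0]), np.array([1, 1, 0, 0]))
        assert res.auc == pytest.approx(0.75)
        assert res.orientation == "higher"

    def test_perfect_separation(self):
        res = roc_analysis(np.array([1.0, 2.0, 10.0, 11.0]), np.array([0, 0, 1, 1]))
        assert res.auc == 1.0
        assert res.se_at_cutoff == 100.0
        assert res.sp_at_cutoff == 100.0

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.sum() < 2 or (1 - labels).sum() < 2:
                continue
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_permuted_labels_average_half(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = np.array([0] * 20 + [1] * 20)
        aucs = []
        for _ in range(500):
            aucs.append(auc_mann_whitney(scores, rng.permutation(labels)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_all_tied_scores_flagged(self):
        res = roc_analysis(np.ones(10), np.array([0, 1] * 5))
        assert res.auc == 0.5
        assert not res.cutoff_defined

    def test_one_class_missing_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(5.0), np.ones(5, dtype=int))


class TestYoudenCutoff:
    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 30))
            scores = np.round(rng.normal(0, 1, n), 1)
            labels = rng.integers(0, 2, n)
            if labels.sum() < 2 or (1 - labels).sum() < 2:
                continue
            res = roc_analysis(scores, labels)
            if not res.cutoff_defined:
                continue
            j, t, se, sp = brute_force_youden(scores, labels, res.orientation)
            assert res.cutoff == pytest.approx(t)
            assert res.se_at_cutoff == pytest.approx(se * 100)
            assert res.sp_at_cutoff == pytest.approx(sp * 100)

    def test_se_sp_recompute_from_confusion_matrix(self, rng):
        scores = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        res = roc_analysis(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        if res.orientation == "higher":
            se, sp = (pos > res.cutoff).mean(), (neg <= res.cutoff).mean()
        else:
            se, sp = (pos <= res.cutoff).mean(), (neg > res.cutoff).mean()
        assert res.se_at_cutoff == pytest.approx(se * 100)
        assert res.sp_at_cutoff == pytest.approx(sp * 100)

    def test_criterion_string_orientation(self):
        res = roc_analysis(np.array([1.0, 2.0, 10.0, 11.0]), np.array([0, 0, 1, 1]))
        assert res.criterion.startswith("> ")
        res_low = roc_analysis(np.array([10.0, 11.0, 1.0, 2.0]), np.array([0, 0, 1, 1]))
        assert res_low.criterion.startswith("<= ")


class TestMonotoneInvariance:
    def test_increasing_transform_preserves_everything(self, rng):
        scores = rng.normal(0, 1, 44)
        labels = np.array([0] * 23 + [1] * 21)
        a = roc_analysis(scores, labels)
        b = roc_analysis(np.exp(scores) + 3, labels)
        assert a.auc == b.auc
        assert a.se_at_cutoff == b.se_at_cutoff
        assert a.sp_at_cutoff == b.sp_at_cutoff

    def test_decreasing_transform_flips_orientation_only(self, rng):
        # the beta/eta pair: eta = cot(pi*beta/2) is strictly decreasing,
        # so both parameters must print identical AUC/Se/Sp rows
        beta = rng.uniform(0.4, 0.9, 44)
        labels = np.array([0] * 23 + [1] * 21)
        eta = np.cos(np.pi * beta / 2) / np.sin(np.pi * beta / 2)
        a = roc_analysis(beta, labels)
        b = roc_analysis(eta, labels)
        assert a.orientation != b.orientation
        assert a.auc == b.auc
        assert a.se_at_cutoff == b.se_at_cutoff
        assert a.sp_at_cutoff == b.sp_at_cutoff


class TestAccuracyClass:
    @pytest.mark.parametrize(
        "auc,cls,adequate",
        [
            (0.967, "high", True),
            (0.74, "moderate", False),
            (0.75, "moderate", True),
            (0.90, "moderate", True),
            (0.65, "low", False),
            (0.70, "low", False),
            (1.0, "high", True),
        ],
    )
    def test_bins_and_adequacy(self, auc, cls, adequate):
        assert accuracy_class(auc) == (cls, adequate)

    def test_unoriented_auc_rejected(self):
        with pytest.raises(ValueError):
            accuracy_class(0.4)


class TestDeLong:
    def test_identical_scores_give_zero_delta_unit_p(self, rng):
        s = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        res = compare_aucs_paired(s, s.copy(), labels)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_affine_transform_gives_zero_delta(self, rng):
        s = rng.normal(0, 1, 30)
        labels = np.array([0] * 15 + [1] * 15)
        res = compare_aucs_paired(s, 2 * s + 7, labels)
        assert res.delta == 0.0

    def test_agrees_with_stratified_bootstrap(self):
        rng = np.random.default_rng(77)
        n = 20
        labels = np.array([0] * n + [1] * n)
        sa = np.r_[rng.normal(0, 1, n), rng.normal(1.5, 1, n)]
        sb = 0.5 * sa + rng.normal(0, 1, 2 * n)
        res = compare_aucs_paired(sa, sb, labels)

        # bootstrap oracle: resample subjects within class, CI-based p
        deltas = []
        idx0, idx1 = np.arange(n), np.arange(n, 2 * n)
        for _ in range(2000):
            b = np.r_[rng.choice(idx0, n), rng.choice(idx1, n)]
            da = auc_mann_whitney(sa[b], labels)
            db = auc_mann_whitney(sb[b], labels)
            deltas.append(da - db)
        deltas = np.asarray(deltas)
        boot_p = 2 * min((deltas <= 0).mean(), (deltas >= 0).mean())
        assert res.p == pytest.approx(boot_p, abs=0.05)


class TestLOOCVThresholdROC:
    def test_perfect_separation_survives_loocv(self):
        scores = np.r_[np.arange(10.0), np.arange(20.0, 30.0)]
        labels = np.array([0] * 10 + [1] * 10)
        assert loocv_threshold_roc(scores, labels).auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(123)
        scores = rng.normal(0, 1, 50)
        labels = np.array([0] * 25 + [1] * 25)
        res = loocv_threshold_roc(scores, labels)
        assert 0.3 <= res.auc <= 0.7

    def test_no_systematic_inflation_over_plain_auc(self, rng):
        # threshold-learning LOOCV can overshoot the plain AUC on single
        # weak-signal fixtures (the learned cutoff couples to the held-out
        # subject's class via the training class counts), but it must not
        # inflate on average, and in the strong-signal regime the two
        # estimates must agree closely
        diffs_weak, diffs_strong = [], []
        for _ in range(100):
            n = int(rng.integers(40, 69))
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.sum() < 3 or (1 - labels).sum() < 3:
                continue
            d = rng.uniform(0, 2.5)
            scores = rng.normal(0, 1, n) + d * labels
            diff = loocv_threshold_roc(scores, labels).auc - roc_analysis(scores, labels).auc
            (diffs_strong if d >= 1.5 else diffs_weak).append(diff)
        assert np.mean(diffs_weak + diffs_strong) <= 0.01
        assert max(diffs_strong) <= 0.05
        assert max(diffs_weak) <= 0.15

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            loocv_threshold_roc(np.arange(8.0), np.array([0, 1] * 4))


class TestHanleyMcNeil:
    def test_published_design_near_twenty_per_group(self):
        assert hanley_mcneil_n(0.75, 0.5, 0.10, 0.10) in range(18, 23)

    def test_huge_effect_needs_tiny_sample(self):
        assert hanley_mcneil_n(0.99, 0.5, 0.05, 0.05) <= 6

    def test_nonincreasing_in_alternative_auc(self):
        ns = [hanley_mcneil_n(a, 0.5, 0.10, 0.10) for a in (0.65, 0.75, 0.85, 0.95)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_n(0.5, 0.5)
        with pytest.raises(ValueError):
            hanley_mcneil_n(0.75, 0.5, type1=0.7)
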
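import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from mtqsar.classifiers import fit_lda
from mtqsar.validation import (
    ConfusionCounts,
    confusion,
    cross_validated_scores,
    metrics,
    roc_auc,
    y_randomization,
)


def allpairs_auc(scores, y):
    """Independent oracle: AUC as the all-pairs win fraction, ties half."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_all_correct_has_no_errors(self):
        y = [1, 0, 1, 1, 0]
        c = confusion(y, y)
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (3, 2)

    def test_inverting_predictions_swaps_count_pairs(self):
        y_true = [1, 1, 0, 0, 1, 0]
        y_pred = [1, 0, 0, 1, 1, 0]
        c = confusion(y_true, y_pred)
        inv = confusion(y_true, [1 - p for p in y_pred])
        assert (inv.tp, inv.fn) == (c.fn, c.tp)
        assert (inv.tn, inv.fp) == (c.fp, c.tn)

    def test_six_item_hand_tally(self):
        y_true = ["active", "active", "inactive", "active", "inactive", "inactive"]
        y_pred = ["active", "inactive", "inactive", "active", "active", "inactive"]
        c = confusion(y_true, y_pred)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 2, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_perfect_classifier(self):
        r = metrics(ConfusionCounts(tp=10, fp=0, tn=5, fn=0))
        assert r.accuracy == 100.0
        assert r.mcc == pytest.approx(1.0)
        assert r.f_measure == pytest.approx(1.0)

    def test_undefined_metric_flagged_not_zeroed(self):
        r = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert "precision" in r.undefined
        assert math.isnan(r.precision)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fp=0, tn=0, fn=0)

    def test_internal_consistency_with_formulas(self):
        c = ConfusionCounts(tp=7, fp=3, tn=8, fn=2)
        r = metrics(c)
        assert r.sensitivity == pytest.approx(100 * 7 / 9, abs=1e-12)
        assert r.specificity == pytest.approx(100 * 8 / 11, abs=1e-12)
        assert r.precision == pytest.approx(70.0, abs=1e-12)
        assert r.accuracy == pytest.approx(75.0, abs=1e-12)

    @given(
        tp=st.integers(0, 500),
        fp=st.integers(0, 500),
        tn=st.integers(0, 500),
        fn=st.integers(0, 500),
    )
    def test_ranges_and_class_swap_symmetry(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        r = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        for value in (r.accuracy, r.sensitivity, r.specificity, r.precision):
            assert math.isnan(value) or 0.0 <= value <= 100.0
        swapped = metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        if not math.isnan(r.sensitivity):
            assert swapped.specificity == pytest.approx(r.sensitivity)
        if not math.isnan(r.mcc):
            assert -1.0 <= r.mcc <= 1.0
            assert abs(swapped.mcc) == pytest.approx(abs(r.mcc))


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert curve["tpr"].iloc[-1] == 1.0 and curve["fpr"].iloc[-1] == 1.0

    def test_constant_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == pytest.approx(0.5)

    def test_eight_point_set_matches_allpairs_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.6, 0.2, 0.7]
        y = [0, 0, 1, 1, 0, 1, 0, 1]
        auc, _ = roc_auc(scores, y)
        assert auc == pytest.approx(allpairs_auc(scores, y), abs=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(10, 50))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            auc, _ = roc_auc(s, y)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @given(st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=20)
        if y.min() == y.max():
            return
        s = rng.normal(size=20)
        auc1, _ = roc_auc(s, y)
        auc2, _ = roc_auc(np.exp(3 * s), y)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


def _lda_fit(X, y):
    return fit_lda(X, y)


def _lda_score(model, X):
    return model.scores(X)


class TestCrossValidation:
    def test_leave_one_out_scores_every_sample_once(self, two_class_data):
        X, y = two_class_data(n=12, p=2, seed=12)
        k = min(np.bincount(y))
        scores = cross_validated_scores(X, y, _lda_fit, _lda_score, k=k, seed=0)
        assert scores.shape == (12,)
        assert np.isfinite(scores).all()

    def test_infeasible_fold_count_rejected(self, two_class_data):
        X, y = two_class_data(n=10, p=2, seed=13)
        with pytest.raises(ValueError, match="infeasible"):
            cross_validated_scores(X, y, _lda_fit, _lda_score, k=50, seed=0)

    def test_out_of_fold_auc_rarely_beats_resubstitution(self, two_class_data):
        wins = 0
        trials = 10
        for seed in range(trials):
            X, y = two_class_data(n=120, p=6, n_informative=2, effect=1.0, seed=seed)
            model = fit_lda(X, y)
            auc_in, _ = roc_auc(model.scores(X), y)
            oof = cross_validated_scores(X, y, _lda_fit, _lda_score, k=5, seed=seed)
            auc_oof, _ = roc_auc(oof, y)
            wins += auc_oof <= auc_in
        assert wins >= 0.8 * trials


class TestYRandomization:
    def test_original_lambda_matches_direct_fit(self, two_class_data):
        X, y = two_class_data(n=100, p=3, seed=14)
        res = y_randomization(X, y, n_perm=3, seed=0)
        assert res.lambda_original == pytest.approx(fit_lda(X, y).wilks_lambda_train)
        assert len(res.lambda_randomized) == 3

    def test_pure_noise_data_shows_no_gap(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(400, 2))
        y = rng.integers(0, 2, size=400)
        res = y_randomization(X, y, n_perm=20, seed=1)
        assert abs(res.mean_lambda_randomized - res.lambda_original) < 0.05

    def test_informative_data_shows_large_gap(self, two_class_data):
        X, y = two_class_data(n=400, p=5, n_informative=3, effect=1.5, seed=16)
        res = y_randomization(X, y, n_perm=20, seed=2)
        assert res.mean_lambda_randomized > res.lambda_original + 0.2

    def test_invalid_permutation_count_rejected(self, two_class_data):
        X, y = two_class_data(n=50, p=2)
        with pytest.raises(ValueError):
            y_randomization(X, y, n_perm=0, seed=0)
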
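"""PA-1 updates, training, C selection and threshold correction."""

import numpy as np
import pytest

import hybridmp as h
from hybridmp.classification import _augment, _scores


def _separable_data(rng, n=60, d=4, margin=1.0):
    y = np.where(rng.random(n) < 0.5, 1, -1)
    x = rng.standard_normal((n, d))
    x[:, 0] = y * (margin + rng.random(n))
    return x, y


class TestUpdate:
    def test_zero_loss_leaves_model_unchanged(self):
        w = np.array([2.0, 0.0])
        out = h.pa1_update(w, np.array([1.0, 0.0]), 1, C=1.0)
        np.testing.assert_array_equal(out, w)  # margin = 2 >= 1

    def test_hand_applied_first_update(self):
        # w=0, x=(1,0), y=+1, C=1: loss 1, tau = min(1, 1/1) = 1 -> w=(1,0)
        w = h.pa1_update(np.zeros(2), np.array([1.0, 0.0]), 1, C=1.0)
        np.testing.assert_array_equal(w, [1.0, 0.0])
        assert w @ np.array([1.0, 0.0]) == 1.0  # margin now exactly 1

    def test_step_never_exceeds_C(self, rng):
        C = 0.05
        w = np.zeros(3)
        for _ in range(200):
            x = rng.standard_normal(3)
            y = 1 if rng.random() < 0.5 else -1
            w_new = h.pa1_update(w, x, y, C)
            tau = np.linalg.norm(w_new - w) / np.linalg.norm(x)
            assert tau <= C + 1e-12
            w = w_new

    def test_zero_vector_with_loss_warns_and_skips(self):
        with pytest.warns(UserWarning):
            w = h.pa1_update(np.zeros(2), np.zeros(2), 1, 1.0)
        np.testing.assert_array_equal(w, np.zeros(2))

    def test_large_C_reduces_to_pure_pa(self, rng):
        # with C -> inf, tau = loss / ||x||^2 exactly
        x = rng.standard_normal(5)
        w0 = rng.standard_normal(5) * 0.1
        y = -1
        loss = max(0.0, 1 - y * (w0 @ x))
        expected = w0 + (loss / (x @ x)) * y * x
        np.testing.assert_allclose(h.pa1_update(w0, x, y, C=1e12), expected)


class TestTraining:
    def test_separable_data_reaches_perfect_training_accuracy(self, rng):
        x, y = _separable_data(rng)
        model = h.train_pa1(x, y, C=1.0, epochs=5, seed=0)
        preds, _ = h.classify(model, x)
        np.testing.assert_array_equal(np.where(preds == 1, 1, -1), y)

    def test_deterministic_given_seed(self, rng):
        x, y = _separable_data(rng)
        m1 = h.train_pa1(x, y, 0.1, seed=3)
        m2 = h.train_pa1(x, y, 0.1, seed=3)
        np.testing.assert_array_equal(m1.w, m2.w)

    def test_hinge_loss_decreases_over_epochs(self, rng):
        x, y = _separable_data(rng)
        xa = _augment(x)

        def total_loss(w):
            return np.maximum(0.0, 1.0 - y * (xa @ w)).sum()

        first = h.train_pa1(x, y, 1.0, epochs=1, seed=0)
        later = h.train_pa1(x, y, 1.0, epochs=5, seed=0)
        assert total_loss(later.w) < total_loss(np.zeros(xa.shape[1]))
        assert total_loss(later.w) <= total_loss(first.w) + 1e-12

    def test_one_class_data_raises(self, rng):
        x = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            h.train_pa1(x, np.ones(10), 1.0)

    def test_matches_sklearn_passive_aggressive_single_epoch(self, rng):
        # independent implementation check: sklearn PA-I, hinge loss, no
        # shuffling, one pass, no intercept, on pre-augmented features
        from sklearn.linear_model import PassiveAggressiveClassifier

        x, y = _separable_data(rng, n=40)
        xa = _augment(x)
        ref = PassiveAggressiveClassifier(
            C=0.5, loss="hinge", fit_intercept=False, max_iter=1,
            shuffle=False, tol=None,
        ).fit(xa, y)
        w = np.zeros(xa.shape[1])
        for i in range(len(y)):
            w = h.pa1_update(w, xa[i], int(y[i]), 0.5)
        np.testing.assert_allclose(w, ref.coef_.ravel(), rtol=1e-10)


class TestModelSelection:
    def test_grid_of_size_one(self, rng):
        x, y = _separable_data(rng)
        c, table = h.select_C_nested_cv(x, y, grid=(0.01,), seed=0)
        assert c == 0.01 and set(table) == {0.01}

    def test_folds_are_stratified(self, rng):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 9 + [-1] * 18)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        x = rng.standard_normal((27, 2))
        for _, va in skf.split(x, y):
            frac = np.mean(y[va] == 1)
            assert abs(frac - 1 / 3) <= 1 / len(va)

    def test_selected_C_maximizes_reported_table(self, rng):
        x, y = _separable_data(rng, n=45)
        c, table = h.select_C_nested_cv(x, y, grid=(1.0, 1e-3, 1e-6), seed=1)
        best = max(table.values())
        assert table[c] == best
        assert c == min(k for k, v in table.items() if v == best)  # tie-break

    def test_too_small_class_raises(self, rng):
        x = rng.standard_normal((5, 2))
        y = np.array([1, 1, -1, -1, -1])
        with pytest.raises(ValueError):
            h.select_C_nested_cv(x, y, k=3)


class TestThresholdCorrection:
    def test_balanced_symmetric_scores_give_zero_offset(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        labels = np.array([-1, -1, 1, 1])
        assert h.correct_threshold(scores, labels) == 0.0

    def test_hand_enumerated_midpoints(self):
        scores = np.array([-1.0, 2.0, 3.0, 4.0])
        labels = np.array([-1, 1, 1, 1])
        off = h.correct_threshold(scores, labels)
        assert -1.0 < off < 2.0  # separates perfectly
        pred = np.where(scores - off > 0, 1, -1)
        np.testing.assert_array_equal(pred, labels)

    def test_corrected_ba_at_least_uncorrected(self, rng):
        # imbalanced (1:20) data with a biased score distribution
        scores = np.concatenate([rng.normal(1.0, 0.3, 5),
                                 rng.normal(-0.2, 0.5, 100)])
        labels = np.concatenate([np.ones(5), -np.ones(100)]).astype(int)
        off = h.correct_threshold(scores, labels)

        def ba(o):
            pred = np.where(scores - o > 0, 1, -1)
            tpr = np.mean(pred[labels == 1] == 1)
            tnr = np.mean(pred[labels == -1] == -1)
            return (tpr + tnr) / 2

        assert ba(off) >= ba(0.0)

    def test_degenerate_scores_return_zero(self):
        assert h.correct_threshold(np.ones(4), np.array([1, 1, -1, -1])) == 0.0


class TestClassify:
    def test_zero_score_predicts_negative(self):
        model = h.PA1Model(w=np.zeros(3), C=1.0)
        pred, score = h.classify(model, np.zeros(2))
        assert (pred, score) == (0, 0.0)  # strict inequality at boundary

    def test_sign_flip_flips_predictions(self, rng):
        x = rng.standard_normal((20, 3))
        m = h.PA1Model(w=rng.standard_normal(4), C=1.0)
        m_neg = h.PA1Model(w=-m.w, C=1.0)
        p1, s1 = h.classify(m, x)
        p2, s2 = h.classify(m_neg, x)
        nz = s1 != 0
        assert np.all(p1[nz] != p2[nz])

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal((50, 4))
        model = h.PA1Model(w=rng.standard_normal(5), C=1.0, decision_offset=0.3)
        preds, scores = h.classify(model, x)
        for i in range(50):
            s = model.w[:4] @ x[i] + model.w[4]
            assert np.isclose(scores[i], s)
            assert preds[i] == (1 if s - 0.3 > 0 else 0)

    def test_dimension_mismatch_raises(self):
        model = h.PA1Model(w=np.zeros(4), C=1.0)
        with pytest.raises(ValueError):
            h.classify(model, np.zeros((3, 7)))


def test_imbalance_threshold_correction_on_separable_stream(rng):
    """~1:20 imbalance: after correction training BA reaches 1.0 on
    linearly separable data even if the raw boundary is biased."""
    n_pos, n_neg = 6, 120
    x = np.vstack([
        rng.standard_normal((n_pos, 3)) * 0.1 + [3, 0, 0],
        rng.standard_normal((n_neg, 3)) * 0.1,
    ])
    y = np.concatenate([np.ones(n_pos), -np.ones(n_neg)]).astype(int)
    model = h.train_pa1(x, y, C=0.01, epochs=2, seed=0)
    model.decision_offset = h.correct_threshold(_scores(model, x), y)
    preds, _ = h.classify(model, x)
    np.testing.assert_array_equal(np.where(preds == 1, 1, -1), y)
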
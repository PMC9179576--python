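"""Loss functions against an independent scalar double-loop oracle, plus limit identities."""

import math

import numpy as np
import pytest

from rccgrade.losses import (
    BatchPrediction,
    LossConfig,
    ce_class0_loss,
    ce_loss,
    class_weights_from_counts,
    mixed_loss,
    total_weighted_grad_logits,
    total_weighted_loss,
    weighted_ce_loss,
)

EPS = 1e-12


# ---- independent oracle: scalar double loops, no vectorization shared with the package ----

def oracle_total(probs, labels, alpha, lam0, lam1):
    n = len(labels)
    first = 0.0
    second = 0.0
    for i in range(n):
        for j in (0, 1):
            l_ij = 1.0 if labels[i] == j else 0.0
            lam = lam0 if j == 0 else lam1
            first += lam * l_ij * math.log(max(probs[i][j], EPS))
        l_i0 = 1.0 if labels[i] == 0 else 0.0
        second += lam0 * l_i0 * math.log(max(probs[i][0], EPS))
    return -alpha * first / n - (1.0 - alpha) * second / n


def oracle_ce(probs, labels):
    return oracle_total(probs, labels, 1.0, 1.0, 1.0)


def oracle_ce0(probs, labels):
    # the alpha -> 0, lambda = 1 limit isolates the low-grade term
    return oracle_total(probs, labels, 0.0, 1.0, 1.0)


def random_batch(rng, n=None):
    n = n or int(rng.integers(1, 17))
    p1 = rng.uniform(0.01, 0.99, size=n)
    probs = np.stack([1 - p1, p1], axis=1)
    labels = rng.integers(0, 2, size=n)
    if labels.sum() == 0 and n > 1:
        labels[0] = 1
    return BatchPrediction(probs, labels)


class TestHandValues:
    def test_ce_perfect_prediction_zero(self):
        b = BatchPrediction(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))
        assert ce_loss(b) == pytest.approx(0.0, abs=1e-9)

    def test_ce_half_half(self):
        b = BatchPrediction(np.array([[0.5, 0.5]]), np.array([1]))
        assert ce_loss(b) == pytest.approx(math.log(2), abs=1e-10)

    def test_ce0_divides_by_full_n(self):
        """One low-grade sample at p0 = 0.5 in a batch of two: (1/2) ln 2."""
        b = BatchPrediction(np.array([[0.5, 0.5], [0.1, 0.9]]), np.array([0, 1]))
        assert ce_class0_loss(b) == pytest.approx(0.5 * math.log(2), abs=1e-10)

    def test_ce0_no_low_samples_zero(self):
        b = BatchPrediction(np.array([[0.3, 0.7], [0.2, 0.8]]), np.array([1, 1]))
        assert ce_class0_loss(b) == 0.0

    def test_ce0_equals_ce_on_all_low_batch(self):
        b = BatchPrediction(np.array([[0.7, 0.3], [0.6, 0.4]]), np.array([0, 0]))
        assert ce_class0_loss(b) == pytest.approx(ce_loss(b), abs=1e-12)


class TestLimitIdentities:
    def test_mixed_alpha1_is_ce(self):
        b = random_batch(np.random.default_rng(0), 8)
        assert mixed_loss(b, LossConfig(alpha=1.0)) == pytest.approx(ce_loss(b), abs=1e-12)

    def test_mixed_alpha0_is_ce0(self):
        b = random_batch(np.random.default_rng(1), 8)
        assert mixed_loss(b, LossConfig(alpha=0.0)) == pytest.approx(ce_class0_loss(b), abs=1e-12)

    def test_weighted_unit_lambda_is_ce(self):
        b = random_batch(np.random.default_rng(2), 8)
        assert weighted_ce_loss(b, LossConfig(alpha=0.4)) == pytest.approx(ce_loss(b), abs=1e-12)

    def test_weighted_homogeneous_in_lambda(self):
        b = random_batch(np.random.default_rng(3), 8)
        one = weighted_ce_loss(b, LossConfig(lambda0=0.7, lambda1=1.3))
        two = weighted_ce_loss(b, LossConfig(lambda0=1.4, lambda1=2.6))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_total_alpha1_is_weighted(self):
        b = random_batch(np.random.default_rng(4), 8)
        cfg = LossConfig(alpha=1.0, lambda0=0.8, lambda1=1.2)
        assert total_weighted_loss(b, cfg) == pytest.approx(weighted_ce_loss(b, cfg), abs=1e-12)

    def test_total_unit_lambda_is_mixed(self):
        b = random_batch(np.random.default_rng(5), 8)
        cfg = LossConfig(alpha=0.4)
        assert total_weighted_loss(b, cfg) == pytest.approx(mixed_loss(b, cfg), abs=1e-12)


class TestOracleEquivalence:
    def test_all_losses_match_oracle_on_1000_batches(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            b = random_batch(rng)
            alpha = float(rng.uniform(0, 1))
            lam0, lam1 = float(rng.uniform(0.1, 3)), float(rng.uniform(0.1, 3))
            cfg = LossConfig(alpha=alpha, lambda0=lam0, lambda1=lam1)
            probs, labels = b.probs.tolist(), b.labels.tolist()
            assert ce_loss(b) == pytest.approx(oracle_ce(probs, labels), abs=1e-10)
            assert ce_class0_loss(b) == pytest.approx(oracle_ce0(probs, labels), abs=1e-10)
            assert mixed_loss(b, cfg) == pytest.approx(
                alpha * oracle_ce(probs, labels) + (1 - alpha) * oracle_ce0(probs, labels), abs=1e-10)
            assert total_weighted_loss(b, cfg) == pytest.approx(
                oracle_total(probs, labels, alpha, lam0, lam1), abs=1e-10)

    def test_spec_worked_mixed_example(self):
        probs = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])
        labels = np.array([0, 1, 1])
        b = BatchPrediction(probs, labels)
        cfg = LossConfig(alpha=0.4)
        assert mixed_loss(b, cfg) == pytest.approx(
            0.4 * oracle_ce(probs.tolist(), labels.tolist())
            + 0.6 * oracle_ce0(probs.tolist(), labels.tolist()), abs=1e-10)


class TestProperties:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        b = random_batch(rng, 12)
        perm = rng.permutation(12)
        bp = BatchPrediction(b.probs[perm], b.labels[perm])
        cfg = LossConfig(alpha=0.3, lambda0=0.5, lambda1=1.5)
        for fn in (ce_loss, lambda x: mixed_loss(x, cfg), lambda x: total_weighted_loss(x, cfg)):
            assert fn(b) == pytest.approx(fn(bp), abs=1e-12)

    def test_losses_nonnegative_and_zero_iff_confident(self):
        rng = np.random.default_rng(8)
        cfg = LossConfig(alpha=0.4, lambda0=0.8, lambda1=1.2)
        for _ in range(50):
            b = random_batch(rng)
            assert total_weighted_loss(b, cfg) >= 0
        sure = BatchPrediction(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))
        assert mixed_loss(sure, cfg) == pytest.approx(0.0, abs=1e-9)

    def test_noise_term_never_penalizes_high_labeled_p0(self):
        """Finite differences: for a high-labeled sample, the mixed loss does not
        depend on p_i0 at all -- only the low-grade term of low-labeled samples does."""
        cfg = LossConfig(alpha=0.4)
        probs = np.array([[0.3, 0.7], [0.6, 0.4]])
        labels = np.array([1, 0])

        def f(p0_high):
            p = probs.copy()
            p[0, 0] = p0_high
            p[0, 1] = 0.7  # hold the counted coordinate fixed; rows re-checked loosely
            b = BatchPrediction.__new__(BatchPrediction)
            b.probs, b.labels = p, labels
            return mixed_loss(b, cfg)

        assert f(0.3) == pytest.approx(f(0.300001), abs=1e-12)

    def test_grad_matches_finite_difference_on_logits(self):
        rng = np.random.default_rng(11)
        logits = rng.standard_normal((5, 2))
        labels = np.array([0, 1, 1, 0, 1])
        cfg = LossConfig(alpha=0.4, lambda0=0.8, lambda1=1.2)

        def loss_of(z):
            e = np.exp(z - z.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            return total_weighted_loss(BatchPrediction(p, labels), cfg)

        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        g = total_weighted_grad_logits(probs, labels, cfg)
        eps = 1e-6
        for i in range(5):
            for j in range(2):
                zp = logits.copy(); zp[i, j] += eps
                zm = logits.copy(); zm[i, j] -= eps
                num = (loss_of(zp) - loss_of(zm)) / (2 * eps)
                assert g[i, j] == pytest.approx(num, abs=1e-6)


class TestClassWeights:
    def test_balanced_counts_unit_weights(self):
        assert class_weights_from_counts(100, 100) == (1.0, 1.0)

    def test_development_cohort_counts(self):
        """354 low / 238 high -> inverse-frequency weights 592/708 and 592/476."""
        lam0, lam1 = class_weights_from_counts(354, 238)
        assert lam0 == pytest.approx(592 / (2 * 354), abs=1e-12)
        assert lam1 == pytest.approx(592 / (2 * 238), abs=1e-12)
        assert lam0 == pytest.approx(0.836, abs=5e-4)
        assert lam1 == pytest.approx(1.244, abs=5e-4)

    def test_noise_adjusted_alpha1_balances_exactly(self):
        lam0, lam1 = class_weights_from_counts(300, 200, "noise_adjusted", alpha=1.0)
        assert lam0 * 300 == pytest.approx(lam1 * 200, rel=1e-12)
        assert lam0 + lam1 == pytest.approx(2.0, rel=1e-12)

    def test_noise_adjusted_expected_balance(self):
        lam0, lam1 = class_weights_from_counts(354, 238, "noise_adjusted", alpha=0.4)
        assert lam0 * 354 == pytest.approx(0.4 * lam1 * 238, rel=1e-12)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            class_weights_from_counts(0, 10)


class TestVariantFlags:
    def test_complement_mixing_swaps_coefficients(self):
        b = random_batch(np.random.default_rng(21), 8)
        printed = mixed_loss(b, LossConfig(alpha=0.3, mixing="as_printed"))
        swapped = mixed_loss(b, LossConfig(alpha=0.7, mixing="complement"))
        assert printed == pytest.approx(swapped, abs=1e-12)

    def test_flip_to_low_covers_all_samples(self):
        b = BatchPrediction(np.array([[0.5, 0.5], [0.25, 0.75]]), np.array([1, 1]))
        # class0 term vanishes on an all-high batch; flip_to_low does not
        assert ce_class0_loss(b, noise_term="class0") == 0.0
        expect = -(math.log(0.5) + math.log(0.25)) / 2
        assert ce_class0_loss(b, noise_term="flip_to_low") == pytest.approx(expect, abs=1e-12)

    def test_flip_to_low_gradient_consistent(self):
        from rccgrade.losses import total_weighted_grad_logits

        cfg = LossConfig(alpha=0.4, noise_term="flip_to_low")
        rng = np.random.default_rng(2)
        logits = rng.standard_normal((4, 2))
        labels = np.array([0, 1, 1, 0])
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        g = total_weighted_grad_logits(probs, labels, cfg)

        def loss_of(z):
            ez = np.exp(z - z.max(axis=1, keepdims=True))
            p = ez / ez.sum(axis=1, keepdims=True)
            return total_weighted_loss(BatchPrediction(p, labels), cfg)

        eps = 1e-6
        for i in range(4):
            for j in range(2):
                zp = logits.copy(); zp[i, j] += eps
                zm = logits.copy(); zm[i, j] -= eps
                assert g[i, j] == pytest.approx((loss_of(zp) - loss_of(zm)) / (2 * eps), abs=1e-6)
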
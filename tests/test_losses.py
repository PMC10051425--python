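"""Loss definitions against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tripledare import autodiff as ad
from tripledare import (KernelBank, KernelBankConfig, classification_loss,
                        compatibility, coral_loss, domain_alignment_loss,
                        mk_mmd_sq, multi_kernel, resolve_kernel_bank,
                        total_cost, triplet_loss)
from tripledare.autodiff import Tensor
from tripledare.losses import classification_loss_logits, mmd_sq_from_joint

from _naive import naive_mmd_sq

BANK = KernelBank(betas=[0.5, 0.3, 0.2], bandwidths=[0.5, 1.0, 2.0])
UNIT_BANK = KernelBank(betas=[1.0], bandwidths=[1.0])


class TestMultiKernel:
    def test_identical_inputs_give_total_weight(self, rng):
        x = rng.standard_normal(5)
        assert multi_kernel(x, x, BANK) == pytest.approx(1.0)

    def test_single_gaussian_closed_form(self):
        x = np.array([1.0, 0.0])
        y = np.array([0.0, 1.0])  # squared distance 2
        assert multi_kernel(x, y, UNIT_BANK) == pytest.approx(np.exp(-1.0))

    def test_symmetry(self, rng):
        for _ in range(10):
            x, y = rng.standard_normal((2, 4))
            assert multi_kernel(x, y, BANK) == pytest.approx(multi_kernel(y, x, BANK))

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multi_kernel(np.zeros(3), np.zeros(4), BANK)


class TestMkMmd:
    def test_identical_multisets_give_zero(self, rng):
        X = rng.standard_normal((10, 4))
        assert abs(mk_mmd_sq(X, X.copy(), BANK)) < 1e-10

    def test_singleton_expansion(self, rng):
        a, b = rng.standard_normal((2, 3))
        got = mk_mmd_sq(a[None], b[None], BANK)
        assert got == pytest.approx(2.0 - 2.0 * multi_kernel(a, b, BANK))

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(30):
            ns, nt = rng.integers(1, 17, size=2)
            d = rng.integers(1, 9)
            Xs = rng.standard_normal((ns, d))
            Xt = rng.standard_normal((nt, d)) + rng.normal(0, 1)
            got = mk_mmd_sq(Xs, Xt, BANK)
            want = naive_mmd_sq(Xs, Xt, BANK.betas, BANK.bandwidths)
            assert got == pytest.approx(want, abs=1e-8)

    def test_nonnegative_and_order_invariant(self, rng):
        Xs = rng.standard_normal((12, 5))
        Xt = rng.standard_normal((9, 5)) + 0.5
        v = mk_mmd_sq(Xs, Xt, BANK)
        assert v >= 0
        perm_s = rng.permutation(12)
        perm_t = rng.permutation(9)
        assert mk_mmd_sq(Xs[perm_s], Xt[perm_t], BANK) == pytest.approx(v, abs=1e-12)

    def test_detects_mean_separation_monotonically(self):
        """MMD between same-distribution samples stays near zero and grows
        with mean separation (Monte-Carlo over 20 seeds)."""
        shifts = (0.0, 0.5, 1.0, 2.0)
        means = []
        for shift in shifts:
            vals = []
            for seed in range(20):
                r = np.random.default_rng(seed)
                Xs = r.standard_normal((40, 3))
                Xt = r.standard_normal((40, 3)) + shift
                bank = resolve_kernel_bank(KernelBankConfig(),
                                           np.concatenate([Xs, Xt]))
                vals.append(mk_mmd_sq(Xs, Xt, bank))
            means.append(np.mean(vals))
        assert all(means[i] < means[i + 1] for i in range(3))
        assert means[0] < 0.05

    def test_tensor_path_matches_numpy_path(self, rng):
        Xs = rng.standard_normal((8, 4))
        Xt = rng.standard_normal((6, 4)) + 1.0
        want = mk_mmd_sq(Xs, Xt, BANK)
        got = mk_mmd_sq(Tensor(Xs), Tensor(Xt), BANK)
        assert float(got.data) == pytest.approx(want, abs=1e-10)

    def test_joint_distance_form_matches(self, rng):
        Xs = rng.standard_normal((8, 4))
        Xt = rng.standard_normal((8, 4)) + 0.5
        joint = Tensor(np.concatenate([Xs, Xt]))
        d2 = ad.pairwise_sq_dists(joint, joint)
        got = mmd_sq_from_joint(d2, 8, 8, BANK)
        assert float(got.data) == pytest.approx(mk_mmd_sq(Xs, Xt, BANK), abs=1e-10)

    def test_empty_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            mk_mmd_sq(np.zeros((0, 3)), np.zeros((2, 3)), BANK)


class TestDomainAlignment:
    def test_identical_layers_give_zero(self, rng):
        layers = [(rng.standard_normal((6, 4)),) * 2 for _ in range(3)]
        assert abs(domain_alignment_loss(layers, BANK)) < 1e-10

    def test_single_layer_reduces_to_mmd(self, rng):
        Xs, Xt = rng.standard_normal((2, 7, 3))
        assert domain_alignment_loss([(Xs, Xt)], BANK) == pytest.approx(
            mk_mmd_sq(Xs, Xt, BANK))

    def test_three_layers_additive(self, rng):
        pairs = [(rng.standard_normal((5, 3)), rng.standard_normal((6, 3)))
                 for _ in range(3)]
        want = sum(mk_mmd_sq(a, b, BANK) for a, b in pairs)
        assert domain_alignment_loss(pairs, BANK) == pytest.approx(want, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            domain_alignment_loss([], BANK)


class TestClassificationLoss:
    def test_perfect_predictions_vanish(self):
        y = np.array([[1, 0, 1], [0, 1, 0]])
        probs = np.clip(y.astype(float), 1e-7, 1 - 1e-7)
        assert classification_loss(probs, y) < 1e-5

    def test_uniform_half_gives_ln2(self, rng):
        y = (rng.random((10, 4)) < 0.5).astype(int)
        probs = np.full((10, 4), 0.5)
        assert classification_loss(probs, y) == pytest.approx(np.log(2.0))

    def test_matches_elementwise_loop(self, rng):
        y = (rng.random((8, 5)) < 0.4).astype(int)
        probs = rng.uniform(0.05, 0.95, (8, 5))
        want = -np.mean([y[i, l] * np.log(probs[i, l])
                         + (1 - y[i, l]) * np.log(1 - probs[i, l])
                         for i in range(8) for l in range(5)])
        assert classification_loss(probs, y) == pytest.approx(want, abs=1e-12)

    def test_positive_weights_applied(self, rng):
        y = np.array([[1, 0]])
        probs = np.array([[0.3, 0.3]])
        w = np.array([4.0, 4.0])
        want = (-4.0 * np.log(0.3) - np.log(0.7)) / 2
        assert classification_loss(probs, y, w) == pytest.approx(want, abs=1e-12)

    def test_logits_path_matches_probability_path(self, rng):
        y = (rng.random((6, 4)) < 0.5).astype(int)
        z = rng.normal(0, 2, (6, 4))
        w = rng.uniform(0.5, 5, 4)
        want = classification_loss(1 / (1 + np.exp(-z)), y, w)
        got = classification_loss_logits(Tensor(z), y, w)
        assert float(got.data) == pytest.approx(want, abs=1e-6)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.full((1, 2), 0.5), np.array([[0.5, 1.0]]))


class TestTripletLoss:
    def test_collapsed_embeddings_give_alpha(self, rng):
        X = np.ones((6, 3))
        triplets = [(0, 1, 2), (3, 4, 5), (1, 2, 3)]
        assert triplet_loss(X, triplets, alpha=0.25) == pytest.approx(0.25)

    def test_hinge_boundary_contributes_zero(self):
        alpha = 0.1
        X = np.array([[0.0], [0.0], [alpha]])  # d(a,p)=0, d(a,n)=alpha
        assert triplet_loss(X, [(0, 1, 2)], alpha) == pytest.approx(0.0)

    def test_matches_per_triplet_loop(self, rng):
        X = rng.standard_normal((10, 4))
        triplets = [tuple(rng.choice(10, 3, replace=False)) for _ in range(25)]
        want = np.mean([max(np.linalg.norm(X[a] - X[p])
                            - np.linalg.norm(X[a] - X[n]) + 0.2, 0.0)
                        for a, p, n in triplets])
        assert triplet_loss(X, triplets, 0.2) == pytest.approx(want, abs=1e-9)

    def test_empty_triplets_give_zero(self, rng):
        assert triplet_loss(rng.standard_normal((4, 2)), [], 0.1) == 0.0


class TestCompatibility:
    def test_shared_positive_count(self):
        assert compatibility(np.array([1, 0, 1]), np.array([1, 1, 0])) == 1

    def test_self_compatibility_is_support_size(self, rng):
        y = (rng.random(9) < 0.5).astype(int)
        assert compatibility(y, y) == int(y.sum())

    def test_disjoint_supports(self):
        assert compatibility(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            compatibility(np.array([2, 0]), np.array([1, 0]))


class TestTotalCost:
    def test_source_only_limit(self):
        assert total_cost(1.7, 9.9, 3.3, (1.0, 0.0, 0.0)) == pytest.approx(1.7)

    def test_all_zero_weights(self):
        assert total_cost(1.0, 2.0, 3.0, (0.0, 0.0, 0.0)) == 0.0

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5),
           st.floats(0, 3), st.floats(0, 3), st.floats(0, 3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity(self, a, b, c, l1, l2, l3):
        direct = total_cost(a, b, c, (l1, l2, l3))
        assert direct == pytest.approx(l1 * a + l2 * b + l3 * c, rel=1e-12, abs=1e-12)


class TestCoral:
    def test_identical_batches_give_zero(self, rng):
        X = rng.standard_normal((8, 3))
        assert coral_loss(X, X.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_variance_case(self, rng):
        a = rng.standard_normal(20)[:, None] * 2.0
        b = rng.standard_normal(25)[:, None] * 0.5
        v1 = a.var(ddof=1)
        v2 = b.var(ddof=1)
        assert coral_loss(a, b) == pytest.approx((v1 - v2) ** 2 / 4.0, abs=1e-10)

    def test_matches_covariance_oracle(self, rng):
        Xs = rng.standard_normal((12, 5))
        Xt = rng.standard_normal((9, 5)) * 1.5
        Cs = np.cov(Xs, rowvar=False)
        Ct = np.cov(Xt, rowvar=False)
        want = ((Cs - Ct) ** 2).sum() / (4 * 25)
        assert coral_loss(Xs, Xt) == pytest.approx(want, abs=1e-8)

    def test_tensor_path_matches(self, rng):
        Xs = rng.standard_normal((7, 3))
        Xt = rng.standard_normal((6, 3)) + 1
        got = coral_loss(Tensor(Xs), Tensor(Xt))
        assert float(got.data) == pytest.approx(coral_loss(Xs, Xt), abs=1e-10)

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            coral_loss(rng.standard_normal((1, 3)), rng.standard_normal((5, 3)))


def test_median_heuristic_bank_is_valid(rng):
    X = rng.standard_normal((30, 4))
    bank = resolve_kernel_bank(KernelBankConfig(), X)
    assert bank.n_kernels == 5
    assert np.all(bank.bandwidths > 0)
    assert bank.betas.sum() == pytest.approx(1.0)
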
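"""Soft normalized-cut loss: oracle equivalence, bounds, gradient sanity."""

import numpy as np
import pytest
import scipy.sparse as sp

from gaseg.ncut import (AffinitySpec, average_pool, pixel_weights,
                        pooled_soft_ncut_loss, soft_ncut_loss,
                        soft_ncut_loss_grad)

SPEC = AffinitySpec(sigma_i=0.15, sigma_x=3.0, radius=3)


def brute_force_soft_ncut(image, probabilities, spec):
    """Independent O(N^2) double summation of the soft-N-cut definition."""
    h, w = image.shape
    n = h * w
    k = probabilities.shape[0]
    flat = image.ravel()
    pm = probabilities.reshape(k, n)
    coords = np.array([(i // w, i % w) for i in range(n)], dtype=float)
    total = float(k)
    for c in range(k):
        num = den = 0.0
        for u in range(n):
            for v in range(n):
                d2 = ((coords[u] - coords[v]) ** 2).sum()
                wgt = 0.0
                if d2 == 0 or np.sqrt(d2) < spec.radius:
                    di = flat[u] - flat[v]
                    wgt = (np.exp(-di * di / spec.sigma_i ** 2)
                           * np.exp(-d2 / spec.sigma_x ** 2))
                num += wgt * pm[c, u] * pm[c, v]
                den += wgt * pm[c, u]
        total -= num / (den + 1e-8)
    return total


def random_instance(rng, max_side=8, k_choices=(2, 3)):
    side = int(rng.integers(3, max_side + 1))
    k = int(rng.choice(k_choices))
    img = rng.random((side, side))
    p = rng.random((k, side, side))
    p /= p.sum(axis=0)
    return img, p


class TestPixelWeights:
    def test_diagonal_is_one_and_symmetric(self, rng):
        w = pixel_weights(rng.random((5, 5)), SPEC)
        assert np.allclose(w.diagonal(), 1.0)
        assert (abs(w - w.T)).max() < 1e-12

    def test_zero_beyond_radius(self, rng):
        img = rng.random((6, 6))
        w = pixel_weights(img, AffinitySpec(0.2, 2.0, 2)).toarray()
        # pixel (0,0) vs (0,2): distance 2 >= radius 2 -> no edge
        assert w[0, 2] == 0.0
        assert w[0, 1] > 0.0

    def test_constant_image_closed_form(self):
        spec = AffinitySpec(sigma_i=0.1, sigma_x=2.0, radius=2)
        w = pixel_weights(np.full((3, 3), 0.4), spec).toarray()
        # center pixel (index 4) vs right neighbour (index 5): d^2 = 1
        assert w[4, 5] == pytest.approx(np.exp(-1.0 / spec.sigma_x ** 2))
        # center vs corner (index 0): d^2 = 2, sqrt(2) < radius -> kept
        assert w[4, 0] == pytest.approx(np.exp(-2.0 / spec.sigma_x ** 2))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            AffinitySpec(sigma_i=-1.0)
        with pytest.raises(ValueError):
            AffinitySpec(sigma_x=0.0)


class TestSoftNcutLoss:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(8):
            img, p = random_instance(rng, max_side=6)
            w = pixel_weights(img, SPEC)
            fast = soft_ncut_loss(p, w)
            slow = brute_force_soft_ncut(img, p, SPEC)
            assert fast == pytest.approx(slow, abs=1e-6)

    def test_bounds_zero_to_k(self, rng):
        for _ in range(20):
            img, p = random_instance(rng)
            j = soft_ncut_loss(p, pixel_weights(img, SPEC))
            assert -1e-9 <= j <= p.shape[0] + 1e-9

    def test_single_class_identity_is_zero(self, rng):
        img = rng.random((5, 5))
        p = np.ones((1, 5, 5))
        assert soft_ncut_loss(p, pixel_weights(img, SPEC)) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_weight_half_half_case(self):
        """2x2 image, w=1 for all pairs, hard half/half split: J = 2 - 1 = 1."""
        w = sp.csr_matrix(np.ones((4, 4)))
        p = np.zeros((2, 2, 2))
        p[0, 0, :] = 1.0
        p[1, 1, :] = 1.0
        assert soft_ncut_loss(p, w) == pytest.approx(1.0, abs=1e-6)

    def test_separation_monotonicity(self):
        """Matching a two-block image beats the flipped-half assignment."""
        img = np.zeros((4, 4))
        img[:, 2:] = 1.0
        w = pixel_weights(img, AffinitySpec(0.1, 4.0, 3))
        good = np.zeros((2, 4, 4))
        good[0, :, :2] = 1.0
        good[1, :, 2:] = 1.0
        bad = np.zeros((2, 4, 4))
        bad[0, :2, :] = 1.0
        bad[1, 2:, :] = 1.0
        assert soft_ncut_loss(good, w) < soft_ncut_loss(bad, w)

    def test_gradient_matches_finite_differences(self, rng):
        img = rng.random((4, 4))
        k = 2
        p = rng.random((16, k))
        p /= p.sum(axis=1, keepdims=True)
        w = pixel_weights(img, SPEC)
        _, grad = soft_ncut_loss_grad(p, w)
        eps = 1e-6
        for idx in [(0, 0), (5, 1), (10, 0), (15, 1)]:
            pp = p.copy()
            pp[idx] += eps
            pm = p.copy()
            pm[idx] -= eps
            fd = (soft_ncut_loss(pp, w) - soft_ncut_loss(pm, w)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, abs=1e-4)

    def test_dead_class_guarded(self, rng):
        img = rng.random((4, 4))
        p = np.zeros((2, 4, 4))
        p[0] = 1.0  # class 1 has zero mass everywhere
        j = soft_ncut_loss(p, pixel_weights(img, SPEC))
        assert np.isfinite(j)


class TestPooledLoss:
    def test_pool_factor_one_is_identity(self, rng):
        img, p = random_instance(rng, max_side=6)
        w = pixel_weights(img, SPEC)
        assert pooled_soft_ncut_loss(img, p, SPEC, 1) == pytest.approx(
            soft_ncut_loss(p, w), abs=1e-9)

    def test_constant_inputs_pooling_invariant(self):
        img = np.full((8, 8), 0.3)
        p = np.full((2, 8, 8), 0.5)
        j1 = pooled_soft_ncut_loss(img, p, SPEC, 1)
        j2 = pooled_soft_ncut_loss(img, p, SPEC, 2)
        j4 = pooled_soft_ncut_loss(img, p, SPEC, 4)
        # constant fields pool to constants; J stays at its uniform value
        assert j1 == pytest.approx(1.0, abs=1e-6)
        assert j2 == pytest.approx(1.0, abs=1e-6)
        assert j4 == pytest.approx(1.0, abs=1e-6)

    def test_pooled_grid_size(self, rng):
        img = rng.random((16, 16))
        assert average_pool(img, 2).shape == (8, 8)
        with pytest.raises(ValueError):
            average_pool(img, 3)
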
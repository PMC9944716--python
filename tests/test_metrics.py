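"""Similarity-metric unit tests against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from nmgreg import (
    Image2D,
    MetricConfig,
    estimate_scale_s,
    gradient_difference,
    gradient_images,
    joint_entropy,
    joint_histogram,
    mutual_information,
    nmg,
    nmi,
    shannon_entropy,
)


def brute_force_joint_entropy(a, b, bins):
    """Independent oracle: explicit double sum over enumerated bin pairs."""
    av, bv = np.ravel(a), np.ravel(b)

    def binned(x):
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(x.size, dtype=int)
        return np.minimum((np.floor((x - lo) / (hi - lo) * bins)).astype(int), bins - 1)

    ia, ib = binned(av), binned(bv)
    h = 0.0
    n = av.size
    for i in range(bins):
        for j in range(bins):
            p = np.sum((ia == i) & (ib == j)) / n
            if p > 0:
                h -= p * np.log2(p)
    return h


def brute_force_mi(a, b, bins):
    """MI as the direct double sum of p log2 p/(P_a P_b)."""
    av, bv = np.ravel(a), np.ravel(b)

    def binned(x):
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(x.size, dtype=int)
        return np.minimum((np.floor((x - lo) / (hi - lo) * bins)).astype(int), bins - 1)

    ia, ib = binned(av), binned(bv)
    n = av.size
    mi = 0.0
    for i in range(bins):
        pa = np.sum(ia == i) / n
        for j in range(bins):
            pb = np.sum(ib == j) / n
            p = np.sum((ia == i) & (ib == j)) / n
            if p > 0:
                mi += p * np.log2(p / (pa * pb))
    return mi


class TestJointHistogram:
    def test_two_by_two_uniform_joint(self):
        # 4 pixel pairs enumerated by hand: (0,0),(0,1),(1,0),(1,1) once each
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [0.0, 1.0]])
        h = joint_histogram(a, b, bins=2)
        assert np.allclose(h.joint_p, 0.25)
        assert h.n_samples == 4

    def test_identical_two_level_image_is_diagonal(self):
        a = np.array([[0.0, 1.0], [0.0, 1.0]])
        h = joint_histogram(a, a, bins=2)
        assert h.counts[0, 1] == 0 and h.counts[1, 0] == 0
        assert h.counts[0, 0] == 2 and h.counts[1, 1] == 2

    def test_conservation_and_marginals(self, random_image):
        h = joint_histogram(random_image, random_image, bins=8)
        assert h.counts.sum() == random_image.pixels.size
        assert abs(h.joint_p.sum() - 1.0) < 1e-12
        assert np.allclose(h.marginal_a, h.joint_p.sum(axis=1), atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            joint_histogram(np.zeros((2, 2)), np.zeros((3, 3)), bins=2)


class TestEntropies:
    @pytest.mark.parametrize(
        "p, expected",
        [((1.0, 0.0), 0.0), ((0.5, 0.5), 1.0), ((0.25, 0.25, 0.25, 0.25), 2.0)],
    )
    def test_closed_forms(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.5, -0.5])

    def test_joint_entropy_identical_half_half(self):
        a = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert joint_entropy(joint_histogram(a, a, 2)) == pytest.approx(1.0, abs=1e-12)

    def test_joint_entropy_independent_two_bits(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert joint_entropy(joint_histogram(a, b, 2)) == pytest.approx(2.0, abs=1e-12)

    def test_entropy_bounds_random(self, rng):
        a, b = rng.random((9, 9)), rng.random((9, 9))
        h = joint_histogram(a, b, bins=6)
        ha, hb = shannon_entropy(h.marginal_a), shannon_entropy(h.marginal_b)
        hj = joint_entropy(h)
        assert max(ha, hb) - 1e-9 <= hj <= ha + hb + 1e-9


class TestMutualInformation:
    def test_mi_of_image_with_itself_is_entropy(self, rng):
        a = rng.random((8, 8))
        h = joint_histogram(a, a, bins=8)
        assert mutual_information(h) == pytest.approx(shannon_entropy(h.marginal_a), abs=1e-9)

    def test_independent_pairs_zero_mi(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert mutual_information(joint_histogram(a, b, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_double_sum(self, rng):
        a, b = rng.random((7, 8)), rng.random((7, 8))
        h = joint_histogram(a, b, bins=4)
        assert mutual_information(h) == pytest.approx(brute_force_mi(a, b, 4), abs=1e-12)
        assert joint_entropy(h) == pytest.approx(brute_force_joint_entropy(a, b, 4), abs=1e-12)


class TestNMI:
    def test_self_similarity_is_two(self, rng):
        a = rng.random((10, 10))
        assert nmi(joint_histogram(a, a, 8)) == pytest.approx(2.0, abs=1e-9)

    def test_independent_two_by_two_is_one(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert nmi(joint_histogram(a, b, 2)) == pytest.approx(1.0, abs=1e-12)

    def test_two_formulations_agree(self, rng):
        a, b = rng.random((20, 20)), rng.random((20, 20))
        h = joint_histogram(a, b, bins=16)
        ha, hb = shannon_entropy(h.marginal_a), shannon_entropy(h.marginal_b)
        hj = joint_entropy(h)
        assert nmi(h) == pytest.approx((ha + hb) / hj, abs=1e-9)

    def test_independent_noise_approaches_one(self, rng):
        a, b = rng.random((100, 100)), rng.random((100, 100))
        assert nmi(joint_histogram(a, b, 32)) == pytest.approx(1.0, abs=0.05)

    def test_constant_images_degenerate(self):
        same = nmi(joint_histogram(np.ones((4, 4)), np.ones((4, 4)), 4))
        assert same == 2.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1, width=32)))
    def test_nmi_bounded(self, arr):
        h = joint_histogram(arr, arr[::-1], bins=4)
        assert 1.0 - 1e-9 <= nmi(h) <= 2.0 + 1e-9


class TestGradients:
    def test_constant_image_zero_gradients(self):
        g = gradient_images(np.full((5, 5), 3.0))
        assert np.all(g.gh == 0) and np.all(g.gv == 0)

    def test_column_ramp(self):
        img = 2.5 * np.tile(np.arange(6.0), (4, 1))
        g = gradient_images(img)
        assert np.allclose(g.gh, 2.5)
        assert np.allclose(g.gv, 0.0)

    def test_matches_stencil_oracle(self, rng):
        img = rng.random((5, 5))
        g = gradient_images(img)
        for r in range(5):
            for c in range(5):
                if c == 0:
                    exp = img[r, 1] - img[r, 0]
                elif c == 4:
                    exp = img[r, 4] - img[r, 3]
                else:
                    exp = (img[r, c + 1] - img[r, c - 1]) / 2
                assert g.gh[r, c] == pytest.approx(exp, abs=1e-12)


class TestScaleFactor:
    def test_identical_images_unit_scale(self, random_image):
        assert estimate_scale_s(random_image, random_image) == pytest.approx(1.0, abs=1e-12)

    def test_exact_double(self, rng):
        b = rng.random((6, 6))
        assert estimate_scale_s(2.0 * b, b) == pytest.approx(2.0, abs=1e-9)

    def test_matches_grid_search(self, rng):
        a = rng.random((8, 8))
        b = a + 0.3 * rng.random((8, 8))
        ga, gb = gradient_images(a), gradient_images(b)

        def residual(s):
            return ((ga.gh - s * gb.gh) ** 2).sum() + ((ga.gv - s * gb.gv) ** 2).sum()

        grid = np.arange(0.0, 5.0, 1e-4)
        best = grid[np.argmin([residual(s) for s in grid])]
        assert estimate_scale_s(a, b) == pytest.approx(best, abs=1e-3)

    def test_fixed_mode_passthrough(self, random_image):
        assert estimate_scale_s(random_image, random_image, mode=1.7) == 1.7

    def test_degenerate_b_returns_one(self, random_image):
        assert estimate_scale_s(random_image, np.ones((12, 10))) == 1.0


class TestGradientDifference:
    def test_identical_images_max_similarity(self, random_image):
        cfg = MetricConfig(s=1.0)
        gd, s, diffs = gradient_difference(random_image, random_image, cfg)
        assert gd == 1.0  # every pixel term sigma/sigma
        assert s == 1.0
        assert np.all(diffs.idv == 0) and np.all(diffs.idh == 0)

    def test_decreases_with_noise_amplitude(self, rng):
        a = rng.random((16, 16))
        cfg = MetricConfig(s=1.0)
        noise = rng.standard_normal((16, 16))
        values = [gradient_difference(a, a + amp * noise, cfg)[0] for amp in (0.1, 0.3, 0.9)]
        assert values[0] > values[1] > values[2]

    def test_three_by_three_brute_force(self):
        a = np.array([[0.0, 1.0, 0.5], [0.2, 0.8, 0.1], [0.9, 0.4, 0.6]])
        b = np.array([[0.3, 0.7, 0.2], [0.1, 0.5, 0.9], [0.6, 0.2, 0.8]])
        cfg = MetricConfig(s=1.0, sigma_v=1.0, sigma_h=1.0, normalize_components=False)
        gd, _, _ = gradient_difference(a, b, cfg)
        ga, gb = gradient_images(a), gradient_images(b)
        expected = 0.0
        for r in range(3):
            for c in range(3):
                expected += 1.0 / (1.0 + (ga.gh[r, c] - gb.gh[r, c]) ** 2)
                expected += 1.0 / (1.0 + (ga.gv[r, c] - gb.gv[r, c]) ** 2)
        assert gd == pytest.approx(expected, abs=1e-12)

    def test_normalized_range(self, rng):
        a, b = rng.random((10, 10)), rng.random((10, 10))
        gd, _, _ = gradient_difference(a, b, MetricConfig())
        assert 0.0 < gd <= 1.0


class TestNMG:
    def test_self_similarity_is_one(self, random_image):
        rep = nmg(random_image, random_image, MetricConfig(s=1.0))
        assert rep.nmg == pytest.approx(1.0, abs=1e-12)
        assert rep.cost == pytest.approx(0.0, abs=1e-12)

    def test_weight_degeneracy_nmi_only(self, rng):
        a, b = rng.random((12, 12)), rng.random((12, 12))
        rep = nmg(a, b, MetricConfig(alpha1=1.0, alpha2=0.0))
        assert rep.nmg == pytest.approx(rep.nmi - 1.0, abs=1e-12)

    def test_definitional_consistency(self, rng):
        a, b = rng.random((12, 12)), rng.random((12, 12))
        cfg = MetricConfig(alpha1=0.3, alpha2=0.7)
        rep = nmg(a, b, cfg)
        assert rep.nmg == pytest.approx(0.3 * (rep.nmi - 1.0) + 0.7 * rep.gd, abs=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            MetricConfig(alpha1=0.7, alpha2=0.7)

    def test_report_entropy_invariants(self, rng):
        a, b = rng.random((15, 15)), rng.random((15, 15))
        rep = nmg(a, b, MetricConfig())
        assert rep.mi <= min(rep.h_a, rep.h_b) + 1e-9
        assert rep.mi >= -1e-9
        assert 1.0 - 1e-9 <= rep.nmi <= 2.0 + 1e-9
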
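import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heteromap import (
    AbundanceDistribution,
    DistanceMatrix,
    build_distance_matrix,
    hill,
    rao_q,
    rao_q_from_sample,
    rao_q_multilayer,
    relative_abundances,
    renyi,
    shannon,
    simpson_dominance,
)
from heteromap.exceptions import (
    EmptySampleError,
    MetricMismatchError,
    ParameterError,
    ShapeMismatchError,
)

from conftest import random_distribution, random_sample
from naive_ref import naive_rao

ARRAY_A = np.arange(1, 10)
ARRAY_B = np.array([1, 102, 103, 104, 105, 106, 107, 108, 109])
LN9 = math.log(9)


# strategy: integer counts -> valid distribution
counts_st = st.lists(st.integers(1, 50), min_size=1, max_size=15)


def dist_from_counts(counts):
    sample = np.repeat(np.arange(len(counts)), counts)
    return relative_abundances(sample)


# ---------------------------------------------------------------------------
# relative_abundances


class TestRelativeAbundances:
    def test_nine_distinct_values(self):
        d = relative_abundances(ARRAY_A)
        assert d.richness == 9
        assert d.n_obs == 9
        np.testing.assert_allclose(d.abundances, np.full(9, 1 / 9))

    def test_constant_sample(self):
        d = relative_abundances(np.array([5, 5, 5, 5]))
        assert d.richness == 1
        assert d.values[0] == 5
        assert d.abundances[0] == 1.0
        assert d.n_obs == 4

    def test_direct_counting(self):
        d = relative_abundances(np.array([2, 2, 7]))
        np.testing.assert_array_equal(d.values, [2, 7])
        np.testing.assert_allclose(d.abundances, [2 / 3, 1 / 3])

    def test_values_sorted_ascending(self):
        d = relative_abundances(np.array([9, 1, 5, 1]))
        assert list(d.values) == [1, 5, 9]

    def test_order_independence(self, rng):
        sample = rng.integers(0, 6, size=40)
        d1 = relative_abundances(sample)
        d2 = relative_abundances(sample[::-1])
        np.testing.assert_array_equal(d1.values, d2.values)
        np.testing.assert_array_equal(d1.abundances, d2.abundances)

    def test_empty_sample_raises(self):
        with pytest.raises(EmptySampleError):
            relative_abundances(np.array([]))

    def test_tuple_values_lexicographic(self):
        obs = np.array([[1, 5], [0, 9], [1, 5], [0, 2]])
        d = relative_abundances(obs)
        np.testing.assert_array_equal(d.values, [[0, 2], [0, 9], [1, 5]])
        np.testing.assert_allclose(d.abundances, [0.25, 0.25, 0.5])

    @given(counts_st)
    @settings(max_examples=100, deadline=None)
    def test_normalization_invariant(self, counts):
        d = dist_from_counts(counts)
        assert abs(d.abundances.sum() - 1.0) <= 1e-12
        assert np.all(d.abundances > 0)
        assert 1 <= d.richness <= d.n_obs


class TestAbundanceDistributionValidation:
    def test_rejects_nonunit_sum(self):
        with pytest.raises(ValueError):
            AbundanceDistribution(
                values=np.array([1, 2]), abundances=np.array([0.5, 0.6]), n_obs=2
            )

    def test_rejects_zero_abundance(self):
        with pytest.raises(ValueError):
            AbundanceDistribution(
                values=np.array([1, 2]), abundances=np.array([1.0, 0.0]), n_obs=2
            )

    def test_rejects_richness_above_n_obs(self):
        with pytest.raises(ValueError):
            AbundanceDistribution(
                values=np.array([1, 2]), abundances=np.array([0.5, 0.5]), n_obs=1
            )


# ---------------------------------------------------------------------------
# shannon


class TestShannon:
    def test_array_a_is_ln9(self, uniform9):
        assert shannon(uniform9) == pytest.approx(LN9, abs=1e-12)

    def test_array_b_equals_array_a(self):
        assert shannon(relative_abundances(ARRAY_B)) == pytest.approx(LN9, abs=1e-12)

    def test_printed_value(self, uniform9):
        # six-decimal value as printed alongside the worked example
        assert shannon(uniform9) == pytest.approx(2.197225, abs=5e-7)

    def test_constant_sample_is_zero(self):
        assert shannon(relative_abundances(np.array([5, 5, 5]))) == 0.0

    @given(counts_st)
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, counts):
        d = dist_from_counts(counts)
        h = shannon(d)
        assert -1e-12 <= h <= math.log(d.richness) + 1e-12
        uniform = len(set(counts)) == 1
        at_max = abs(h - math.log(d.richness)) <= 1e-12
        assert at_max == uniform


# ---------------------------------------------------------------------------
# renyi


class TestRenyi:
    def test_alpha0_log_richness(self, uniform9):
        assert renyi(uniform9, 0) == pytest.approx(LN9, abs=1e-12)

    def test_alpha2_two_classes(self):
        d = relative_abundances(np.array([0, 1]))
        # direct evaluation: (1/(1-2)) * ln(0.25 + 0.25) = ln 2
        assert renyi(d, 2) == pytest.approx(math.log(2), abs=1e-12)

    def test_alpha1_routes_to_shannon(self, rng):
        for _ in range(10):
            d = random_distribution(rng)
            assert renyi(d, 1.0) == shannon(d)

    def test_negative_alpha_rejected(self, uniform9):
        with pytest.raises(ParameterError):
            renyi(uniform9, -0.5)

    def test_large_alpha_stable(self):
        d = relative_abundances(np.array([0] * 99 + [1]))
        # alpha -> inf limit is -ln(p_max)
        assert renyi(d, 500) == pytest.approx(-math.log(0.99), rel=1e-2)
        assert np.isfinite(renyi(d, 500))

    @given(counts_st, st.floats(0, 20), st.floats(0, 20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_nonincreasing_in_alpha(self, counts, a1, a2):
        d = dist_from_counts(counts)
        lo, hi = sorted((a1, a2))
        assert renyi(d, lo) >= renyi(d, hi) - 1e-9

    def test_limit_continuity_100_random(self, rng):
        for _ in range(100):
            d = random_distribution(rng)
            h = shannon(d)
            assert abs(renyi(d, 1 + 1e-6) - h) < 1e-4
            assert abs(renyi(d, 1 - 1e-6) - h) < 1e-4


# ---------------------------------------------------------------------------
# simpson


class TestSimpsonDominance:
    def test_single_class(self):
        assert simpson_dominance(relative_abundances(np.array([3]))) == 1.0

    def test_uniform_nine(self, uniform9):
        assert simpson_dominance(uniform9) == pytest.approx(1 / 9, abs=1e-15)

    def test_two_even_classes(self):
        d = relative_abundances(np.array([0, 1]))
        assert simpson_dominance(d) == pytest.approx(0.5, abs=1e-15)

    @given(counts_st)
    @settings(max_examples=100, deadline=None)
    def test_renyi2_identity(self, counts):
        d = dist_from_counts(counts)
        assert abs(renyi(d, 2) - math.log(1 / simpson_dominance(d))) <= 1e-12


# ---------------------------------------------------------------------------
# hill


class TestHill:
    def test_q0_is_richness(self, uniform9):
        assert hill(uniform9, 0) == pytest.approx(9.0, abs=1e-12)

    def test_constant_sample_any_q(self):
        d = relative_abundances(np.array([7, 7]))
        for q in (0, 0.5, 1, 2, 10):
            assert hill(d, q) == pytest.approx(1.0, abs=1e-12)

    def test_q2_two_even_classes(self):
        d = relative_abundances(np.array([0, 1]))
        # (0.25 + 0.25)^(1/(1-2)) = 2
        assert hill(d, 2) == pytest.approx(2.0, abs=1e-12)

    def test_negative_q_rejected(self, uniform9):
        with pytest.raises(ParameterError):
            hill(uniform9, -1)

    @given(counts_st, st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_exp_renyi_identity(self, counts, q):
        d = dist_from_counts(counts)
        assert hill(d, q) == pytest.approx(math.exp(renyi(d, q)), abs=1e-9)


# ---------------------------------------------------------------------------
# distance matrix


class TestBuildDistanceMatrix:
    def test_two_extremes(self):
        d = relative_abundances(np.array([0, 255]))
        m = build_distance_matrix(d, "absolute-difference")
        np.testing.assert_array_equal(m.entries, [[0, 255], [255, 0]])

    def test_three_four_five_triangle(self):
        d = relative_abundances(np.array([[0, 0], [3, 4]]))
        m = build_distance_matrix(d, "euclidean")
        assert m.entries[0, 1] == pytest.approx(5.0, abs=1e-12)

    def test_three_values(self):
        d = relative_abundances(np.array([1, 2, 3]))
        m = build_distance_matrix(d)
        np.testing.assert_array_equal(m.entries, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])

    def test_manhattan(self):
        d = relative_abundances(np.array([[0, 0], [3, 4]]))
        m = build_distance_matrix(d, "manhattan")
        assert m.entries[0, 1] == 7.0

    def test_scalar_metric_on_tuples_rejected(self):
        d = relative_abundances(np.array([[0, 0], [1, 1]]))
        with pytest.raises(MetricMismatchError):
            build_distance_matrix(d, "absolute-difference")

    def test_tuple_metric_on_scalars_rejected(self):
        d = relative_abundances(np.array([1, 2]))
        with pytest.raises(MetricMismatchError):
            build_distance_matrix(d, "euclidean")

    def test_unknown_metric_rejected(self, uniform9):
        with pytest.raises(ParameterError):
            build_distance_matrix(uniform9, "chebyshev")

    def test_symmetric_zero_diagonal(self, rng):
        for _ in range(5):
            d = random_distribution(rng)
            m = build_distance_matrix(d)
            assert np.array_equal(m.entries, m.entries.T)
            assert np.all(np.diagonal(m.entries) == 0)

    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(entries=np.array([[0.0, 1.0], [2.0, 0.0]]), metric_name="x")
        with pytest.raises(ValueError):
            DistanceMatrix(entries=np.array([[1.0]]), metric_name="x")


# ---------------------------------------------------------------------------
# rao


class TestRaoQ:
    def test_constant_window_is_zero(self):
        assert rao_q_from_sample(np.array([4, 4, 4, 4])) == 0.0

    def test_two_extremes(self):
        # brute force over the 4 ordered pixel pairs: 2 * 255 / 4
        assert rao_q_from_sample(np.array([0, 255])) == pytest.approx(127.5, abs=1e-12)

    def test_array_a(self):
        # brute force: sum |i - j| over 81 ordered pairs = 240, / 81
        assert rao_q_from_sample(ARRAY_A) == pytest.approx(240 / 81, abs=1e-12)

    def test_dimension_mismatch_rejected(self, uniform9):
        m = DistanceMatrix(entries=np.zeros((2, 2)), metric_name="absolute-difference")
        with pytest.raises(ShapeMismatchError):
            rao_q(uniform9, m)

    def test_bounds(self, rng):
        for _ in range(20):
            sample = random_sample(rng)
            d = relative_abundances(sample)
            m = build_distance_matrix(d)
            q = rao_q(d, m)
            assert 0.0 <= q <= m.entries.max() + 1e-12

    def test_oracle_equivalence_100_random_samples(self, rng):
        # distinct-value formulation vs brute force over all ordered
        # pixel pairs x 1/n^2
        for _ in range(100):
            sample = random_sample(rng, max_size=81)
            expected = naive_rao([int(v) for v in sample])
            assert rao_q_from_sample(sample) == pytest.approx(expected, abs=1e-10)

    @given(counts_st, st.integers(-1000, 1000), st.floats(0.01, 100))
    @settings(max_examples=60, deadline=None)
    def test_translation_and_scale(self, counts, shift, scale):
        sample = np.repeat(np.arange(len(counts), dtype=np.float64), counts)
        base = rao_q_from_sample(sample)
        assert rao_q_from_sample(sample + shift) == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert rao_q_from_sample(sample * scale) == pytest.approx(
            scale * base, rel=1e-9, abs=1e-9
        )

    def test_distance_sensitivity_contrast(self):
        # equal Shannon, but the wide-spread array has the larger Rao Q
        da, db = relative_abundances(ARRAY_A), relative_abundances(ARRAY_B)
        assert shannon(da) == pytest.approx(shannon(db), abs=1e-12)
        assert rao_q_from_sample(ARRAY_B) > rao_q_from_sample(ARRAY_A)


class TestRaoQMultilayer:
    def test_two_identical_constant_layers(self):
        layers = [np.full(9, 3.0), np.full(9, 3.0)]
        assert rao_q_multilayer(layers) == 0.0

    def test_single_layer_reduces_exactly(self, rng):
        for _ in range(10):
            sample = random_sample(rng)
            assert rao_q_multilayer([sample], "absolute-difference") == rao_q_from_sample(
                sample
            )

    def test_two_layer_euclidean(self):
        # cross pair distance sqrt(3^2 + 4^2) = 5; 2 * 5 / 4 ordered pairs
        q = rao_q_multilayer([np.array([0, 3]), np.array([0, 4])], "euclidean")
        assert q == pytest.approx(2.5, abs=1e-12)

    def test_two_layer_against_naive(self, rng):
        from naive_ref import euclidean, naive_rao

        for _ in range(10):
            n = int(rng.integers(2, 40))
            l1 = rng.integers(0, 6, size=n)
            l2 = rng.integers(0, 6, size=n)
            tuples = list(zip(l1.tolist(), l2.tolist()))
            expected = naive_rao(tuples, distance=euclidean)
            assert rao_q_multilayer([l1, l2], "euclidean") == pytest.approx(
                expected, abs=1e-10
            )

    def test_misaligned_layers_rejected(self):
        with pytest.raises(ShapeMismatchError):
            rao_q_multilayer([np.arange(4), np.arange(5)])

    def test_no_layers_rejected(self):
        with pytest.raises(EmptySampleError):
            rao_q_multilayer([])
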
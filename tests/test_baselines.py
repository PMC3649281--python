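import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from copamix import (
    copa_statistic,
    most_statistic,
    order_statistic_moments,
    ort_statistic,
    os_statistic,
    robust_center_scale_pooled,
    t_statistic,
)
from copamix.baselines import MAD_SCALE, OrderStatMoments

import naive_reference as ref
from conftest import make_dataset, random_dataset

# shared hand-worked fixture: normal (1..5), one extreme cancer value
X_HAND = [[1.0, 2.0, 3.0, 4.0, 5.0]]
Y_HAND = [[1.0, 2.0, 3.0, 4.0, 20.0]]


class TestRobustCenterScale:
    def test_hand_computed_even_count(self):
        ds = make_dataset([[1.0, 2.0, 3.0]], [[4.0, 5.0, 100.0]])
        med, mad = robust_center_scale_pooled(ds, "g1")
        assert med == pytest.approx(3.5)
        assert mad == pytest.approx(MAD_SCALE * 1.5)

    def test_constant_gene_has_zero_mad(self):
        ds = make_dataset([[2.0, 2.0]], [[2.0, 2.0]])
        med, mad = robust_center_scale_pooled(ds, "g1")
        assert (med, mad) == (2.0, 0.0)

    def test_symmetric_data_centered_at_zero(self):
        ds = make_dataset([[-3.0, -1.0, 1.0]], [[3.0, -2.0, 2.0]])
        assert robust_center_scale_pooled(ds, "g1")[0] == 0.0


class TestTStatistic:
    def test_hand_computed_pooled_variance(self):
        ds = make_dataset([[0.0, 1.0]], [[2.0, 3.0]])
        assert t_statistic(ds).score[0] == pytest.approx(2.0 / math.sqrt(0.5))

    def test_identical_groups_give_zero(self):
        ds = make_dataset([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        assert t_statistic(ds).score[0] == 0.0

    def test_sign_flips_when_classes_swap(self):
        x, y = [[0.0, 1.0, 0.5]], [[2.0, 3.0, 2.5]]
        assert t_statistic(make_dataset(x, y)).score[0] == pytest.approx(
            -t_statistic(make_dataset(y, x)).score[0]
        )

    def test_requires_two_cancer_samples(self):
        with pytest.raises(ValueError, match="2 cancer"):
            t_statistic(make_dataset([[0.0, 1.0]], [[2.0]]))

    def test_zero_pooled_variance_is_nan(self):
        ds = make_dataset([[1.0, 1.0]], [[1.0, 1.0]])
        assert np.isnan(t_statistic(ds).score[0])


class TestCopa:
    def test_hand_computed_value(self):
        ds = make_dataset([[1.0, 2.0, 3.0]], [[4.0, 5.0, 100.0]])
        # q90 of cancer by linear order-statistic interpolation = 81
        expected = (81.0 - 3.5) / (MAD_SCALE * 1.5)
        assert copa_statistic(ds, r=90).score[0] == pytest.approx(expected)

    def test_constant_cancer_class_any_percentile(self):
        ds = make_dataset([[1.0, 2.0, 3.0]], [[7.0, 7.0, 7.0]])
        med, mad = robust_center_scale_pooled(ds, "g1")
        for r in (25, 75, 90, 95):
            assert copa_statistic(ds, r=r).score[0] == pytest.approx((7.0 - med) / mad)

    def test_translation_invariance(self):
        ds = make_dataset(X_HAND, Y_HAND)
        shifted = make_dataset(np.asarray(X_HAND) + 5, np.asarray(Y_HAND) + 5)
        assert copa_statistic(ds).score[0] == pytest.approx(
            copa_statistic(shifted).score[0]
        )

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError, match="percentile"):
            copa_statistic(make_dataset(X_HAND, Y_HAND), r=0.0)


class TestOutlierSum:
    def test_hand_computed_value(self):
        ds = make_dataset(X_HAND, Y_HAND)
        # pooled q75 = 4, IQR = 2, threshold 6 -> outliers {20}; med 3, mad 1.4826
        assert os_statistic(ds).score[0] == pytest.approx(17.0 / MAD_SCALE)

    def test_no_exceedance_gives_zero(self):
        ds = make_dataset(X_HAND, [[1.0, 2.0, 3.0, 4.0, 5.0]])
        assert os_statistic(ds).score[0] == 0.0

    def test_outlier_sum_is_additive_over_outlier_set(self):
        """Each duplicated outlier sample adds its own standardized exceedance."""
        base = make_dataset([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], [[1.0, 2.0, 3.0, 20.0]])
        dup = make_dataset(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], [[1.0, 2.0, 3.0, 20.0, 20.0]]
        )
        med_b, mad_b = robust_center_scale_pooled(base, "g1")
        med_d, mad_d = robust_center_scale_pooled(dup, "g1")
        assert os_statistic(base).score[0] * mad_b == pytest.approx(20.0 - med_b)
        assert os_statistic(dup).score[0] * mad_d == pytest.approx(2 * (20.0 - med_d))


class TestOrt:
    def test_hand_computed_value(self):
        ds = make_dataset(X_HAND, Y_HAND)
        # normal q75 = 4, IQR = 2, threshold 6; med_x = 3, mad* = 1.4826
        assert ort_statistic(ds).score[0] == pytest.approx(17.0 / MAD_SCALE)

    def test_all_cancer_below_threshold(self):
        ds = make_dataset(X_HAND, [[0.0, 1.0, 2.0, 3.0, 4.0]])
        assert ort_statistic(ds).score[0] == 0.0

    def test_scale_invariance(self):
        ds = make_dataset(X_HAND, Y_HAND)
        scaled = make_dataset(np.asarray(X_HAND) * 3.7, np.asarray(Y_HAND) * 3.7)
        assert ort_statistic(ds).score[0] == pytest.approx(
            ort_statistic(scaled).score[0]
        )


class TestOrderStatMoments:
    def test_single_sample_is_standard_normal(self):
        m = order_statistic_moments(1, reps=50_000, seed=4)
        se = 1.0 / math.sqrt(m.reps)
        assert abs(m.mu[0]) < 3 * se
        assert abs(m.sigma[0] - 1.0) < 0.02

    def test_expected_maximum_of_two(self):
        """E[max of two N(0,1)] = 1/sqrt(pi)."""
        m = order_statistic_moments(2, reps=100_000, seed=4)
        sd_max = math.sqrt(1.0 - 1.0 / math.pi)
        assert abs(m.mu[0] - 1.0 / math.sqrt(math.pi)) < 3 * sd_max / math.sqrt(m.reps)

    @pytest.mark.parametrize("n1", [2, 5, 20])
    def test_full_sum_moments(self, n1):
        """The sum of all order statistics is the plain sum: mean 0, var n1."""
        m = order_statistic_moments(n1, reps=100_000, seed=4)
        assert abs(m.mu[-1]) < 3 * math.sqrt(n1 / m.reps)
        se_var = n1 * math.sqrt(2.0 / (m.reps - 1))
        assert abs(m.sigma[-1] ** 2 - n1) < 3 * se_var

    def test_deterministic_and_cached(self):
        a = order_statistic_moments(3, reps=2000, seed=11)
        b = order_statistic_moments(3, reps=2000, seed=11)
        assert a is b
        np.testing.assert_array_equal(a.mu, b.mu)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n1"):
            order_statistic_moments(0)
        with pytest.raises(ValueError, match="1000"):
            order_statistic_moments(5, reps=10)


class TestMost:
    def analytic_single_moments(self):
        return OrderStatMoments(
            n1=1, mu=np.array([0.0]), sigma=np.array([1.0]), reps=0, seed=0
        )

    def test_single_cancer_sample_reduction(self):
        ds = make_dataset(X_HAND, [[20.0]])
        score = most_statistic(ds, self.analytic_single_moments()).score[0]
        med_x, _ = 3.0, None
        mad_star = MAD_SCALE * ref.median(
            [abs(v - 3.0) for v in X_HAND[0]] + [0.0]
        )
        assert score == pytest.approx((20.0 - 3.0) / mad_star)

    def test_matches_bruteforce_k_enumeration(self):
        moments = order_statistic_moments(5, reps=2000, seed=3)
        ds = make_dataset(X_HAND, Y_HAND)
        expected = ref.most_stat(X_HAND[0], Y_HAND[0], moments.mu, moments.sigma)
        assert most_statistic(ds, moments).score[0] == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance(self):
        moments = order_statistic_moments(5, reps=2000, seed=3)
        ds = make_dataset(X_HAND, Y_HAND)
        shifted = make_dataset(np.asarray(X_HAND) - 2.5, np.asarray(Y_HAND) - 2.5)
        assert most_statistic(ds, moments).score[0] == pytest.approx(
            most_statistic(shifted, moments).score[0]
        )

    def test_moment_size_mismatch_rejected(self):
        moments = order_statistic_moments(4, reps=2000, seed=3)
        with pytest.raises(ValueError, match="n1"):
            most_statistic(make_dataset(X_HAND, Y_HAND), moments)


@given(
    a=st.floats(min_value=0.1, max_value=50.0),
    b=st.floats(min_value=-20.0, max_value=20.0),
)
def test_affine_invariance_of_all_statistics(a, b):
    """Every statistic is unchanged by v -> a*v + b (a > 0) on a gene row."""
    rng = np.random.default_rng(8)
    ds = random_dataset(rng, G=6, n0=6, n1=6)
    scaled = make_dataset(a * ds.normal_values + b, a * ds.cancer_values + b)
    moments = order_statistic_moments(6, reps=2000, seed=3)
    for fn in (
        t_statistic,
        copa_statistic,
        os_statistic,
        ort_statistic,
        lambda d: most_statistic(d, moments),
    ):
        np.testing.assert_allclose(
            fn(scaled).score, fn(ds).score, rtol=1e-7, atol=1e-9, equal_nan=True
        )
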
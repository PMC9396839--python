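"""Metric definitions against independent oracles and known values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarval import (
    ActivityPairs,
    DegenerateInputError,
    Eq4Convention,
    InsufficientDataError,
    ND,
    UsageError,
    compute_metric_set,
    concordance_cc,
    r0prime_sq_eq4,
    r0sq_eq3,
    r0sq_eq5,
    rm_squared,
    rto_slopes,
    squared_correlation,
)
from oracles import (
    oracle_ccc,
    oracle_r0prime_sq_swapped,
    oracle_r0sq_eq3,
    oracle_r0sq_eq5,
    oracle_r2,
    oracle_rm2,
    oracle_slope_numeric,
    oracle_slopes,
    oracle_uncentered_corr_sq,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def pairs(x, y):
    return ActivityPairs(x, y)


class TestSquaredCorrelation:
    def test_perfect_prediction(self):
        assert squared_correlation(pairs([1, 2, 3], [1, 2, 3])) == pytest.approx(1.0)

    def test_perfect_anticorrelation_squares_to_one(self):
        p = pairs([1, 2, 3], [5, 3, 1])
        assert squared_correlation(p) == pytest.approx(1.0)
        assert compute_metric_set(p).pearson_sign == -1

    def test_matches_direct_formula_oracle(self):
        x, y = [1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8]
        assert squared_correlation(pairs(x, y)) == pytest.approx(
            oracle_r2(x, y), rel=1e-12
        )

    def test_symmetric_in_arguments(self, random_pairs):
        p = random_pairs(15)
        q = ActivityPairs(p.y_pred, p.y_exp)
        assert squared_correlation(p) == pytest.approx(squared_correlation(q))

    @pytest.mark.parametrize(
        "x,y,exc",
        [
            ([1, 1, 1], [1, 2, 3], DegenerateInputError),
            ([1, 2, 3], [2, 2, 2], DegenerateInputError),
            ([1, 2], [1, 2], InsufficientDataError),
        ],
    )
    def test_degenerate_inputs(self, x, y, exc):
        with pytest.raises(exc):
            squared_correlation(pairs(x, y))


class TestThroughOriginSlopes:
    def test_identity_vectors(self):
        k, kp = rto_slopes(pairs([1, 2, 3], [1, 2, 3]))
        assert k == pytest.approx(1.0) and kp == pytest.approx(1.0)

    def test_proportional_scaling(self):
        k, kp = rto_slopes(pairs([1, 2, 3], [2, 4, 6]))
        assert k == pytest.approx(0.5)
        assert kp == pytest.approx(2.0)

    def test_slope_product_is_squared_uncentered_correlation(self, random_pairs):
        for _ in range(20):
            p = random_pairs(10)
            k, kp = rto_slopes(p)
            assert k * kp == pytest.approx(
                oracle_uncentered_corr_sq(list(p.y_exp), list(p.y_pred)), rel=1e-12
            )

    def test_matches_numeric_minimisation(self, random_pairs):
        p = random_pairs(9)
        k, _ = rto_slopes(p)
        assert k == pytest.approx(
            oracle_slope_numeric(list(p.y_exp), list(p.y_pred)), abs=1e-7
        )

    def test_all_zero_vector_errors(self):
        with pytest.raises(DegenerateInputError):
            rto_slopes(pairs([1, 2], [0, 0]))


class TestThroughOriginR0sq:
    def test_identical_vectors(self):
        assert r0sq_eq3(pairs([1, 2, 3], [1, 2, 3])) == pytest.approx(1.0)

    def test_exact_proportional_fit(self):
        assert r0sq_eq3(pairs([1, 2, 3], [2, 4, 6])) == pytest.approx(1.0)

    def test_matches_minimisation_oracle(self):
        x, y = [1, 2, 3, 4], [1.5, 1.8, 3.5, 3.7]
        assert r0sq_eq3(pairs(x, y)) == pytest.approx(
            oracle_r0sq_eq3(x, y), abs=1e-7
        )

    def test_never_exceeds_r2(self, random_pairs):
        for _ in range(50):
            p = random_pairs(8, corr_noise=1.5)
            assert r0sq_eq3(p) <= squared_correlation(p) + 1e-12

    def test_constant_experimental_errors(self):
        with pytest.raises(DegenerateInputError):
            r0sq_eq3(pairs([2, 2, 2], [1, 2, 3]))


class TestReverseR0sqConventions:
    def test_identical_vectors_all_conventions(self):
        p = pairs([1, 2, 3], [1, 2, 3])
        for conv in Eq4Convention:
            assert r0prime_sq_eq4(p, conv) == pytest.approx(1.0)

    def test_printed_form_literal_arithmetic(self):
        # K'=2; residuals y_exp-2*y_pred = (-3,-6,-9); SS=126; SStot=2
        assert r0prime_sq_eq4(
            pairs([1, 2, 3], [2, 4, 6]), "printed"
        ) == pytest.approx(-62.0)

    def test_swapped_centered_proportional_case(self):
        assert r0prime_sq_eq4(
            pairs([1, 2, 3], [2, 4, 6]), "swapped_centered"
        ) == pytest.approx(1.0)

    def test_swapped_matches_oracle(self, random_pairs):
        p = random_pairs(11)
        assert r0prime_sq_eq4(p, "swapped_centered") == pytest.approx(
            oracle_r0prime_sq_swapped(list(p.y_exp), list(p.y_pred)), abs=1e-7
        )

    def test_uncentered_equals_eq5(self, random_pairs):
        p = random_pairs(7)
        assert r0prime_sq_eq4(p, "uncentered") == pytest.approx(
            r0sq_eq5(p), rel=1e-12
        )

    def test_unknown_convention_is_usage_error(self):
        with pytest.raises(UsageError):
            r0prime_sq_eq4(pairs([1, 2, 3], [1, 2, 4]), "centered")


class TestUncenteredR0sq:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 0], [0, 1], 0.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert r0sq_eq5(pairs(x, y)) == pytest.approx(expected)

    def test_swap_invariant(self, random_pairs):
        p = random_pairs(9)
        q = ActivityPairs(p.y_pred, p.y_exp)
        assert r0sq_eq5(p) == pytest.approx(r0sq_eq5(q), rel=1e-12)


class TestRmSquared:
    @pytest.mark.parametrize(
        "r2,r0,expected",
        [
            (0.834, 0.823, 0.7465293420626093),
            (0.725, 0.310, 0.25795142115621404),
            (0.9, 0.9, 0.9),
        ],
    )
    def test_values(self, r2, r0, expected):
        assert rm_squared(r2, r0) == pytest.approx(expected, abs=1e-9)
        assert rm_squared(r2, r0) == pytest.approx(oracle_rm2(r2, r0), abs=1e-12)

    def test_nd_when_r2_below_r0(self):
        assert rm_squared(0.372, 0.376) is ND

    def test_monotone_nonincreasing_in_gap(self):
        r2 = 0.85
        values = [rm_squared(r2, r2 - gap) for gap in (0.0, 0.05, 0.2, 0.5)]
        assert values == sorted(values, reverse=True)
        assert values[0] == pytest.approx(r2)

    def test_never_exceeds_r2(self, rng):
        for _ in range(100):
            r2 = rng.uniform(0.01, 1.0)
            r0 = r2 - rng.uniform(0.0, r2)
            assert rm_squared(r2, r0) <= r2 + 1e-12


class TestConcordance:
    def test_identical_vectors(self):
        assert concordance_cc(pairs([4, 5, 6], [4, 5, 6])) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        assert concordance_cc(pairs([1, 2, 3], [2, 3, 4])) == pytest.approx(4 / 7)

    def test_bounded_by_pearson(self, random_pairs):
        for _ in range(30):
            p = random_pairs(10, corr_noise=1.0)
            r = math.sqrt(squared_correlation(p))
            assert abs(concordance_cc(p)) <= r + 1e-12

    def test_bias_decreases_ccc_not_r2(self):
        base = pairs([5, 6, 7, 8, 9], [5.1, 5.9, 7.2, 7.8, 9.0])
        r2_base = squared_correlation(base)
        cccs = []
        for b in (0.0, 0.5, 1.0, 2.0):
            shifted = ActivityPairs(base.y_exp, base.y_pred + b)
            assert squared_correlation(shifted) == pytest.approx(r2_base)
            cccs.append(concordance_cc(shifted))
        assert cccs == sorted(cccs, reverse=True)
        assert cccs[-1] < cccs[0]

    def test_both_constant_errors(self):
        with pytest.raises(DegenerateInputError):
            concordance_cc(pairs([1, 1, 1], [1, 1, 1]))


def test_all_metrics_match_oracles_on_seeded_vectors():
    """Every metric agrees with its independent direct-summation oracle on
    1,000 random vectors of lengths 3-50."""
    rng = np.random.default_rng(424242)
    for _ in range(1000):
        n = int(rng.integers(3, 51))
        x = rng.uniform(-2.0, 12.0, n)
        y = x * rng.uniform(0.5, 1.5) + rng.normal(0, 1.0, n)
        if np.ptp(x) == 0 or np.ptp(y) == 0 or (x == 0).all() or (y == 0).all():
            continue
        p = ActivityPairs(x, y)
        xs, ys = list(x), list(y)
        assert squared_correlation(p) == pytest.approx(oracle_r2(xs, ys), rel=1e-9)
        k, kp = rto_slopes(p)
        ok, okp = oracle_slopes(xs, ys)
        assert k == pytest.approx(ok, rel=1e-9)
        assert kp == pytest.approx(okp, rel=1e-9)
        assert k * kp == pytest.approx(r0sq_eq5(p), rel=1e-12)
        assert r0sq_eq5(p) == pytest.approx(oracle_r0sq_eq5(xs, ys), rel=1e-9)
        assert concordance_cc(p) == pytest.approx(oracle_ccc(xs, ys), rel=1e-9)
        mx = sum(xs) / n
        ss_tot = sum((v - mx) ** 2 for v in xs)
        ss_res = sum((a - k * b) ** 2 for a, b in zip(xs, ys))
        assert r0sq_eq3(p) == pytest.approx(1 - ss_res / ss_tot, rel=1e-9, abs=1e-9)


@given(
    st.lists(st.floats(-50, 50), min_size=3, max_size=30),
    st.floats(0.01, 5),
    st.booleans(),
)
@settings(max_examples=200)
def test_ccc_is_one_only_for_exact_agreement(values, magnitude, negate):
    if max(values) - min(values) < 1e-6:  # effectively constant
        return
    p = ActivityPairs(values, values)
    assert concordance_cc(p) == pytest.approx(1.0)
    shift = -magnitude if negate else magnitude
    q = ActivityPairs(values, [v + shift for v in values])
    assert concordance_cc(q) < 1.0


@given(st.lists(st.floats(0.1, 20), min_size=3, max_size=25), st.data())
@settings(max_examples=200)
def test_slope_product_identity_property(xs, data):
    ys = data.draw(
        st.lists(
            st.floats(0.1, 20), min_size=len(xs), max_size=len(xs)
        )
    )
    p = ActivityPairs(xs, ys)
    k, kp = rto_slopes(p)
    assert k * kp == pytest.approx(r0sq_eq5(p), rel=1e-9)
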
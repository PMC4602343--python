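import math
from fractions import Fraction

import pytest

from dcjmoments import (
    ModelParams,
    bd_expected_components,
    breakpoint_recurrence,
    eh_expected_cycles,
    eh_expected_cycles_table,
    eh_formula,
    expected_breakpoints,
    expected_breakpoints_exact,
    proposition_mapping,
    seq4_expected_differences,
    seq_expected_differences,
)
from dcjmoments.moments import PrecisionError, eh_coefficients
from dcjmoments.oracles import exact_transposition_cycle_expectation


class TestExpectedBreakpoints:
    def test_zero_steps(self):
        assert expected_breakpoints(ModelParams.from_an(7, 9), 0) == 0.0

    def test_asymptote(self):
        p = ModelParams.from_an(2, 4)
        assert expected_breakpoints(p, 10_000) == pytest.approx(12 / 7)

    def test_one_step_equals_a_times_cut_probability(self):
        # single-step enumeration over all n(n-1) moves gives a * 2/n
        p = ModelParams.from_an(2, 4)
        assert expected_breakpoints(p, 1) == pytest.approx(1.0)
        assert expected_breakpoints_exact(p, 1) == Fraction(1)

    def test_increasing_concave_bounded(self):
        p = ModelParams.from_an(100, 120)
        vals = [expected_breakpoints(p, k) for k in range(0, 600)]
        diffs = [b - a for a, b in zip(vals, vals[1:])]
        assert all(d > 0 for d in diffs)
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(diffs, diffs[1:]))
        assert vals[-1] < 100 * 238 / 239

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_breakpoints(ModelParams.from_an(1, 1), 3)


class TestRecurrenceIdentity:
    @pytest.mark.parametrize("a,n", [(2, 4), (100, 120), (980, 1020)])
    def test_matches_closed_form(self, a, n):
        p = ModelParams.from_an(a, n)
        for k in (0, 1, 2, 10, 100, 1000, 2000):
            closed = expected_breakpoints(p, k)
            rec = breakpoint_recurrence(p, k)
            assert rec == pytest.approx(closed, rel=1e-12, abs=1e-12)

    def test_first_step_is_a_ps(self):
        p = ModelParams.from_an(50, 60)
        assert breakpoint_recurrence(p, 1) == pytest.approx(50 * 2 / 60)


class TestSequenceModels:
    def test_saturation_and_zero(self):
        assert seq_expected_differences(100, 0) == 0.0
        assert seq_expected_differences(100, 10**6) == pytest.approx(50.0)
        assert seq4_expected_differences(100, 0) == 0.0
        assert seq4_expected_differences(100, 10**5) == pytest.approx(50.0)

    def test_two_site_single_step_exhaustive(self):
        # N=2, one substitution: exactly one site differs, always
        assert seq_expected_differences(2, 1) == pytest.approx(1.0)

    def test_four_by_four_equals_rescaled_single_site(self):
        # quadrupling the length and quartering the differences turns the
        # 4x4 model into a single-site one, after matching the decay rates
        for N in (40, 100, 400):
            for k_s in (1, 5, 20, 100):
                four = seq4_expected_differences(N, k_s)
                k_single = k_s * math.log(1 - 8 / N) / math.log(1 - 2 / (4 * N))
                single = seq_expected_differences(4 * N, k_single)
                assert four == pytest.approx(single / 4, rel=1e-12)
                assert k_single == pytest.approx(16 * k_s, rel=0.25)


class TestPropositionMapping:
    def test_exact_equality_with_breakpoint_formula(self):
        p = ModelParams.from_an(980, 1020)
        for k in range(0, 4001, 97):
            sp = proposition_mapping(p, k)
            half = seq_expected_differences(sp.N, sp.k_s) / 2
            expect = expected_breakpoints(p, k)
            assert half == pytest.approx(expect, rel=1e-9, abs=1e-12)

    def test_zero_steps_map_to_zero(self):
        sp = proposition_mapping(ModelParams.from_an(10, 12), 0)
        assert sp.k_s == 0.0

    def test_approximations(self):
        for a, n in [(490, 510), (980, 1020), (4900, 5100)]:
            sp = proposition_mapping(ModelParams.from_an(a, n), 100)
            assert sp.N == pytest.approx(4 * a, rel=1e-3)
            assert sp.k_s == pytest.approx(4 * 100 * a / n, rel=0.02)

    def test_a_zero_rejected(self):
        with pytest.raises(ValueError):
            proposition_mapping(ModelParams.from_an(0, 5), 1)


class TestTranspositionWalkSeries:
    def test_n2_printed_series_is_the_distance(self):
        # the verbatim series alternates 0,1,0,1..., i.e. n - cycles
        assert [eh_formula(2, k, exact=True) for k in range(6)] == [0, 1, 0, 1, 0, 1]
        assert [eh_expected_cycles(2, k, exact=True) for k in range(4)] == [2, 1, 2, 1]

    def test_n2_coefficient_values(self):
        ((a11, base),) = eh_coefficients(2)
        assert a11 == Fraction(-1, 2)
        assert base == Fraction(-1)

    def test_zero_steps_give_n_cycles(self):
        for n in (2, 5, 17, 60):
            assert eh_expected_cycles(n, 0, exact=(n < 10)) == pytest.approx(n)

    def test_matches_partition_chain_oracle(self):
        for n in (4, 6, 8):
            for k in (1, 3, 7, 15):
                exact = exact_transposition_cycle_expectation(n, k)
                assert float(eh_expected_cycles(n, k, exact=True)) == pytest.approx(
                    float(exact), rel=1e-12
                )

    def test_distance_and_cycles_are_complementary(self):
        for n, k in [(10, 5), (40, 30), (80, 100)]:
            assert eh_formula(n, k) + eh_expected_cycles(n, k) == pytest.approx(n)

    def test_table_consistent_with_pointwise(self):
        table = eh_expected_cycles_table(30, 25)
        for k in (0, 7, 25):
            assert table[k] == pytest.approx(eh_expected_cycles(30, k), rel=1e-9)

    def test_insufficient_precision_raises_not_garbage(self):
        with pytest.raises(PrecisionError):
            eh_formula(120, 3, dps=12)


class TestRandomGraphSeries:
    def test_small_k_limit_is_n(self):
        assert bd_expected_components(200, 0) == 200.0
        assert bd_expected_components(200, 1e-9) == pytest.approx(200.0)

    def test_monotone_non_increasing_in_k(self):
        vals = [bd_expected_components(150, k) for k in range(0, 600, 5)]
        assert all(b <= a + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_subcritical_closed_form_is_n_minus_k(self):
        # the tree-count series telescopes to n - k for 2k <= n
        for n, k in [(200, 20), (200, 50), (1000, 400)]:
            assert bd_expected_components(n, k) == pytest.approx(n - k, rel=1e-9)

    def test_within_o_sqrt_n_of_transposition_walk(self):
        for n in (50, 100, 200):
            worst = max(
                abs(bd_expected_components(n, k) - eh_expected_cycles(n, k))
                for k in range(1, 2 * n, max(1, n // 8))
            )
            assert worst <= 0.75 * math.sqrt(n)
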
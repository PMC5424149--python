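"""Audic-Claverie test, significance filter and direction-bias binomial.

The exact oracle evaluates the posterior tail sums in integer/rational
arithmetic: with equal totals p(y|x) = C(x+y, y) / 2^(x+y+1), and in general
p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)) with r = N2/N1 held as a
Fraction. scipy's negative-binomial distribution provides a second,
independent route to the same tails.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import nbinom

from irtools.differential_ir import (
    ACTestInput,
    audic_claverie_p,
    audic_claverie_tails,
    differential_filter,
    direction_bias_test,
    run_differential,
)
from irtools.ir_quant import IRQuant


def exact_lower_tail_equal_totals(x: int, y: int) -> Fraction:
    """P(Y <= y | x) with N1 == N2, exact: sum_j C(x+j, j) 2^(y-j) / 2^(x+y+1)."""
    num = 0
    comb = 1  # C(x+j, j) built incrementally
    for j in range(y + 1):
        if j > 0:
            comb = comb * (x + j) // j
        num += comb * (1 << (y - j))
    return Fraction(num, 1 << (x + y + 1))


def exact_tails_general(x: int, y: int, n1: int, n2: int) -> tuple[Fraction, Fraction]:
    r = Fraction(n2, n1)
    lower = Fraction(0)
    for j in range(y + 1):
        term = (
            r**j
            * math.comb(x + j, j)
            / (1 + r) ** (x + j + 1)
        )
        lower += term
    upper = 1 - (lower - r**y * math.comb(x + y, y) / (1 + r) ** (x + y + 1))
    return lower, upper


class TestAudicClaverie:
    def test_zero_zero_equal_totals(self):
        lower, upper = audic_claverie_tails(0, 0)
        assert lower == pytest.approx(0.5)
        assert upper == pytest.approx(1.0)
        assert audic_claverie_p(0, 0) == 1.0

    def test_zero_vs_twenty_closed_form(self):
        # p(y|0) = 2^-(y+1) with equal totals, so P(Y >= 20 | 0) = 2^-20
        _, upper = audic_claverie_tails(0, 20)
        assert upper == pytest.approx(2.0**-20, rel=1e-9)
        assert audic_claverie_p(0, 20) == pytest.approx(2.0**-19, rel=1e-9)

    def test_symmetry_under_sample_exchange(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = int(rng.integers(0, 300)), int(rng.integers(0, 300))
            n1, n2 = float(rng.uniform(50, 500)), float(rng.uniform(50, 500))
            assert audic_claverie_p(x, y, n1, n2) == pytest.approx(
                audic_claverie_p(y, x, n2, n1), rel=1e-9, abs=1e-12
            )

    def test_matches_exact_oracle_equal_totals(self):
        for x in range(0, 101, 7):
            for y in range(0, 101, 7):
                lower, upper = audic_claverie_tails(x, y)
                want = exact_lower_tail_equal_totals(x, y)
                assert lower == pytest.approx(float(want), abs=1e-9)
                want_up = 1 - (want - Fraction(math.comb(x + y, y), 1 << (x + y + 1)))
                assert upper == pytest.approx(float(want_up), abs=1e-9)

    def test_matches_fraction_oracle_unequal_totals(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x, y = int(rng.integers(0, 80)), int(rng.integers(0, 80))
            n1, n2 = int(rng.integers(10, 400)), int(rng.integers(10, 400))
            lower, upper = audic_claverie_tails(x, y, n1, n2)
            elo, eup = exact_tails_general(x, y, n1, n2)
            assert lower == pytest.approx(float(elo), abs=1e-9)
            assert upper == pytest.approx(float(eup), abs=1e-9)

    def test_posterior_is_negative_binomial(self):
        """Y | x ~ NB(x+1, N1/(N1+N2)): an independent scipy route."""
        for x, n1, n2 in [(0, 1, 1), (17, 120, 80), (60, 33, 99)]:
            pnb = n1 / (n1 + n2)
            for y in (0, 5, 40):
                lower, upper = audic_claverie_tails(x, y, n1, n2)
                assert lower == pytest.approx(nbinom.cdf(y, x + 1, pnb), abs=1e-10)
                assert upper == pytest.approx(nbinom.sf(y - 1, x + 1, pnb), abs=1e-10)

    def test_normalization_sums_to_one(self):
        for x in (0, 3, 50, 200):
            ys = np.arange(0, 20 * (x + 2))
            pnb = 0.5
            lower, _ = audic_claverie_tails(x, int(ys[-1]))
            assert lower == pytest.approx(1.0, abs=1e-9)

    def test_large_counts_no_overflow(self):
        p = audic_claverie_p(10**6, 10**6 + 5000, 2e6, 2e6)
        assert 0.0 < p <= 1.0 and np.isfinite(p)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            ACTestInput(-1, 0)

    def test_type_one_error_controlled_on_null(self):
        """Equal true IR in both samples: rejection fraction at alpha=0.05
        stays below 0.075 over 2000 simulated introns."""
        rng = np.random.default_rng(7)
        n, rej = 2000, 0
        for _ in range(n):
            lam_i = rng.uniform(5, 80)
            lam_s = rng.uniform(20, 200)
            x, y = int(rng.poisson(lam_i)), int(rng.poisson(lam_i))
            s1, s2 = int(rng.poisson(lam_s)), int(rng.poisson(lam_s))
            rej += audic_claverie_p(x, y, max(x + s1, 1), max(y + s2, 1)) < 0.05
        assert rej / n <= 0.075


def _quant(intron_id="i", splice=50, intronic=10.0, sample="s"):
    ratio = intronic / (intronic + splice) if intronic + splice else None
    return IRQuant(intron_id, sample, splice, splice, splice, splice, intronic, 100,
                   ratio, None if ratio is None else ratio >= 0.1)


class TestDifferentialFilter:
    def test_all_three_criteria_met(self):
        q1 = _quant(splice=11, intronic=11 * 0.05 / 0.95)  # ratio ~0.05
        q2 = _quant(splice=12, intronic=12 * 0.15 / 0.85)  # ratio ~0.15
        res = differential_filter(q1, q2, p_value=0.04)
        assert res.passes_filter and res.direction == "increased"

    def test_splice_floor_is_strict(self):
        q1, q2 = _quant(splice=9, intronic=5), _quant(splice=50, intronic=20)
        res = differential_filter(q1, q2, p_value=0.04)
        assert not res.pass_splice and not res.passes_filter

    def test_splice_exactly_ten_fails(self):
        q1, q2 = _quant(splice=10, intronic=5), _quant(splice=50, intronic=20)
        assert not differential_filter(q1, q2, p_value=0.01).pass_splice

    def test_p_boundary(self):
        q1, q2 = _quant(splice=20, intronic=5), _quant(splice=20, intronic=20)
        assert not differential_filter(q1, q2, p_value=0.06).pass_p
        assert not differential_filter(q1, q2, p_value=0.05).pass_p
        assert differential_filter(q1, q2, p_value=0.049).pass_p

    def test_ir_floor_needs_one_sample_above(self):
        q1 = _quant(splice=90, intronic=10)  # ratio 0.1 exactly: not above
        q2 = _quant(splice=90, intronic=10)
        assert not differential_filter(q1, q2, p_value=0.01).pass_ir
        q3 = _quant(splice=80, intronic=20)  # 0.2
        assert differential_filter(q1, q3, p_value=0.01).pass_ir

    def test_fold_change_uses_epsilon(self):
        q1 = _quant(splice=100, intronic=0)  # ratio 0
        q2 = _quant(splice=50, intronic=50)  # ratio 0.5
        res = differential_filter(q1, q2, p_value=0.01)
        assert res.fold_change == pytest.approx(0.51 / 0.01)

    def test_not_assessable_is_error(self):
        bad = _quant(splice=0, intronic=0.0)
        with pytest.raises(ValueError):
            differential_filter(bad, _quant(), p_value=0.5)


class TestDirectionBias:
    def test_fifteen_five_split(self):
        one_sided = 21700 / 2**20
        assert direction_bias_test(15, 5) == pytest.approx(2 * one_sided)
        assert direction_bias_test(15, 5) < 0.05

    def test_even_split_is_one(self):
        assert direction_bias_test(10, 10) == 1.0

    def test_total_sweep(self):
        assert direction_bias_test(20, 0) == pytest.approx(2 * 2.0**-20)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            direction_bias_test(0, 0)


class TestRunDifferential:
    def test_skips_not_assessable_and_summarizes(self):
        q1 = [_quant("a", 50, 30), _quant("b", 0, 0.0)]
        q2 = [_quant("a", 50, 5, "t"), _quant("b", 0, 0.0, "t")]
        table, summary = run_differential(q1, q2)
        assert summary["n_tested"] == 1 and summary["n_skipped"] == 1

    def test_bh_flag_adds_q_values(self):
        q1 = [_quant(f"i{k}", 50, 30) for k in range(5)]
        q2 = [_quant(f"i{k}", 50, 5, "t") for k in range(5)]
        table, _ = run_differential(q1, q2, bh_correct=True)
        assert "q_value" in table.columns
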
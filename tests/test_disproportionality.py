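"""Contingency construction, the four estimators, and ranking."""

import math

import numpy as np
import pytest
import sympy
from scipy.stats import chi2_contingency

from helpers import make_report
from pvsignal.disproportionality import (
    BcpnnPriors,
    ContingencyTable,
    build_contingency,
    compute_bcpnn,
    compute_ebgm,
    compute_prr_chi2,
    compute_ror,
    pair_count_frame,
    rank_frequency,
    rank_strength,
    reconstruct_from_stats,
    score_all,
    score_table,
)


def random_tables(seed, n, low=1):
    rng = np.random.default_rng(seed)
    return [
        ContingencyTable(
            a=int(rng.integers(low, 50)),
            b=int(rng.integers(low, 2000)),
            c=int(rng.integers(low, 5000)),
            d=int(rng.integers(1000, 100_000)),
        )
        for _ in range(n)
    ]


class TestBuildContingency:
    def test_hand_enumerated_cells(self):
        cohort = [make_report(1, ["X"]), make_report(2, ["X", "Y"])]
        background = [make_report(3, ["Y"])]
        t = build_contingency(cohort, background, "X")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 0, 1)

    def test_absent_pt_gives_zero_a(self):
        cohort = [make_report(1, ["X"])]
        t = build_contingency(cohort, [make_report(2, ["Z"])], "Q")
        assert t.a == 0

    def test_duplicate_pt_within_report_counts_once(self):
        cohort = [make_report(1, ["X", "X", "Y"])]
        t = build_contingency(cohort, [make_report(2, ["Z"])], "X")
        assert (t.a, t.b) == (1, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_recount_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        vocab = [f"pt{i}" for i in range(12)]
        def draw(n0):
            return [make_report(i + n0, rng.choice(
                vocab, size=rng.integers(1, 5), replace=True).tolist())
                for i in range(rng.integers(5, 50))]
        cohort, background = draw(0), draw(1000)
        frame = pair_count_frame([r.reactions for r in cohort],
                                 [r.reactions for r in background])
        for pt in vocab:
            # direct double loop over reports x PTs
            a = sum(pt in r.reactions for r in cohort)
            b = sum(len(set(r.reactions)) - (pt in r.reactions) for r in cohort)
            c = sum(pt in r.reactions for r in background)
            d = sum(len(set(r.reactions)) - (pt in r.reactions)
                    for r in background)
            t = build_contingency(cohort, background, pt)
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
            if pt in frame.index:
                assert tuple(frame.loc[pt]) == (a, c, b, d) or \
                    tuple(frame.loc[pt, ["a", "b", "c", "d"]]) == (a, b, c, d)


class TestRor:
    def test_independence_no_signal(self):
        ror, lo, hi, _, flag = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert ror == 1.0 and lo < 1.0 < hi and not flag

    def test_closed_form_example(self):
        ror, lo, hi, se, flag = compute_ror(ContingencyTable(5, 10, 20, 1000))
        assert ror == pytest.approx(25.0)
        assert se == pytest.approx(0.5925, abs=1e-4)
        assert lo == pytest.approx(7.83, abs=0.01)
        assert hi == pytest.approx(79.85, abs=0.01)
        assert flag

    def test_minimum_count_rule(self):
        ror, lo, _, _, flag = compute_ror(ContingencyTable(2, 1, 10, 1000))
        assert lo > 1.0 and not flag  # strong ratio but a < 3

    def test_zero_cell_reports_infinite_without_signal(self):
        ror, *_, flag = compute_ror(ContingencyTable(5, 0, 20, 1000))
        assert math.isinf(ror) and not flag


class TestPrrChi2:
    def test_closed_form_example(self):
        prr, lo, hi, chi2, prr_flag, mhra_flag = compute_prr_chi2(
            ContingencyTable(5, 10, 20, 1000))
        assert prr == pytest.approx(17.0)
        assert chi2 == pytest.approx(61.73, abs=0.01)
        assert prr_flag and mhra_flag

    def test_independence(self):
        prr, _, _, chi2, *_ = compute_prr_chi2(ContingencyTable(1, 2, 3, 6))
        assert prr == pytest.approx(1.0) and chi2 == pytest.approx(0.0)

    def test_boundary_prr_exactly_two(self):
        # PRR == 2 satisfies the >=2 criterion but not the strict > 2 one
        prr, lo, _, chi2, prr_flag, mhra_flag = compute_prr_chi2(
            ContingencyTable(400, 400, 1000, 3000))
        assert prr == pytest.approx(2.0)
        assert lo >= 1.0 and chi2 >= 4.0
        assert prr_flag and not mhra_flag

    @pytest.mark.parametrize("t", random_tables(7, 25))
    def test_chi2_equals_expected_counts_pearson_oracle(self, t):
        observed = np.array([[t.a, t.b], [t.c, t.d]])
        expected = chi2_contingency(observed, correction=False).statistic
        assert compute_prr_chi2(t)[3] == pytest.approx(expected, rel=1e-9)


def sympy_bcpnn(t, priors=BcpnnPriors()):
    """Arbitrary-precision oracle for E(IC), V(IC) and IC-2SD."""
    a, b, c, d = (sympy.Integer(x) for x in (t.a, t.b, t.c, t.d))
    al, be = sympy.Rational(priors.alpha), sympy.Rational(priors.beta)
    a1, b1 = sympy.Rational(priors.alpha1), sympy.Rational(priors.beta1)
    g11 = sympy.Rational(priors.gamma11)
    n = a + b + c + d
    g = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    e_ic = sympy.log((a + g11) * (n + al) * (n + be)
                     / ((n + g) * (a + b + a1) * (a + c + b1)), 2)
    v_ic = ((n - a + g - g11) / ((a + g11) * (1 + n + g))
            + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
            + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be))
            ) / sympy.log(2) ** 2
    ic2sd = e_ic - 2 * sympy.sqrt(v_ic)
    return (float(e_ic.evalf(30)), float(v_ic.evalf(30)),
            float(ic2sd.evalf(30)))


class TestBcpnn:
    def test_perfect_independence_ic_zero(self):
        ic, *_ = compute_bcpnn(ContingencyTable(10, 10, 10, 10))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_derived_example_with_default_priors(self):
        ic, e_ic, v_ic, ic2sd, flag = compute_bcpnn(
            ContingencyTable(5, 10, 20, 1000))
        assert e_ic == pytest.approx(2.099, abs=1e-3)
        assert v_ic == pytest.approx(0.552, abs=1e-3)
        assert ic2sd == pytest.approx(0.613, abs=1e-3)
        assert flag

    def test_zero_a_is_negative_and_unflagged(self):
        *_, ic2sd, flag = compute_bcpnn(ContingencyTable(0, 500, 500, 50_000))
        assert ic2sd < 0 and not flag

    def test_matches_arbitrary_precision_oracle_on_100_tables(self):
        for t in random_tables(13, 100, low=0):
            if t.n == 0:
                continue
            _, e_ic, v_ic, ic2sd, _ = compute_bcpnn(t)
            oe, ov, oi = sympy_bcpnn(t)
            assert e_ic == pytest.approx(oe, rel=1e-10, abs=1e-10)
            assert v_ic == pytest.approx(ov, rel=1e-10)
            assert ic2sd == pytest.approx(oi, rel=1e-10, abs=1e-10)


class TestEbgm:
    def test_closed_form_example(self):
        ebgm, eb05, eb95, flag = compute_ebgm(ContingencyTable(5, 10, 20, 1000))
        assert ebgm == pytest.approx(13.8)
        assert eb05 == pytest.approx(4.32, abs=0.01)
        assert flag

    def test_equal_margins_give_unity(self):
        ebgm, _, _, flag = compute_ebgm(ContingencyTable(10, 10, 10, 10))
        assert ebgm == pytest.approx(1.0) and not flag

    def test_flag_is_inclusive_at_threshold(self):
        for t in random_tables(17, 40):
            ebgm, eb05, _, flag = compute_ebgm(t)
            assert flag == (eb05 >= 2.0)


class TestTableInvariants:
    @pytest.mark.parametrize("t", random_tables(23, 40))
    def test_geometric_mean_ci_identities(self, t):
        s = score_table("x", t)
        assert math.sqrt(s.ror_lo * s.ror_hi) == pytest.approx(s.ror, rel=1e-9)
        assert math.sqrt(s.prr_lo * s.prr_hi) == pytest.approx(s.prr, rel=1e-9)
        assert math.sqrt(s.eb05 * s.eb95) == pytest.approx(s.ebgm, rel=1e-9)
        assert s.eb05 < s.ebgm < s.eb95

    def test_independence_limit_all_statistics(self):
        # ad = bc with equal margins
        s = score_table("x", ContingencyTable(20, 20, 20, 20))
        assert s.ror == pytest.approx(1.0)
        assert s.prr == pytest.approx(1.0)
        assert s.chi2 == pytest.approx(0.0, abs=1e-12)
        assert s.ic == pytest.approx(0.0, abs=1e-12)
        assert s.ebgm == pytest.approx(1.0)
        assert not any(s.flags.values())

    def test_ror_and_prr_strictly_increase_in_a(self):
        b, c, d = 50, 200, 10_000
        rors = [compute_ror(ContingencyTable(a, b, c, d))[0]
                for a in range(1, 30)]
        prrs = [compute_prr_chi2(ContingencyTable(a, b, c, d))[0]
                for a in range(1, 30)]
        assert all(x < y for x, y in zip(rors, rors[1:]))
        assert all(x < y for x, y in zip(prrs, prrs[1:]))


class TestScoreAllAndRanking:
    def _scores(self):
        cohort = (
            [make_report(i, ["anemia", "nausea"]) for i in range(8)]
            + [make_report(100 + i, ["neutropenia"]) for i in range(8)]
            + [make_report(200 + i, ["fatigue"]) for i in range(3)]
        )
        background = [make_report(1000 + i, ["nausea", "fatigue"])
                      for i in range(300)] + \
                     [make_report(2000 + i, ["anemia"]) for i in range(2)] + \
                     [make_report(3000 + i, ["neutropenia"]) for i in range(2)]
        return score_all(cohort, background)

    def test_ordering_by_count_then_name(self):
        scores = self._scores()
        keys = [(-s.a, s.pt) for s in scores]
        assert keys == sorted(keys)

    def test_empty_pt_list_empty_result(self):
        assert score_all([make_report(1, ["anemia"])],
                         [make_report(2, ["nausea"])], pts=[]) == []

    def test_no_disproportion_no_flags(self):
        # identical composition in cohort and background
        cohort = [make_report(i, ["anemia", "nausea"]) for i in range(50)]
        background = [make_report(1000 + i, ["anemia", "nausea"])
                      for i in range(500)]
        for s in score_all(cohort, background):
            assert not any(s.flags.values())

    def test_rank_frequency_orders_by_count_with_alpha_ties(self):
        scores = self._scores()
        table = rank_frequency(scores, 30)
        assert list(table["PT"])[:2] == ["anemia", "neutropenia"]
        assert rank_frequency(scores, 0).empty

    def test_rank_strength_orders_by_ror(self):
        scores = self._scores()
        table = rank_strength(scores, 20)
        rors = [float(v.split(" ")[0]) for v in table["ROR (95%CI)"]]
        assert rors == sorted(rors, reverse=True)

    def test_ranking_invariant_to_input_order(self):
        scores = self._scores()
        rng = np.random.default_rng(2)
        shuffled = [scores[i] for i in rng.permutation(len(scores))]
        assert rank_strength(scores, 10).equals(rank_strength(shuffled, 10))


class TestReconstruction:
    @pytest.mark.parametrize("cells", [
        (25, 900, 4000, 2_000_000),
        (60, 1500, 30_000, 9_000_000),
        (8, 1200, 90, 4_000_000),
    ])
    def test_round_trip_from_rounded_statistics(self, cells):
        t0 = ContingencyTable(*cells)
        s = score_table("x", t0)
        t = reconstruct_from_stats(
            a=t0.a,
            ror=round(s.ror, 2), ror_lo=round(s.ror_lo, 2),
            ror_hi=round(s.ror_hi, 2), prr=round(s.prr, 2),
            chi2=round(s.chi2, 2))
        back = score_table("x", t)
        # the reconstructed table must reproduce every input statistic at
        # its printed precision
        assert round(back.ror, 2) == round(s.ror, 2)
        assert round(back.prr, 2) == round(s.prr, 2)
        assert back.chi2 == pytest.approx(s.chi2, rel=2e-3)
        assert back.eb05 == pytest.approx(s.eb05, rel=2e-3)
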
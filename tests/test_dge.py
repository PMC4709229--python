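import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from dgepipe.dge import ac_pmf, ac_two_sided_pvalue, bh_fdr, call_degs
from dgepipe.quantification import CountTable

from conftest import ac_pvalue_exact


class TestAcPmf:
    @pytest.mark.parametrize(
        "i, x, n1, n2, expected",
        [
            (0, 0, 10**6, 10**6, Fraction(1, 2)),
            (1, 2, 10**6, 10**6, Fraction(3, 16)),
            (1, 0, 10**6, 2 * 10**6, Fraction(2, 9)),
        ],
    )
    def test_rational_oracle_values(self, i, x, n1, n2, expected):
        assert ac_pmf(i, x, n1, n2) == pytest.approx(float(expected), abs=1e-14)

    @pytest.mark.parametrize("x", [0, 3, 17, 50])
    @pytest.mark.parametrize("n1, n2", [(10**6, 10**6), (10**6, 3 * 10**6)])
    def test_exact_against_rational_arithmetic(self, x, n1, n2):
        """>= 12 significant digits against Fraction arithmetic for x+i <= 50."""
        r = Fraction(n2, n1)
        for i in range(0, 51 - x):
            exact = Fraction(
                math.factorial(x + i),
                math.factorial(x) * math.factorial(i),
            ) * r**i / (1 + r) ** (x + i + 1)
            assert ac_pmf(i, x, n1, n2) == pytest.approx(
                float(exact), rel=1e-12
            )

    def test_matches_negative_binomial_form(self):
        """p(i|x) is NB(r=x+1, p=N1/(N1+N2)) evaluated at i."""
        n1, n2 = 2_000_000, 3_000_000
        for x in (0, 4, 40):
            i = np.arange(0, 60)
            ours = np.array([ac_pmf(int(k), x, n1, n2) for k in i])
            ref = nbinom.pmf(i, x + 1, n1 / (n1 + n2))
            np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_normalisation(self):
        for x, n1, n2 in [(0, 10, 10), (25, 10**6, 5 * 10**5)]:
            total = sum(ac_pmf(i, x, n1, n2) for i in range(2000))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ac_pmf(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            ac_pmf(0, 0, 0, 10)


class TestTwoSidedPvalue:
    def test_symmetric_null_point_is_one(self):
        assert ac_two_sided_pvalue(0, 0, 10**6, 10**6) == 1.0

    def test_brute_force_oracle_x5_y15(self):
        expected = float(ac_pvalue_exact(5, 15, Fraction(1)))
        assert ac_two_sided_pvalue(5, 15, 10**6, 10**6) == pytest.approx(
            expected, abs=1e-10
        )

    def test_equal_large_counts_near_one(self):
        assert ac_two_sided_pvalue(100, 100, 10**6, 10**6) > 0.9

    @pytest.mark.parametrize("ratio", [Fraction(1), Fraction(2), Fraction(1, 2)])
    def test_oracle_grid(self, ratio):
        """Spot grid against the rational brute-force oracle (full grid in acceptance)."""
        n1 = 10**6
        n2 = int(n1 * ratio)
        for x in (0, 1, 7, 30):
            for y in (0, 2, 15, 30):
                expected = float(ac_pvalue_exact(x, y, ratio))
                got = ac_two_sided_pvalue(x, y, n1, n2)
                assert got == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x=st.integers(0, 500),
        y=st.integers(0, 500),
        n1=st.integers(1000, 10**7),
        n2=st.integers(1000, 10**7),
    )
    def test_symmetry_and_range(self, x, y, n1, n2):
        p = ac_two_sided_pvalue(x, y, n1, n2)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(ac_two_sided_pvalue(y, x, n2, n1), abs=1e-10)


class TestBhFdr:
    def test_hand_stepup_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.8], rtol=1e-12)

    def test_constant_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
        np.testing.assert_allclose(bh_fdr([0.123]), [0.123])

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, float("nan")])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_q_dominates_p_and_is_monotone(self, p):
        q = bh_fdr(p)
        assert ((q >= np.asarray(p) - 1e-15) & (q <= 1.0)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDegs:
    def _table(self, rows):
        frame = pd.DataFrame(
            rows, columns=["gene_id", "length", "count_lib1", "count_lib2"]
        )
        for c in ("length", "count_lib1", "count_lib2"):
            frame[c] = frame[c].astype(np.int64)
        return CountTable(frame, n1=10**6, n2=10**6)

    def test_threshold_rule(self):
        """Both conditions (FDR and |log2 ratio| >= 1) are required for a call."""
        # strong count contrast, ratio 4 -> up; ratio ~1.3 -> significant p
        # but not enough fold change -> not_significant
        table = self._table(
            [
                ("gBig", 1000, 4000, 1000),
                ("gSmallRatio", 1000, 130000, 100000),
                ("gNull", 1000, 50, 50),
            ]
        )
        res = call_degs(table).set_index("gene_id")
        assert res.loc["gBig", "call"] == "up"
        assert res.loc["gBig", "fdr"] <= 0.001
        assert res.loc["gSmallRatio", "fdr"] <= 0.001
        assert res.loc["gSmallRatio", "call"] == "not_significant"
        assert res.loc["gNull", "call"] == "not_significant"

    def test_down_call_mirrors_up(self):
        table = self._table([("gB", 500, 1000, 4000), ("gN", 500, 50, 50)])
        res = call_degs(table).set_index("gene_id")
        assert res.loc["gB", "call"] == "down"
        assert res.loc["gB", "log2_ratio"] == pytest.approx(-2.0)

    def test_zero_handling(self):
        table = self._table(
            [("gOne", 500, 0, 200), ("gBoth", 500, 0, 0), ("gN", 500, 10, 10)]
        )
        res = call_degs(table).set_index("gene_id")
        assert res.loc["gOne", "zero_flag"] == "pseudocount"
        assert res.loc["gOne", "call"] == "down"
        assert res.loc["gBoth", "zero_flag"] == "both_zero"
        assert res.loc["gBoth", "call"] == "not_significant"
        assert np.isnan(res.loc["gBoth", "log2_ratio"])
        # p-value for the both-zero gene is still the exact-test value 1.0
        assert res.loc["gBoth", "p_value"] == 1.0

    def test_fdr_dominates_p_and_output_is_sorted(self, rng):
        from conftest import random_count_table

        res = call_degs(random_count_table(rng, 100))
        assert (res["fdr"] >= res["p_value"] - 1e-15).all()
        key = list(zip(res["fdr"], res["gene_id"]))
        assert key == sorted(key)
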
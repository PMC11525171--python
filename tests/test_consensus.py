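import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varprior.consensus import (
    assign_tiers,
    binomial_consensus,
    majority_consensus,
    percent_rounded,
    percentile_hit_flags,
    sum_scores,
)


class TestMajorityConsensus:
    def test_strict_majority_strong(self):
        values = {f"c{i}": 2 for i in range(4)} | {"c4": 0, "c5": 0}
        cons = majority_consensus(values, "ATAC", "v")
        assert cons.value == 2 and cons.n_supporting == 4 and cons.n_cell_lines == 6

    def test_half_is_not_majority(self):
        values = {"a": 2, "b": 2, "c": 2, "d": 0, "e": 0, "f": 0}
        assert majority_consensus(values, "ATAC", "v").value == 0

    def test_level_wise_weak_consensus(self):
        # 2 strong + 3 weak of 6: >=2 count is 2 (no), >=1 count is 5 (yes)
        values = {"a": 2, "b": 2, "c": 1, "d": 1, "e": 1, "f": 0}
        cons = majority_consensus(values, "CHROMHMM", "v")
        assert cons.value == 1 and cons.n_supporting == 5

    def test_empty_denominator(self):
        assert majority_consensus({}, "ATAC", "v").value == 0

    @given(
        scores=st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=8),
    )
    def test_permutation_invariant_and_zero_line_never_raises(self, scores):
        base = {f"c{i}": s for i, s in enumerate(scores)}
        shuffled = {f"c{i}": s for i, s in enumerate(reversed(scores))}
        v0 = majority_consensus(base, "ATAC", "v").value
        assert v0 == majority_consensus(shuffled, "ATAC", "v").value
        with_zero = dict(base) | {"extra": 0}
        assert majority_consensus(with_zero, "ATAC", "v").value <= v0


def binomial_tail_oracle(n, k, p0=0.10):
    """Exact enumeration of P(X >= k) for X ~ Binomial(n, p0)."""
    return sum(
        math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
    )


class TestBinomialConsensus:
    def test_n6_k3_is_hit(self):
        # P = 0.01585 -> 1
        flags = [True] * 3 + [False] * 3
        assert binomial_consensus(flags) == 1
        assert abs(binomial_tail_oracle(6, 3) - 0.01585) < 5e-5

    def test_n6_k4_is_strong(self):
        # P = 0.00127 -> 2
        assert binomial_consensus([True] * 4 + [False] * 2) == 2
        assert abs(binomial_tail_oracle(6, 4) - 0.00127) < 5e-6

    def test_n6_k1_is_nothing(self):
        # P = 0.4686 -> 0
        assert binomial_consensus([True] + [False] * 5) == 0
        assert abs(binomial_tail_oracle(6, 1) - 0.4686) < 5e-5

    def test_k0_short_circuits(self):
        assert binomial_consensus([False] * 6) == 0

    def test_n0(self):
        assert binomial_consensus([]) == 0

    def test_matches_enumeration_oracle_exhaustively(self):
        for n in range(1, 9):
            for k in range(0, n + 1):
                flags = [True] * k + [False] * (n - k)
                got = binomial_consensus(flags)
                if k == 0:
                    assert got == 0
                    continue
                p = binomial_tail_oracle(n, k)
                expected = 2 if p < 0.01 else 1 if p < 0.05 else 0
                assert got == expected, (n, k, p)


class TestPercentileHitFlags:
    def _table(self, scores):
        return pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(len(scores))], "score": scores}
        )

    def test_boundary_inclusive(self):
        df = self._table(list(range(10)))  # q90 of 0..9 = 8.1
        flags = percentile_hit_flags({"c": df})
        assert flags[("v9", "c")] and not flags[("v8", "c")]
        df2 = self._table([1.0] * 5 + [8.1] * 5)
        # exact equality with the quantile value counts as a hit
        flags2 = percentile_hit_flags({"c": df2})
        assert flags2[("v9", "c")]

    def test_degenerate_distribution_flags_everything(self):
        flags = percentile_hit_flags({"c": self._table([3.0] * 7)})
        assert all(flags.values())

    def test_absent_cell_line_excluded(self):
        flags = percentile_hit_flags({"c1": self._table([1, 2, 3]), "c2": pd.DataFrame(columns=["variant_id", "score"])})
        assert not any(cl == "c2" for _, cl in flags)

    def test_best_score_per_variant(self):
        df = pd.DataFrame(
            {"variant_id": ["a"] * 2 + ["b"] * 8, "score": [0.0, 9.0] + [1.0] * 8}
        )
        flags = percentile_hit_flags({"c": df})
        assert flags[("a", "c")]


class TestSumScores:
    def test_example(self):
        terms = {"MPRA:c1": 2, "MPRA:c2": 1, "MPRA:c3": 0, "FINEMAP": 2, "ATAC": 2}
        assert sum_scores(terms) == 7

    def test_all_zero(self):
        assert sum_scores({"FINEMAP": 0, "ATAC": 0}) == 0

    def test_upper_bound_with_three_mpra_lines(self):
        terms = {f"MPRA:c{i}": 2 for i in range(3)}
        for t in ("FINEMAP", "CHROMHMM", "ATAC", "SMR_NORMAL", "SMR_TUMOR",
                  "AKITA", "CTCF", "MICROC", "ABC"):
            terms[t] = 2
        assert sum_scores(terms) == 2 * (3 + 9)


class TestAssignTiers:
    def test_distinct_scores_exact_split(self):
        totals = [(f"v{i}", float(i)) for i in range(10)]
        tiers = assign_tiers(totals)
        counts = {t: sum(1 for x in tiers if x.tier == t) for t in (1, 2, 3)}
        assert counts == {1: 2, 2: 3, 3: 5}
        by_id = {t.variant_id: t.tier for t in tiers}
        assert by_id["v9"] == 1 and by_id["v8"] == 1 and by_id["v0"] == 3

    def test_all_tied_promotes_everyone(self):
        tiers = assign_tiers([(f"v{i}", 5.0) for i in range(10)])
        assert all(t.tier == 1 for t in tiers)

    def test_single_variant_is_tier1(self):
        (t,) = assign_tiers([("v", 0.0)])
        assert t.tier == 1 and t.rank_percentile == 1.0

    def test_empty(self):
        assert assign_tiers([]) == []

    def test_boundary_tie_promotion(self):
        # scores: 9, 5, 5, 5, 1, 1, 1, 1, 1, 0 — the 5s straddle the Tier 1
        # boundary (ceil(0.2*10)=2) so all of them become Tier 1
        totals = [("a", 9.0)] + [(f"b{i}", 5.0) for i in range(3)] + [
            (f"c{i}", 1.0) for i in range(5)
        ] + [("d", 0.0)]
        by_id = {t.variant_id: t.tier for t in assign_tiers(totals)}
        assert by_id["a"] == 1
        assert all(by_id[f"b{i}"] == 1 for i in range(3))
        assert by_id["d"] == 3

    @given(
        scores=st.lists(
            st.integers(min_value=0, max_value=20), min_size=1, max_size=60
        )
    )
    @settings(max_examples=300)
    def test_invariants(self, scores):
        totals = [(f"v{i}", float(s)) for i, s in enumerate(scores)]
        tiers = assign_tiers(totals)
        n = len(totals)
        # monotone: higher score never gets a worse tier
        by_score = sorted(tiers, key=lambda t: -t.total_score)
        for a, b in zip(by_score, by_score[1:]):
            assert a.tier <= b.tier
        n1 = sum(1 for t in tiers if t.tier == 1)
        n3 = sum(1 for t in tiers if t.tier == 3)
        assert n1 >= math.ceil(0.2 * n)
        assert n3 <= math.floor(0.5 * n)
        # the excess over the exact quantile is entirely tie-driven
        boundary_score = by_score[math.ceil(0.2 * n) - 1].total_score
        assert all(
            t.total_score >= boundary_score for t in tiers if t.tier == 1
        )

    def test_order_independence(self):
        rng = np.random.default_rng(5)
        totals = [(f"v{i}", float(rng.integers(0, 8))) for i in range(30)]
        a = {t.variant_id: t.tier for t in assign_tiers(totals)}
        shuffled = list(totals)
        rng.shuffle(shuffled)
        b = {t.variant_id: t.tier for t in assign_tiers(shuffled)}
        assert a == b


class TestPercentRounded:
    @pytest.mark.parametrize(
        "num,den,expected", [(40, 170, 24), (98, 170, 58), (82, 170, 48), (1798, 8880, 20)]
    )
    def test_printed_arithmetic(self, num, den, expected):
        assert percent_rounded(num, den) == expected

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent_rounded(1, 0)
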
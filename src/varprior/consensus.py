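"""Cross-cell-line consensus, score summation and tier assignment.

Two consensus rules exist: a strict-majority rule for track-based terms
(ATAC, CTCF, Micro-C, ChromHMM) and a binomial-tail rule for analyses whose
native scores are ranked within each cell line (ABC, TF). Consensus scores
plus the non-cell-line terms are summed per variant, ranked globally and cut
into Tier 1 (top 20%), Tier 3 (bottom 50%) and Tier 2 (the remainder), with
ties across a boundary promoted to the better tier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = [
    "ConsensusScore",
    "TierAssignment",
    "MAJORITY_TERMS",
    "majority_consensus",
    "binomial_consensus",
    "percentile_hit_flags",
    "sum_scores",
    "assign_tiers",
    "percent_rounded",
]

#: Terms collapsed by the strict-majority rule.
MAJORITY_TERMS = ("ATAC", "CTCF", "MICROC", "CHROMHMM")


@dataclass(frozen=True, slots=True)
class ConsensusScore:
    variant_id: str
    term: str
    value: int
    n_cell_lines: int
    n_supporting: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1, 2):
            raise ValidationError(f"consensus value must be 0/1/2, got {self.value}")
        if self.n_supporting > self.n_cell_lines:
            raise ValidationError("n_supporting exceeds n_cell_lines")


@dataclass(frozen=True, slots=True)
class TierAssignment:
    variant_id: str
    total_score: float
    rank_percentile: float
    tier: int

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3):
            raise ValidationError(f"tier must be 1/2/3, got {self.tier}")


def majority_consensus(
    values: Mapping[str, int], term: str, variant_id: str = ""
) -> ConsensusScore:
    """Strict-majority consensus over per-cell-line scores.

    ``values`` maps cell line -> score for the cell lines with data; the
    denominator is its size. A level L in {2, 1} is retained iff strictly
    more than half of the cell lines score >= L; the consensus is the highest
    retained level, else 0. An empty denominator yields 0.
    """
    n = len(values)
    if n == 0:
        return ConsensusScore(variant_id, term, 0, 0, 0)
    for level in (2, 1):
        n_ge = sum(1 for s in values.values() if s >= level)
        if n_ge * 2 > n:
            return ConsensusScore(variant_id, term, level, n, n_ge)
    return ConsensusScore(variant_id, term, 0, n, 0)


def binomial_consensus(
    hit_flags: Iterable[bool], p0: float = 0.10
) -> int:
    """Binomial-tail consensus over per-cell-line top-decile flags.

    With n the number of cell lines carrying data and k the number of flags
    set, the tail probability is P(X >= k) for X ~ Binomial(n, p0). k = 0 is
    short-circuited to 0 without testing (no flags cannot signal enrichment).
    Score 2 iff P < 0.01; 1 iff 0.01 <= P < 0.05; else 0.
    """
    flags = list(hit_flags)
    n = len(flags)
    k = sum(bool(f) for f in flags)
    if n == 0 or k == 0:
        return 0
    p = float(stats.binom.sf(k - 1, n, p0))
    if p < 0.01:
        return 2
    if p < 0.05:
        return 1
    return 0


def percentile_hit_flags(
    scores_by_cell_line: Mapping[str, pd.DataFrame],
    quantile: float = 0.90,
) -> dict[tuple[str, str], bool]:
    """Per-(variant, cell line) flags: best score >= the cell line's q-quantile.

    Each cell line's table must have columns ``variant_id`` and ``score``
    covering all scored items for the analysis in that line; the quantile is
    taken over all of them (not only candidate variants). The flag comparison
    is inclusive, so a degenerate all-equal distribution flags everything.
    Variants absent from a cell line get no flag there (excluded from n).
    """
    flags: dict[tuple[str, str], bool] = {}
    for cell_line, df in scores_by_cell_line.items():
        if df.empty:
            continue
        cutoff = float(np.quantile(df["score"].to_numpy(dtype=float), quantile))
        best = df.groupby("variant_id")["score"].max()
        for variant_id, score in best.items():
            flags[(str(variant_id), cell_line)] = bool(score >= cutoff)
    return flags


def sum_scores(term_values: Mapping[str, int]) -> int:
    """Sum annotation values for one variant.

    Keys are term names; per-cell-line MPRA summands use ``MPRA:<cell_line>``
    keys so each assayed cell line contributes once. Missing terms simply do
    not appear and contribute 0.
    """
    return int(sum(term_values.values()))


def assign_tiers(
    totals: Sequence[tuple[str, float]],
    top_frac: float = 0.20,
    bottom_frac: float = 0.50,
) -> list[TierAssignment]:
    """Rank variants by descending total score and cut into tiers.

    The top ceil(top_frac * N) positions are Tier 1, the bottom
    floor(bottom_frac * N) are Tier 3, the remainder Tier 2. Variants sharing
    a score that straddles a boundary are all promoted to the better tier, so
    tiering is order-independent and monotone non-increasing in score. The
    reported percentile is best-rank / N (ties share their best rank).
    """
    if not totals:
        return []
    n = len(totals)
    order = sorted(totals, key=lambda t: (-t[1], t[0]))
    n_tier1 = math.ceil(top_frac * n)
    n_tier3 = math.floor(bottom_frac * n)
    tier2_end = n - n_tier3  # positions [n_tier1, tier2_end) are Tier 2

    positional = []
    for idx in range(n):
        if idx < n_tier1:
            positional.append(1)
        elif idx < tier2_end:
            positional.append(2)
        else:
            positional.append(3)

    # tie promotion: every score value takes the best positional tier among
    # the positions it occupies
    best_tier_for_score: dict[float, int] = {}
    best_rank_for_score: dict[float, int] = {}
    for idx, (_vid, score) in enumerate(order):
        best_tier_for_score[score] = min(
            best_tier_for_score.get(score, 3), positional[idx]
        )
        best_rank_for_score.setdefault(score, idx + 1)

    out = []
    for vid, score in order:
        out.append(
            TierAssignment(
                variant_id=vid,
                total_score=score,
                rank_percentile=best_rank_for_score[score] / n,
                tier=best_tier_for_score[score],
            )
        )
    return out


def percent_rounded(numerator: float, denominator: float) -> int:
    """Integer-rounded percentage (round-half-away-from-zero, as printed)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
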
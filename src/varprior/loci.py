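"""Risk-locus definition, candidate-variant selection and credible sets.

Loci are defined by greedy distance clumping of genome-wide-significant
variants; candidates for functional testing are chosen by two association
rules evaluated against the lead; credible sets are the ranked-PIP prefix
reaching a coverage target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import Interval, ValidationError, Variant

__all__ = [
    "Locus",
    "FineMapRecord",
    "define_loci",
    "select_candidate_variants",
    "build_credible_set",
    "GENOME_WIDE_P",
    "DEFAULT_MIN_SEPARATION_BP",
    "DEFAULT_WINDOW_BP",
]

GENOME_WIDE_P = 5e-8
DEFAULT_MIN_SEPARATION_BP = 500_000
DEFAULT_WINDOW_BP = 250_000


@dataclass(frozen=True, slots=True)
class FineMapRecord:
    """One fine-mapping posterior: variant id, PIP, optional credible-set id."""

    variant_id: str
    pip: float
    credible_set_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pip <= 1.0):
            raise ValidationError(f"{self.variant_id}: PIP out of [0, 1]: {self.pip}")


@dataclass
class Locus:
    """A risk locus: lead variant, symmetric window and member variants."""

    locus_id: str
    lead: Variant
    window: Interval
    members: list[Variant]


def define_loci(
    stats: Sequence[Variant],
    p_threshold: float = GENOME_WIDE_P,
    min_separation_bp: int = DEFAULT_MIN_SEPARATION_BP,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[Locus]:
    """Greedy distance clumping of significant variants into risk loci.

    Variants with ``gwas_p < p_threshold`` are sorted by ascending P (ties
    broken by chrom, pos, id for determinism) and accepted as leads iff they
    lie at least ``min_separation_bp`` from every previously accepted lead on
    the same chromosome. Each locus window is lead +/- ``window_bp``; every
    input variant within the window of its nearest lead becomes a member
    (regardless of significance — downstream selection filters them).
    """
    qualifying = [v for v in stats if v.gwas_p is not None and v.gwas_p < p_threshold]
    if not qualifying:
        return []
    qualifying.sort(key=lambda v: (v.gwas_p, v.chrom, v.pos, v.id))
    leads: list[Variant] = []
    for v in qualifying:
        if all(
            v.chrom != l.chrom or abs(v.pos - l.pos) >= min_separation_bp for l in leads
        ):
            leads.append(v)
    # deterministic locus ids in genome order
    leads.sort(key=lambda v: (v.chrom, v.pos))

    def nearest_lead(v: Variant) -> Optional[int]:
        best, best_d = None, None
        for i, l in enumerate(leads):
            if v.chrom != l.chrom:
                continue
            d = abs(v.pos - l.pos)
            if d <= window_bp and (best_d is None or d < best_d):
                best, best_d = i, d
        return best

    member_lists: list[list[Variant]] = [[] for _ in leads]
    for v in stats:
        i = nearest_lead(v)
        if i is not None:
            member_lists[i].append(v)

    loci: list[Locus] = []
    for i, lead in enumerate(leads):
        locus_id = f"L{i + 1:03d}"
        start0 = max(0, lead.pos - 1 - window_bp)
        window = Interval(lead.chrom, start0, lead.pos - 1 + window_bp + 1)
        members = sorted(member_lists[i], key=lambda v: (v.pos, v.id))
        loci.append(Locus(locus_id, lead, window, members))
    return loci


def select_candidate_variants(
    locus: Locus,
    orders_of_magnitude: float = 3.0,
    frac_log_lead: float = 0.7,
    r2_min: float = 0.2,
    p_max_rule2: float = 1e-5,
) -> list[Variant]:
    """Select locus members for functional testing.

    A member passes iff it lies in the locus window and either

    * rule 1: its P is within ``orders_of_magnitude`` of the lead's
      (``gwas_p <= 10**orders_of_magnitude * lead.gwas_p``, boundary
      inclusive), or
    * rule 2: ``-log10(P) > frac_log_lead * -log10(P_lead)`` with
      ``r2_to_lead > r2_min`` and ``gwas_p < p_max_rule2``.

    Members without an r2 value are only eligible through rule 1. The lead is
    always selected. Output is sorted by position.
    """
    lead = locus.lead
    if lead.gwas_p is None:
        raise ValidationError(f"locus {locus.locus_id}: lead has no gwas_p")
    log_lead = -math.log10(lead.gwas_p)
    p_cut_rule1 = (10.0 ** orders_of_magnitude) * lead.gwas_p
    selected: list[Variant] = []
    for v in locus.members:
        if v.id == lead.id:
            selected.append(v)
            continue
        if v.gwas_p is None or not variant_in_window(v, locus.window):
            continue
        if v.gwas_p <= p_cut_rule1:
            selected.append(v)
            continue
        if (
            v.r2_to_lead is not None
            and v.r2_to_lead > r2_min
            and v.gwas_p < p_max_rule2
            and -math.log10(v.gwas_p) > frac_log_lead * log_lead
        ):
            selected.append(v)
    selected.sort(key=lambda v: (v.pos, v.id))
    return selected


def variant_in_window(v: Variant, window: Interval) -> bool:
    return v.chrom == window.chrom and window.contains_point(v.pos - 1)


def build_credible_set(
    records: Iterable[FineMapRecord],
    coverage: float = 0.95,
    min_pip: float = 0.001,
) -> set[str]:
    """Ranked-PIP credible set.

    Variants with ``pip > min_pip`` are sorted by descending PIP (ties broken
    lexicographically by id) and included until the cumulative PIP reaches
    ``coverage``, including the record that crosses the threshold. If the
    total eligible mass never reaches ``coverage``, all eligible variants are
    included.
    """
    eligible = sorted(
        (r for r in records if r.pip > min_pip),
        key=lambda r: (-r.pip, r.variant_id),
    )
    out: set[str] = set()
    cum = 0.0
    for rec in eligible:
        out.add(rec.variant_id)
        cum += rec.pip
        if cum >= coverage:
            break
    return out
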
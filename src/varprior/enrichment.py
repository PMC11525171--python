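"""Permutation enrichment tests: AVS/peak overlap and TF-count enrichment.

Both tests share the empirical-p convention: p is the plain proportion of
permutations whose null tally is greater than or equal to the observed tally
(no pseudocount by default; ``smooth=True`` switches to (obs+1)/(n+1)).
Randomness flows from a single integer seed through one spawned generator
per permutation index, so results are reproducible and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import Interval, IntervalIndex, ValidationError, Variant
from .loci import Locus

log = logging.getLogger(__name__)

__all__ = [
    "AVS",
    "EnrichmentResult",
    "build_avs",
    "avs_enrichment",
    "tf_count_enrichment",
]


@dataclass
class AVS:
    """Associated variant set: a locus's lead plus its strong-LD partners."""

    locus_id: str
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError(f"AVS {self.locus_id} is empty")

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class EnrichmentResult:
    observed_tally: int
    null_tallies: np.ndarray
    n_perm: int
    p_value: float


def build_avs(
    loci: Sequence[Locus],
    ld: Optional[Mapping[str, tuple[float, float]]] = None,
    r2_min: float = 0.8,
    dprime_min: float = 0.8,
) -> list[AVS]:
    """Per locus, members with r2 >= 0.8 AND D' >= 0.8 (inclusive); lead always in.

    LD values are read from each member's ``r2_to_lead``/``dprime_to_lead``
    fields unless an explicit ``ld`` mapping (variant_id -> (r2, dprime)) is
    supplied.
    """
    out: list[AVS] = []
    for locus in loci:
        members = [locus.lead]
        for v in locus.members:
            if v.id == locus.lead.id:
                continue
            if ld is not None and v.id in ld:
                r2, dp = ld[v.id]
            else:
                r2, dp = v.r2_to_lead, v.dprime_to_lead
            if r2 is not None and dp is not None and r2 >= r2_min and dp >= dprime_min:
                members.append(v)
        out.append(AVS(locus.locus_id, members))
    return out


def _empirical_p(null: np.ndarray, observed: int, smooth: bool) -> float:
    n = null.size
    hits = int(np.count_nonzero(null >= observed))
    if smooth:
        return (hits + 1) / (n + 1)
    return hits / n


def avs_enrichment(
    avs_list: Sequence[AVS],
    peaks: Sequence[Interval],
    background: Sequence[Variant],
    n_perm: int = 50_000,
    seed: int = 0,
    tally: str = "loci",
    smooth: bool = False,
) -> EnrichmentResult:
    """AVS/peak overlap enrichment against size-matched background draws.

    The observed tally is, by default, the number of AVS with at least one
    member inside a peak (``tally="variants"`` counts overlapping members
    instead). Each permutation draws, per AVS, a size-matched set of
    background variants without replacement and recomputes the tally. LD
    structure of the null is proxied by size-matching; full LD matching would
    require genotypes the pipeline does not consume.
    """
    if tally not in ("loci", "variants"):
        raise ValueError(f"tally must be 'loci' or 'variants', got {tally!r}")
    if not background:
        raise ValidationError("empty background pool")
    sizes = [len(a) for a in avs_list]
    if max(sizes, default=0) > len(background):
        worst = max(avs_list, key=len)
        raise ValidationError(
            f"background pool ({len(background)}) smaller than AVS "
            f"{worst.locus_id} ({len(worst)})"
        )

    index = IntervalIndex(peaks)
    bg_flags = np.array(
        [index.any_contains(v.chrom, v.pos - 1) for v in background], dtype=bool
    )

    def tally_of(flag_groups: list[np.ndarray]) -> int:
        if tally == "loci":
            return sum(bool(g.any()) for g in flag_groups)
        return int(sum(int(g.sum()) for g in flag_groups))

    observed = tally_of(
        [
            np.array([index.any_contains(v.chrom, v.pos - 1) for v in a.variants])
            for a in avs_list
        ]
    )

    n_bg = len(background)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_perm)]
    null = np.empty(n_perm, dtype=np.int64)
    all_size_one = all(s == 1 for s in sizes)
    for i, rng in enumerate(streams):
        if all_size_one:
            draws = rng.integers(0, n_bg, size=len(sizes))
            if tally == "loci":
                null[i] = int(bg_flags[draws].sum())
            else:
                null[i] = int(bg_flags[draws].sum())
        else:
            groups = [bg_flags[rng.choice(n_bg, size=k, replace=False)] for k in sizes]
            null[i] = tally_of(groups)
    return EnrichmentResult(
        observed_tally=observed,
        null_tallies=null,
        n_perm=n_perm,
        p_value=_empirical_p(null, observed, smooth),
    )


def tf_count_enrichment(
    gwas_regions: Sequence[Interval],
    tf_sites: Sequence[Interval],
    null_variant_pool: Sequence[Variant],
    n_perm: int = 50_000,
    seed: int = 0,
    smooth: bool = False,
    null_p_min: float = 0.95,
) -> EnrichmentResult:
    """Bound-TF count enrichment of GWAS regions against null-variant windows.

    ``tf_sites`` are intervals labelled with the TF predicted bound there.
    The observed tally counts, over all GWAS regions, the distinct TFs with a
    site overlapping each region (one unit per (region, TF) pair). Each
    permutation draws one null variant per region (filtered to
    ``gwas_p > null_p_min``; without replacement, falling back to with
    replacement with a warning when the pool is too small), centres a window
    of the same width on it and recounts.
    """
    pool = [
        v
        for v in null_variant_pool
        if v.gwas_p is not None and v.gwas_p > null_p_min
    ]
    if not pool:
        raise ValidationError("null variant pool is empty after P filter")
    index = IntervalIndex(tf_sites)

    def count_tfs(chrom: str, start: int, end: int) -> int:
        return len({iv.label for iv in index.query_interval(chrom, start, end)})

    observed = sum(count_tfs(r.chrom, r.start, r.end) for r in gwas_regions)

    widths = [r.width for r in gwas_regions]
    n_regions = len(gwas_regions)
    replace = n_regions > len(pool)
    if replace:
        log.warning(
            "null pool (%d) smaller than region count (%d); drawing with replacement",
            len(pool),
            n_regions,
        )
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_perm)]
    null = np.empty(n_perm, dtype=np.int64)
    for i, rng in enumerate(streams):
        draws = rng.choice(len(pool), size=n_regions, replace=replace)
        total = 0
        for j, idx in enumerate(draws):
            v = pool[int(idx)]
            half = widths[j] // 2
            start = max(0, v.pos - 1 - half)
            total += count_tfs(v.chrom, start, start + widths[j])
        null[i] = total
    return EnrichmentResult(
        observed_tally=observed,
        null_tallies=null,
        n_perm=n_perm,
        p_value=_empirical_p(null, observed, smooth),
    )
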
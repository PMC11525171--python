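"""Per-variant, per-annotation, per-cell-line scores in {0, 1, 2}.

Every scorer maps one variant and one evidence source to an integer score:
0 = no hit, 1 = hit, 2 = strong hit. Missing evidence yields 0, never an
error, so a sparse input cannot abort a run. Thresholds live in
:class:`ScoringConfig`, which mirrors the config YAML field-for-field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (
    GeneModel,
    Interaction,
    Interval,
    ValidationError,
    Variant,
    variant_in_interval,
)
from .loci import FineMapRecord

log = logging.getLogger(__name__)

__all__ = [
    "TERMS",
    "AnnotationScore",
    "MPRARecord",
    "DisruptionTrack",
    "ScoringConfig",
    "DEFAULT_STATE_MAP",
    "score_mpra",
    "score_finemap",
    "score_chromhmm",
    "score_peak_overlap",
    "score_smr",
    "score_akita",
    "score_microc",
]

#: Annotation terms. MPRA, CHROMHMM, ATAC, CTCF and MICROC are cell-line
#: resolved; FINEMAP, SMR_* and AKITA are not. ABC and TF enter the total via
#: the binomial consensus (see :mod:`varprior.consensus`).
TERMS = (
    "MPRA",
    "FINEMAP",
    "CHROMHMM",
    "ATAC",
    "SMR_NORMAL",
    "SMR_TUMOR",
    "AKITA",
    "CTCF",
    "MICROC",
)

_CELL_LINE_TERMS = frozenset({"MPRA", "CHROMHMM", "ATAC", "CTCF", "MICROC"})


@dataclass(frozen=True, slots=True)
class AnnotationScore:
    variant_id: str
    term: str
    value: int
    cell_line: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value not in (0, 1, 2):
            raise ValidationError(f"score value must be 0/1/2, got {self.value}")
        if self.term in _CELL_LINE_TERMS and self.cell_line is None:
            raise ValidationError(f"term {self.term} requires a cell line")
        if self.term not in _CELL_LINE_TERMS and self.cell_line is not None:
            raise ValidationError(f"term {self.term} is not cell-line resolved")


@dataclass(frozen=True, slots=True)
class MPRARecord:
    """Allelic-activity summary for one variant in one cell line.

    ``log_ratio`` is the alt-vs-ref activity log-ratio; its sign carries the
    direction of effect used for eQTL concordance checks.
    """

    variant_id: str
    cell_line: str
    log_ratio: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"{self.variant_id}: FDR out of [0, 1]: {self.fdr}")


class DisruptionTrack:
    """Positionwise 3D-structure disruption scores for one chromosome.

    Positions are 1-based and strictly increasing; scores are non-negative.
    Global strong/hit quantile thresholds are computed once over all scores
    in the track and cached.
    """

    def __init__(self, chrom: str, positions: Sequence[int], scores: Sequence[float]):
        self.chrom = chrom
        self.positions = np.asarray(positions, dtype=np.int64)
        self.scores = np.asarray(scores, dtype=float)
        if self.positions.shape != self.scores.shape:
            raise ValidationError("disruption track: positions/scores length mismatch")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("disruption track: positions must strictly increase")
        if np.any(self.scores < 0):
            raise ValidationError("disruption track: negative score")
        self._quantile_cache: dict[float, float] = {}

    def quantile(self, q: float) -> float:
        if q not in self._quantile_cache:
            self._quantile_cache[q] = float(np.quantile(self.scores, q))
        return self._quantile_cache[q]

    def window(self, pos: int, half_width: int) -> np.ndarray:
        """Scores at positions within ``half_width`` bp of ``pos`` (inclusive)."""
        lo = np.searchsorted(self.positions, pos - half_width, side="left")
        hi = np.searchsorted(self.positions, pos + half_width, side="right")
        return self.scores[lo:hi]


#: Default chromatin-state score map (Roadmap-style 15-state labels plus a
#: few common aliases). Strong states (active promoter/enhancer) map to 2,
#: weak/flanking states to 1, everything else to 0. The map is config, not
#: hard-coded truth: override ``chromhmm_state_map`` to match your model.
DEFAULT_STATE_MAP: dict[str, int] = {
    "TssA": 2,
    "TssAFlnk": 2,
    "Enh": 2,
    "EnhA": 2,
    "EnhG": 2,
    "Prom": 2,
    "TssFlnk": 1,
    "TssFlnkU": 1,
    "TssFlnkD": 1,
    "EnhWk": 1,
    "EnhBiv": 1,
    "TssBiv": 1,
    "BivFlnk": 1,
    "TxWk": 1,
    "ZNF/Rpts": 0,
    "Tx": 0,
    "Het": 0,
    "ReprPC": 0,
    "ReprPCWk": 0,
    "Quies": 0,
}


@dataclass
class ScoringConfig:
    """Thresholds for every annotation scorer (hit vs strong hit).

    Invariant: each strong threshold is at least as strict as its hit
    threshold.
    """

    mpra_fdr_strong: float = 1e-3
    mpra_fdr_hit: float = 0.05
    pip_strong: float = 0.5
    finemap_literal_pip: bool = False  # True: score 1 on PIP > 0 instead of set membership
    chromhmm_state_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STATE_MAP)
    )
    akita_window_bp: int = 100
    akita_frac: float = 0.25
    akita_top_strong: float = 0.10
    akita_top_hit: float = 0.20
    microc_minus_log10p_min: float = 2.0
    tss_pad_bp: int = 0
    consensus_p0: float = 0.10

    def __post_init__(self) -> None:
        if self.mpra_fdr_strong > self.mpra_fdr_hit:
            raise ValidationError("mpra_fdr_strong must be <= mpra_fdr_hit")
        if self.akita_top_strong > self.akita_top_hit:
            raise ValidationError("akita_top_strong must be <= akita_top_hit")
        for lbl, val in self.chromhmm_state_map.items():
            if val not in (0, 1, 2):
                raise ValidationError(f"state map value for {lbl!r} must be 0/1/2")

    def to_dict(self) -> dict:
        return {
            "mpra_fdr_strong": self.mpra_fdr_strong,
            "mpra_fdr_hit": self.mpra_fdr_hit,
            "pip_strong": self.pip_strong,
            "finemap_literal_pip": self.finemap_literal_pip,
            "chromhmm_state_map": dict(self.chromhmm_state_map),
            "akita_window_bp": self.akita_window_bp,
            "akita_frac": self.akita_frac,
            "akita_top_strong": self.akita_top_strong,
            "akita_top_hit": self.akita_top_hit,
            "microc_minus_log10p_min": self.microc_minus_log10p_min,
            "tss_pad_bp": self.tss_pad_bp,
            "consensus_p0": self.consensus_p0,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringConfig":
        return cls(**dict(d))


# ---------------------------------------------------------------------------
# scorers
# ---------------------------------------------------------------------------


def score_mpra(rec: MPRARecord, cfg: ScoringConfig | None = None) -> AnnotationScore:
    """2 iff FDR <= strong cut (default 1e-3), 1 iff <= hit cut (0.05), else 0.

    Boundaries are inclusive. One score per (variant, cell line); each cell
    line is a separate summand downstream.
    """
    cfg = cfg or ScoringConfig()
    if rec.fdr <= cfg.mpra_fdr_strong:
        value = 2
    elif rec.fdr <= cfg.mpra_fdr_hit:
        value = 1
    else:
        value = 0
    return AnnotationScore(rec.variant_id, "MPRA", value, cell_line=rec.cell_line)


def score_finemap(
    rec: FineMapRecord, in_set: bool, cfg: ScoringConfig | None = None
) -> AnnotationScore:
    """2 iff PIP > 0.5; else 1 iff the variant is in a credible set; else 0.

    With ``finemap_literal_pip`` the hit level uses PIP > 0 instead of set
    membership.
    """
    cfg = cfg or ScoringConfig()
    if rec.pip > cfg.pip_strong:
        value = 2
    elif (rec.pip > 0) if cfg.finemap_literal_pip else in_set:
        value = 1
    else:
        value = 0
    return AnnotationScore(rec.variant_id, "FINEMAP", value)


def score_chromhmm(
    v: Variant,
    segmentation: Sequence[Interval],
    cfg: ScoringConfig | None = None,
    cell_line: str = "NA",
) -> AnnotationScore:
    """Score from the chromatin-state label of the containing segment.

    Unmapped labels score 0; an uncovered position scores 0 with a warning
    (segmentations are expected to tile the genome).
    """
    cfg = cfg or ScoringConfig()
    value = 0
    covered = False
    for seg in segmentation:
        if variant_in_interval(v, seg):
            covered = True
            value = max(value, cfg.chromhmm_state_map.get(seg.label or "", 0))
    if not covered:
        log.warning(
            "variant %s at %s:%d not covered by segmentation (%s); scoring 0",
            v.id,
            v.chrom,
            v.pos,
            cell_line,
        )
    return AnnotationScore(v.id, "CHROMHMM", value, cell_line=cell_line)


def score_peak_overlap(
    v: Variant,
    peaks: Sequence[Interval],
    term: str,
    cell_line: str = "NA",
) -> AnnotationScore:
    """2 iff the variant falls inside any peak, else 0 (never 1)."""
    if term not in ("ATAC", "CTCF"):
        raise ValueError(f"peak-overlap term must be ATAC or CTCF, got {term!r}")
    value = 2 if any(variant_in_interval(v, p) for p in peaks) else 0
    return AnnotationScore(v.id, term, value, cell_line=cell_line)


def score_smr(
    variant_id: str,
    passing_links: Iterable[tuple[str, str]],
    tissue: str,
) -> AnnotationScore:
    """2 iff the variant participates in any filter-passing SMR link for the tissue."""
    if tissue not in ("normal", "tumor"):
        raise ValueError(f"tissue must be 'normal' or 'tumor', got {tissue!r}")
    term = "SMR_NORMAL" if tissue == "normal" else "SMR_TUMOR"
    value = 2 if any(vid == variant_id for vid, _gene in passing_links) else 0
    return AnnotationScore(variant_id, term, value)


def score_akita(
    v: Variant, track: DisruptionTrack | None, cfg: ScoringConfig | None = None
) -> AnnotationScore:
    """Neighbourhood 3D-disruption score.

    Let W be the scored positions within ``akita_window_bp`` of the variant
    (inclusive). With q90/q80 the global (1 - akita_top_strong/hit) quantiles
    of all scores in the track: score 2 iff the fraction of W at or above q90
    exceeds ``akita_frac``; else 1 on the same test against q80; else 0.
    "Top X%" is inclusive of the quantile value itself; the denominator is
    the number of scored positions actually present in the window, so the
    scorer is robust to track gaps.
    """
    cfg = cfg or ScoringConfig()
    if track is None or track.scores.size == 0 or track.chrom != v.chrom:
        return AnnotationScore(v.id, "AKITA", 0)
    w = track.window(v.pos, cfg.akita_window_bp)
    if w.size == 0:
        log.warning("variant %s: empty disruption window; scoring 0", v.id)
        return AnnotationScore(v.id, "AKITA", 0)
    q_strong = track.quantile(1.0 - cfg.akita_top_strong)
    q_hit = track.quantile(1.0 - cfg.akita_top_hit)
    f_strong = float(np.mean(w >= q_strong))
    f_hit = float(np.mean(w >= q_hit))
    if f_strong > cfg.akita_frac:
        value = 2
    elif f_hit > cfg.akita_frac:
        value = 1
    else:
        value = 0
    return AnnotationScore(v.id, "AKITA", value)


def score_microc(
    v: Variant,
    interactions: Sequence[Interaction],
    genes: Sequence[GeneModel],
    cfg: ScoringConfig | None = None,
    cell_line: str = "NA",
) -> AnnotationScore:
    """Long-range-contact score.

    Over all interactions passing the significance filter in which the
    variant lies inside one anchor: 2 if any distal anchor contains a gene's
    TSS point (optionally padded by ``tss_pad_bp``); else 1 if any distal
    anchor overlaps a gene body; else 0. Symmetric in the two anchors.
    """
    cfg = cfg or ScoringConfig()
    value = 0
    pad = cfg.tss_pad_bp
    for x in interactions:
        if x.neg_log10_p < cfg.microc_minus_log10p_min:
            continue
        if variant_in_interval(v, x.anchor_a):
            distal = x.anchor_b
        elif variant_in_interval(v, x.anchor_b):
            distal = x.anchor_a
        else:
            continue
        for g in genes:
            if g.chrom != distal.chrom:
                continue
            if distal.start - pad <= g.tss_pos - 1 < distal.end + pad:
                return AnnotationScore(v.id, "MICROC", 2, cell_line=cell_line)
            if g.body.overlaps(distal):
                value = 1
    return AnnotationScore(v.id, "MICROC", value, cell_line=cell_line)
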
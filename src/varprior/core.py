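"""Domain types, coordinate conventions and track readers/writers.

Coordinate conventions used throughout the package:

* ``Interval`` objects are 0-based, half-open (BED convention).
* ``Variant`` positions are 1-based points (GWAS/VCF summary convention).
* The bridge between the two is exactly ``pos - 1 in [start, end)``; see
  :func:`variant_in_interval`.

Chromosome names are compared verbatim — no ``chr`` prefix normalisation is
performed, so inputs in mixed namespaces fail loudly rather than silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "Variant",
    "Interval",
    "Interaction",
    "GeneModel",
    "CellLinePanel",
    "IntervalIndex",
    "load_interval_track",
    "write_interval_track",
    "load_interaction_track",
    "write_interaction_track",
    "variant_in_interval",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect (wrong column count, ...)."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant (inverted interval, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Variant:
    """A genomic point variant with association summary statistics.

    ``pos`` is 1-based. ``r2_to_lead``/``dprime_to_lead`` are LD summaries
    relative to the lead variant of the locus the variant belongs to; both are
    optional because background variants carry no locus assignment.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str = "N"
    alt_allele: str = "N"
    gwas_p: Optional[float] = None
    locus_id: Optional[str] = None
    is_lead: bool = False
    r2_to_lead: Optional[float] = None
    dprime_to_lead: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.gwas_p is not None and not (0.0 < self.gwas_p <= 1.0):
            raise ValidationError(f"variant {self.id}: gwas_p out of (0, 1]: {self.gwas_p}")
        for name in ("r2_to_lead", "dprime_to_lead"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValidationError(f"variant {self.id}: {name} out of [0, 1]: {val}")


@dataclass(frozen=True, slots=True)
class Interval:
    """0-based, half-open genomic interval with an optional label and score."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"interval start < 0: {self}")
        if self.start >= self.end:
            raise ValidationError(
                f"interval start >= end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains_point(self, pos0: int) -> bool:
        """Whether a 0-based point falls inside the interval."""
        return self.start <= pos0 < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class Interaction:
    """A chromatin contact: two anchors plus a -log10(P) significance."""

    anchor_a: Interval
    anchor_b: Interval
    neg_log10_p: float

    def __post_init__(self) -> None:
        if self.neg_log10_p < 0:
            raise ValidationError(f"interaction neg_log10_p < 0: {self.neg_log10_p}")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene body plus its TSS position (1-based) and strand."""

    gene_id: str
    chrom: str
    body: Interval
    tss_pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.body.contains_point(self.tss_pos - 1):
            raise ValidationError(
                f"gene {self.gene_id}: TSS {self.tss_pos} outside body "
                f"[{self.body.start}, {self.body.end})"
            )


@dataclass
class CellLinePanel:
    """The roster of cell lines with data for one assay.

    The roster is free-form on purpose: different assays in a study may cover
    different (and differently sized) sets of cell lines, so nothing in the
    pipeline assumes a fixed panel.
    """

    assay: str
    cell_lines: list[str] = field(default_factory=list)
    availability: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cell_lines:
            raise ValidationError(f"panel for assay {self.assay!r} is empty")
        for cl in self.cell_lines:
            self.availability.setdefault(cl, True)

    @property
    def available(self) -> list[str]:
        return [cl for cl in self.cell_lines if self.availability.get(cl, False)]


# ---------------------------------------------------------------------------
# point / interval predicates
# ---------------------------------------------------------------------------


def variant_in_interval(v: Variant, iv: Interval) -> bool:
    """True iff the 1-based variant position falls in the 0-based interval.

    The bridge is ``iv.start <= v.pos - 1 < iv.end``; chromosomes must match
    verbatim.
    """
    return v.chrom == iv.chrom and iv.contains_point(v.pos - 1)


class IntervalIndex:
    """Per-chromosome vectorised overlap queries over a set of intervals.

    Intervals may overlap each other; queries are O(n) per chromosome via
    numpy masks, which is ample for track sizes this pipeline handles.
    """

    def __init__(self, intervals: Iterable[Interval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[Interval]]] = {}
        buckets: dict[str, list[Interval]] = {}
        for iv in intervals:
            buckets.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in buckets.items():
            ivs.sort(key=lambda i: (i.start, i.end))
            starts = np.array([i.start for i in ivs], dtype=np.int64)
            ends = np.array([i.end for i in ivs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, ivs)

    def query_point(self, chrom: str, pos0: int) -> list[Interval]:
        """All intervals containing the 0-based point."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, ivs = entry
        mask = (starts <= pos0) & (pos0 < ends)
        return [ivs[i] for i in np.flatnonzero(mask)]

    def any_contains(self, chrom: str, pos0: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends, _ = entry
        return bool(np.any((starts <= pos0) & (pos0 < ends)))

    def query_interval(self, chrom: str, start: int, end: int) -> list[Interval]:
        """All intervals overlapping [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, ivs = entry
        mask = (starts < end) & (start < ends)
        return [ivs[i] for i in np.flatnonzero(mask)]


# ---------------------------------------------------------------------------
# track IO
# ---------------------------------------------------------------------------

_DIALECT_NCOLS = {"bed3": 3, "bed4_label": 4, "bed5_score": 5}


def load_interval_track(path: str | Path, dialect: str = "bed3") -> list[Interval]:
    """Read a BED-style interval track.

    Supported dialects: ``bed3`` (chrom, start, end), ``bed4_label`` (adds a
    text label such as a chromatin state or peak name), ``bed5_score`` (label
    plus a numeric score). Lines beginning with ``#`` or ``track`` are
    skipped. The returned list is sorted by (chrom, start, end) with a stable
    sort, so equal keys preserve file order.
    """
    if dialect not in _DIALECT_NCOLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = _DIALECT_NCOLS[dialect]
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {ncols} columns for {dialect}, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            label = fields[3] if ncols >= 4 else None
            score = None
            if ncols >= 5:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                out.append(Interval(chrom, start, end, label=label, score=score))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_interval_track(
    intervals: Sequence[Interval], path: str | Path, dialect: str = "bed3"
) -> None:
    """Write intervals in the given BED dialect (inverse of load_interval_track)."""
    if dialect not in _DIALECT_NCOLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = _DIALECT_NCOLS[dialect]
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols >= 4:
                fields.append(iv.label if iv.label is not None else ".")
            if ncols >= 5:
                fields.append(_fmt_float(iv.score) if iv.score is not None else "0")
            fh.write("\t".join(fields) + "\n")


def load_interaction_track(path: str | Path) -> list[Interaction]:
    """Read a BEDPE-like 7-column interaction file.

    Columns: chromA, startA, endA, chromB, startB, endB, neg_log10_p.
    Records are returned in file order; negative significances are rejected.
    """
    out: list[Interaction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                a = Interval(fields[0], int(fields[1]), int(fields[2]))
                b = Interval(fields[3], int(fields[4]), int(fields[5]))
                nlp = float(fields[6])
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed field") from exc
            if nlp < 0:
                raise ValidationError(
                    f"{path}:{lineno}: neg_log10_p must be >= 0, got {nlp}"
                )
            out.append(Interaction(a, b, nlp))
    return out


def write_interaction_track(interactions: Sequence[Interaction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for x in interactions:
            fh.write(
                "\t".join(
                    [
                        x.anchor_a.chrom,
                        str(x.anchor_a.start),
                        str(x.anchor_a.end),
                        x.anchor_b.chrom,
                        str(x.anchor_b.start),
                        str(x.anchor_b.end),
                        _fmt_float(x.neg_log10_p),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# generic TSV tables with '#' metadata lines
# ---------------------------------------------------------------------------


def _fmt_float(x: float) -> str:
    return format(float(x), ".10g")


def write_table(
    df: pd.DataFrame, path: str | Path, meta: Optional[Mapping[str, object]] = None
) -> None:
    """Write a TSV with a header line, preceded by '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping '#' metadata lines."""
    return pd.read_csv(path, sep="\t", comment="#")
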
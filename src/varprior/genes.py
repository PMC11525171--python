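"""SMR filtering, MPRA/eQTL direction concordance and target-gene nomination.

Gene nomination works per locus on the Tier 1 variants: a gene needs at
least two distinct evidence sources (SMR normal, SMR tumor, ABC, Micro-C
TSS) across the locus's Tier 1 variants to be a strong prediction. When that
fails, three fallbacks fire in order, each only when every earlier stage
produced nothing at the locus: Micro-C gene-body contacts (weak), the same
procedure on Tier 2 variants when the locus has no Tier 1 variants (weak),
and finally the host gene of an intronic considered variant (weak).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core import GeneModel, ValidationError, Variant
from .scoring import MPRARecord

log = logging.getLogger(__name__)

__all__ = [
    "SMRRecord",
    "GeneLink",
    "EVIDENCE_SOURCES",
    "filter_smr",
    "eqtl_bonferroni_threshold",
    "truncate_significant",
    "harmonize_beta",
    "direction_concordance",
    "nominate_genes",
    "closest_gene",
]

#: Evidence sources eligible for the >= 2-source strong-link rule.
EVIDENCE_SOURCES = ("SMR_NORMAL", "SMR_TUMOR", "ABC", "MICROC_TSS")


@dataclass(frozen=True, slots=True)
class SMRRecord:
    """One SMR test result for a (gene, variant) pair in one tissue."""

    gene_id: str
    variant_id: str
    locus_id: str
    tissue: str  # "normal" | "tumor"
    p_smr: float
    p_heidi: float
    beta: float  # eQTL effect of the alt allele

    def __post_init__(self) -> None:
        if self.tissue not in ("normal", "tumor"):
            raise ValidationError(f"tissue must be normal/tumor, got {self.tissue!r}")
        for name in ("p_smr", "p_heidi"):
            p = getattr(self, name)
            if not (0.0 < p <= 1.0):
                raise ValidationError(f"{self.gene_id}/{self.variant_id}: {name}={p}")


@dataclass(frozen=True, slots=True)
class GeneLink:
    gene_id: str
    locus_id: str
    variant_id: str
    evidence: frozenset
    status: str  # "strong" | "weak"
    fallback_used: Optional[str] = None  # microc_body | tier2 | intronic

    def __post_init__(self) -> None:
        if self.status == "strong" and len(self.evidence) < 2:
            raise ValidationError("strong link requires >= 2 evidence sources")
        if self.status == "weak" and self.fallback_used is None:
            raise ValidationError("weak link must record which fallback produced it")
        if self.status not in ("strong", "weak"):
            raise ValidationError(f"bad status {self.status!r}")


def filter_smr(
    records: Iterable[SMRRecord],
    genes_per_locus: Mapping[str, int],
) -> set[tuple[str, str, str]]:
    """Apply the per-locus Bonferroni and HEIDI filters.

    A record passes iff ``p_smr * genes_per_locus[locus] < 0.05`` and
    ``p_heidi > 0.05``. Records whose locus is absent from the count map are
    rejected with a warning. Returns passing (variant_id, gene_id, tissue)
    triples.
    """
    passing: set[tuple[str, str, str]] = set()
    for rec in records:
        n_genes = genes_per_locus.get(rec.locus_id)
        if n_genes is None:
            log.warning(
                "SMR record %s/%s: locus %s missing from gene-count map; rejected",
                rec.variant_id,
                rec.gene_id,
                rec.locus_id,
            )
            continue
        if rec.p_smr * n_genes < 0.05 and rec.p_heidi > 0.05:
            passing.add((rec.variant_id, rec.gene_id, rec.tissue))
    return passing


def eqtl_bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected eQTL significance threshold: alpha / n_genes."""
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    return alpha / n_genes


def truncate_significant(x: float, digits: int = 3) -> float:
    """Truncate (not round) a positive number to the given significant digits."""
    if x <= 0:
        raise ValueError("truncate_significant requires a positive value")
    exponent = math.floor(math.log10(x))
    scale = 10.0 ** (exponent - digits + 1)
    return math.floor(x / scale) * scale


def harmonize_beta(
    beta: float,
    eqtl_effect_allele: str,
    mpra_ref: str,
    mpra_alt: str,
) -> float:
    """Orient an eQTL effect to the MPRA alt allele.

    Flips the sign when the eQTL effect allele is the MPRA reference allele;
    raises if the effect allele matches neither MPRA allele.
    """
    if eqtl_effect_allele == mpra_alt:
        return beta
    if eqtl_effect_allele == mpra_ref:
        return -beta
    raise ValidationError(
        f"eQTL effect allele {eqtl_effect_allele!r} matches neither "
        f"ref {mpra_ref!r} nor alt {mpra_alt!r}"
    )


def direction_concordance(mpra: MPRARecord, smr: SMRRecord) -> bool:
    """True iff MPRA log-ratio and eQTL beta share a nonzero sign.

    Both effects must already be oriented to the alt allele (use
    :func:`harmonize_beta` first when orientations differ). A zero effect on
    either side is non-concordant by definition, with a warning.
    """
    if mpra.log_ratio == 0 or smr.beta == 0:
        log.warning(
            "zero effect for %s (mpra=%g, beta=%g); treating as non-concordant",
            mpra.variant_id,
            mpra.log_ratio,
            smr.beta,
        )
        return False
    return (mpra.log_ratio > 0) == (smr.beta > 0)


def _intronic_gene(v: Variant, genes: Sequence[GeneModel]) -> Optional[str]:
    # Without an exon table, "intronic" degrades to "inside the gene body".
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom == v.chrom and g.body.contains_point(v.pos - 1):
            return g.gene_id
    return None


def nominate_genes(
    tiers: Mapping[str, int],
    variant_locus: Mapping[str, str],
    evidence: Mapping[str, set[tuple[str, str]]],
    microc_body: set[tuple[str, str]] | None = None,
    genes: Sequence[GeneModel] = (),
    variants: Mapping[str, Variant] | None = None,
    same_variant: bool = False,
) -> list[GeneLink]:
    """Nominate target genes per locus from tiered variants.

    Parameters
    ----------
    tiers:
        variant_id -> tier (1/2/3) for every tiered variant.
    variant_locus:
        variant_id -> locus_id.
    evidence:
        source name (one of :data:`EVIDENCE_SOURCES`) -> set of
        (variant_id, gene_id) pairs supported by that source.
    microc_body:
        (variant_id, gene_id) pairs with a Micro-C gene-body contact, used by
        the first fallback.
    genes, variants:
        gene models and variant records, needed only for the intronic
        fallback.
    same_variant:
        when True, the two evidence sources must involve the same variant
        (strict reading); by default evidence is unioned per gene across the
        locus's considered variants.

    Stages per locus: (1) strong links from >= 2 evidence sources over Tier 1
    variants; (2) if none, weak links from Micro-C gene-body contacts of Tier
    1 variants; (3) if the locus has no Tier 1 variants at all, stages 1-2
    run on Tier 2 variants and every link is weak; (4) if still nothing, an
    intronic considered variant links weakly to its host gene. A locus
    exhausting all stages yields no link, which is a legitimate outcome.
    """
    microc_body = microc_body or set()
    variants = variants or {}
    unknown = set(evidence) - set(EVIDENCE_SOURCES)
    if unknown:
        raise ValueError(f"unknown evidence sources: {sorted(unknown)}")

    by_locus: dict[str, list[str]] = {}
    for vid, locus_id in variant_locus.items():
        by_locus.setdefault(locus_id, []).append(vid)

    links: list[GeneLink] = []
    for locus_id in sorted(by_locus):
        locus_vids = by_locus[locus_id]
        tier1 = sorted(v for v in locus_vids if tiers.get(v) == 1)
        tier2 = sorted(v for v in locus_vids if tiers.get(v) == 2)
        if tier1:
            considered, fallback_tag = tier1, None
        else:
            considered, fallback_tag = tier2, "tier2"
        if not considered:
            continue

        locus_links = _evidence_links(
            locus_id, considered, evidence, fallback_tag, same_variant
        )
        if not locus_links:
            locus_links = _body_links(locus_id, considered, microc_body)
        if not locus_links:
            for vid in considered:
                v = variants.get(vid)
                if v is None:
                    continue
                host = _intronic_gene(v, genes)
                if host is not None:
                    locus_links.append(
                        GeneLink(
                            gene_id=host,
                            locus_id=locus_id,
                            variant_id=vid,
                            evidence=frozenset(),
                            status="weak",
                            fallback_used="intronic",
                        )
                    )
                    break
        links.extend(locus_links)

    links.sort(key=lambda l: (l.locus_id, l.gene_id, l.variant_id))
    return links


def _evidence_links(
    locus_id: str,
    considered: Sequence[str],
    evidence: Mapping[str, set[tuple[str, str]]],
    fallback_tag: Optional[str],
    same_variant: bool,
) -> list[GeneLink]:
    # gene -> evidence sources (optionally per variant), plus a representative
    # variant per (gene, source) for reporting
    per_gene: dict[str, dict[str, set[str]]] = {}
    for source in EVIDENCE_SOURCES:
        for vid, gene in evidence.get(source, set()):
            if vid in considered:
                per_gene.setdefault(gene, {}).setdefault(source, set()).add(vid)
    out: list[GeneLink] = []
    for gene in sorted(per_gene):
        sources = per_gene[gene]
        if same_variant:
            # require two sources sharing at least one variant
            shared = [
                vid
                for vid in considered
                if sum(vid in vids for vids in sources.values()) >= 2
            ]
            if not shared:
                continue
            vid = shared[0]
            ev = frozenset(s for s, vids in sources.items() if vid in vids)
        else:
            if len(sources) < 2:
                continue
            ev = frozenset(sources)
            vid = min(min(vids) for vids in sources.values())
        status = "strong" if fallback_tag is None else "weak"
        out.append(
            GeneLink(
                gene_id=gene,
                locus_id=locus_id,
                variant_id=vid,
                evidence=ev,
                status=status,
                fallback_used=fallback_tag,
            )
        )
    return out


def _body_links(
    locus_id: str,
    considered: Sequence[str],
    microc_body: set[tuple[str, str]],
) -> list[GeneLink]:
    pairs = sorted((vid, gene) for vid, gene in microc_body if vid in considered)
    seen: set[str] = set()
    out: list[GeneLink] = []
    for vid, gene in pairs:
        if gene in seen:
            continue
        seen.add(gene)
        out.append(
            GeneLink(
                gene_id=gene,
                locus_id=locus_id,
                variant_id=vid,
                evidence=frozenset(),
                status="weak",
                fallback_used="microc_body",
            )
        )
    return out


def closest_gene(v: Variant, genes: Sequence[GeneModel]) -> Optional[str]:
    """The gene with the nearest TSS on the variant's chromosome (ties by id)."""
    best: Optional[tuple[int, str]] = None
    for g in genes:
        if g.chrom != v.chrom:
            continue
        d = abs(g.tss_pos - v.pos)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    return best[1] if best else None
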
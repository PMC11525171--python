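"""End-to-end orchestration: load a dataset directory, run every stage,
write audited TSV intermediates.

The stage chain is: define loci -> select candidates -> credible sets ->
per-annotation scores -> cross-cell-line consensus -> summed scores and
tiers -> gene nomination -> (optional) permutation enrichments -> report.
Every stage writes a plain TSV with '#' metadata lines (package version,
seed, config hash) so any stage can be re-run and audited in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .consensus import (
    MAJORITY_TERMS,
    assign_tiers,
    binomial_consensus,
    majority_consensus,
    percentile_hit_flags,
    sum_scores,
)
from .core import (
    GeneModel,
    Interval,
    Variant,
    load_interaction_track,
    load_interval_track,
    read_table,
    variant_in_interval,
    write_table,
)
from .enrichment import avs_enrichment, build_avs, tf_count_enrichment
from .genes import (
    SMRRecord,
    closest_gene,
    filter_smr,
    nominate_genes,
)
from .loci import (
    FineMapRecord,
    Locus,
    build_credible_set,
    define_loci,
    select_candidate_variants,
)
from .scoring import (
    DisruptionTrack,
    MPRARecord,
    ScoringConfig,
    score_akita,
    score_chromhmm,
    score_finemap,
    score_microc,
    score_mpra,
    score_peak_overlap,
    score_smr,
)

log = logging.getLogger(__name__)

__all__ = ["Dataset", "PipelineResult", "load_dataset", "run_all", "report_summary"]


@dataclass
class Dataset:
    """All parsed pipeline inputs for one dataset directory."""

    root: Path
    chrom: str
    cell_lines: list[str]
    variants: list[Variant]
    finemap: dict[str, float]
    mpra: pd.DataFrame
    atac: dict[str, list[Interval]]
    ctcf: dict[str, list[Interval]]
    chromhmm: dict[str, list[Interval]]
    microc: dict[str, list]
    akita: dict[str, DisruptionTrack]
    smr: list[SMRRecord]
    abc: pd.DataFrame
    tf: pd.DataFrame
    tf_sites: list[Interval]
    genes: list[GeneModel]
    background: list[Variant]


def load_dataset(root: str | Path) -> Dataset:
    """Load a dataset directory via its ``dataset.yaml`` index.

    Validates that every referenced file exists before any parsing, so a
    broken config fails before computation starts.
    """
    root = Path(root)
    index_path = root / "dataset.yaml"
    with open(index_path) as fh:
        index = yaml.safe_load(fh)

    def _resolve(entry):
        if isinstance(entry, dict):
            return {k: _resolve(v) for k, v in entry.items()}
        p = Path(entry)
        return str(p if p.is_absolute() else root / p)

    files = {k: _resolve(v) for k, v in index["files"].items()}

    missing = []
    for key, val in files.items():
        entries = val.values() if isinstance(val, dict) else [val]
        for p in entries:
            if not Path(p).exists():
                missing.append(str(p))
    if missing:
        raise FileNotFoundError(f"dataset references missing files: {missing}")

    gwas = read_table(files["gwas"])
    ld = read_table(files["ld"]).set_index("variant_id")
    variants = []
    for row in gwas.itertuples(index=False):
        r2 = dp = None
        if row.id in ld.index:
            r2 = float(ld.at[row.id, "r2"])
            dp = float(ld.at[row.id, "dprime"])
        variants.append(
            Variant(
                id=str(row.id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                gwas_p=float(row.p),
                r2_to_lead=r2,
                dprime_to_lead=dp,
            )
        )

    finemap_df = read_table(files["finemap"])
    finemap = dict(zip(finemap_df["variant_id"].astype(str), finemap_df["pip"].astype(float)))

    akita_df = read_table(files["akita"])
    akita = {
        chrom: DisruptionTrack(
            chrom,
            grp.sort_values("pos")["pos"].to_numpy(),
            grp.sort_values("pos")["score"].to_numpy(),
        )
        for chrom, grp in akita_df.groupby("chrom")
    }

    smr_records = [
        SMRRecord(
            gene_id=str(r.gene_id),
            variant_id=str(r.variant_id),
            locus_id=str(r.locus_id),
            tissue=str(r.tissue),
            p_smr=float(r.p_smr),
            p_heidi=float(r.p_heidi),
            beta=float(r.beta),
        )
        for r in read_table(files["smr"]).itertuples(index=False)
    ]

    genes_df = read_table(files["genes"])
    genes = [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            body=Interval(str(r.chrom), int(r.start), int(r.end)),
            tss_pos=int(r.tss),
            strand=str(r.strand),
        )
        for r in genes_df.itertuples(index=False)
    ]

    bg_df = read_table(files["background"])
    background = [
        Variant(id=str(r.id), chrom=str(r.chrom), pos=int(r.pos), gwas_p=float(r.p))
        for r in bg_df.itertuples(index=False)
    ]

    return Dataset(
        root=root,
        chrom=index.get("chrom", "chr1"),
        cell_lines=list(index["cell_lines"]),
        variants=variants,
        finemap=finemap,
        mpra=read_table(files["mpra"]),
        atac={cl: load_interval_track(p, "bed3") for cl, p in files["atac"].items()},
        ctcf={cl: load_interval_track(p, "bed3") for cl, p in files["ctcf"].items()},
        chromhmm={
            cl: load_interval_track(p, "bed4_label") for cl, p in files["chromhmm"].items()
        },
        microc={cl: load_interaction_track(p) for cl, p in files["microc"].items()},
        akita=akita,
        smr=smr_records,
        abc=read_table(files["abc"]),
        tf=read_table(files["tf"]),
        tf_sites=load_interval_track(files["tf_sites"], "bed4_label"),
        genes=genes,
        background=background,
    )


@dataclass
class PipelineResult:
    loci: list[Locus]
    candidates: dict[str, list[Variant]]  # locus_id -> selected variants
    credible_sets: dict[str, set[str]]  # locus_id -> member variant ids
    score_table: pd.DataFrame  # long: variant_id, term, cell_line, value
    total_table: pd.DataFrame  # variant_id, locus_id, total_score
    tier_table: pd.DataFrame  # variant_id, locus_id, total_score, percentile, tier
    gene_links: pd.DataFrame
    report: dict
    enrichment: dict = field(default_factory=dict)


def _config_hash(cfg: ScoringConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _pairs_majority(per_line_pairs: dict[str, set], n_lines: int) -> set:
    """Pairs present in strictly more than half of the cell lines with data."""
    counts: dict[tuple, int] = {}
    for pairs in per_line_pairs.values():
        for pair in pairs:
            counts[pair] = counts.get(pair, 0) + 1
    return {pair for pair, c in counts.items() if 2 * c > n_lines}


def run_all(
    dataset: Dataset,
    cfg: Optional[ScoringConfig] = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    per_locus_tiers: bool = False,
    enrich: bool = False,
    n_perm: int = 2_000,
) -> PipelineResult:
    """Run the full prioritization chain on a loaded dataset.

    ``per_locus_tiers`` switches tier ranking from the default global ranking
    to within-locus ranking. ``enrich`` additionally runs both permutation
    enrichment tests (AVS x ATAC peaks of the first cell line, and TF counts)
    at ``n_perm`` permutations.
    """
    cfg = cfg or ScoringConfig()
    meta = {
        "version": __version__,
        "seed": seed,
        "config_sha256": _config_hash(cfg),
    }

    # --- stage 1-2: loci and candidates ------------------------------------
    loci = define_loci(dataset.variants)
    candidates: dict[str, list[Variant]] = {}
    variant_locus: dict[str, str] = {}
    for locus in loci:
        sel = select_candidate_variants(locus)
        candidates[locus.locus_id] = sel
        for v in sel:
            variant_locus[v.id] = locus.locus_id

    # --- stage 3: credible sets --------------------------------------------
    credible_sets: dict[str, set[str]] = {}
    for locus in loci:
        records = [
            FineMapRecord(v.id, dataset.finemap.get(v.id, 0.0)) for v in locus.members
        ]
        credible_sets[locus.locus_id] = build_credible_set(records)

    # --- SMR filters shared by scoring and linking -------------------------
    genes_per_locus: dict[str, int] = {}
    for locus in loci:
        n = sum(
            1
            for g in dataset.genes
            if g.chrom == locus.window.chrom and locus.window.contains_point(g.tss_pos - 1)
        )
        genes_per_locus[locus.locus_id] = max(1, n)
    smr_pass = filter_smr(dataset.smr, genes_per_locus)
    smr_links = {
        "normal": {(v, g) for v, g, t in smr_pass if t == "normal"},
        "tumor": {(v, g) for v, g, t in smr_pass if t == "tumor"},
    }

    # --- percentile flags for the binomial-consensus analyses --------------
    abc_flags = percentile_hit_flags(
        {cl: grp[["variant_id", "score"]] for cl, grp in dataset.abc.groupby("cell_line")}
    )
    tf_flags = percentile_hit_flags(
        {cl: grp[["variant_id", "score"]] for cl, grp in dataset.tf.groupby("cell_line")}
    )

    mpra_by_variant: dict[str, list[MPRARecord]] = {}
    for r in dataset.mpra.itertuples(index=False):
        rec = MPRARecord(str(r.variant_id), str(r.cell_line), float(r.log_ratio), float(r.fdr))
        mpra_by_variant.setdefault(rec.variant_id, []).append(rec)

    # --- stage 4-6: scores, consensus, totals ------------------------------
    score_rows = []
    total_rows = []
    microc_tss_by_line: dict[str, set] = {cl: set() for cl in dataset.cell_lines}
    microc_body_by_line: dict[str, set] = {cl: set() for cl in dataset.cell_lines}

    for locus in loci:
        cset = credible_sets[locus.locus_id]
        for v in candidates[locus.locus_id]:
            terms: dict[str, int] = {}

            for rec in mpra_by_variant.get(v.id, []):
                s = score_mpra(rec, cfg)
                terms[f"MPRA:{rec.cell_line}"] = s.value
                score_rows.append((v.id, "MPRA", rec.cell_line, s.value))

            fm = FineMapRecord(v.id, dataset.finemap.get(v.id, 0.0))
            s = score_finemap(fm, v.id in cset, cfg)
            terms["FINEMAP"] = s.value
            score_rows.append((v.id, "FINEMAP", None, s.value))

            for term, tracks in (("ATAC", dataset.atac), ("CTCF", dataset.ctcf)):
                per_line = {
                    cl: score_peak_overlap(v, peaks, term, cl).value
                    for cl, peaks in tracks.items()
                }
                for cl, val in per_line.items():
                    score_rows.append((v.id, term, cl, val))
                cons = majority_consensus(per_line, term, v.id)
                terms[term] = cons.value

            per_line = {
                cl: score_chromhmm(v, segs, cfg, cl).value
                for cl, segs in dataset.chromhmm.items()
            }
            for cl, val in per_line.items():
                score_rows.append((v.id, "CHROMHMM", cl, val))
            terms["CHROMHMM"] = majority_consensus(per_line, "CHROMHMM", v.id).value

            per_line = {}
            for cl, contacts in dataset.microc.items():
                s = score_microc(v, contacts, dataset.genes, cfg, cl)
                per_line[cl] = s.value
                score_rows.append((v.id, "MICROC", cl, s.value))
                # collect gene-evidence pairs for the linking stage
                for x in contacts:
                    if x.neg_log10_p < cfg.microc_minus_log10p_min:
                        continue
                    if variant_in_interval(v, x.anchor_a):
                        distal = x.anchor_b
                    elif variant_in_interval(v, x.anchor_b):
                        distal = x.anchor_a
                    else:
                        continue
                    for g in dataset.genes:
                        if g.chrom != distal.chrom:
                            continue
                        if distal.contains_point(g.tss_pos - 1):
                            microc_tss_by_line[cl].add((v.id, g.gene_id))
                        elif g.body.overlaps(distal):
                            microc_body_by_line[cl].add((v.id, g.gene_id))
            terms["MICROC"] = majority_consensus(per_line, "MICROC", v.id).value

            for tissue, term in (("normal", "SMR_NORMAL"), ("tumor", "SMR_TUMOR")):
                s = score_smr(v.id, smr_links[tissue], tissue)
                terms[term] = s.value
                score_rows.append((v.id, term, None, s.value))

            s = score_akita(v, dataset.akita.get(v.chrom), cfg)
            terms["AKITA"] = s.value
            score_rows.append((v.id, "AKITA", None, s.value))

            for name, flags in (("ABC", abc_flags), ("TF", tf_flags)):
                vals = [
                    flags[(v.id, cl)]
                    for cl in dataset.cell_lines
                    if (v.id, cl) in flags
                ]
                val = binomial_consensus(vals, cfg.consensus_p0)
                terms[name] = val
                score_rows.append((v.id, name, None, val))

            total_rows.append(
                {
                    "variant_id": v.id,
                    "locus_id": locus.locus_id,
                    "total_score": sum_scores(terms),
                }
            )

    total_table = pd.DataFrame(
        total_rows, columns=["variant_id", "locus_id", "total_score"]
    ).sort_values("variant_id", kind="stable")
    score_table = pd.DataFrame(
        score_rows, columns=["variant_id", "term", "cell_line", "value"]
    ).sort_values(["variant_id", "term", "cell_line"], kind="stable")

    # --- stage 7: tiers ----------------------------------------------------
    tier_rows = []
    if per_locus_tiers:
        for locus_id, grp in total_table.groupby("locus_id"):
            pairs = list(zip(grp["variant_id"], grp["total_score"]))
            for t in assign_tiers(pairs):
                tier_rows.append((t.variant_id, locus_id, t.total_score, t.rank_percentile, t.tier))
    else:
        pairs = list(zip(total_table["variant_id"], total_table["total_score"]))
        locus_of = dict(zip(total_table["variant_id"], total_table["locus_id"]))
        for t in assign_tiers(pairs):
            tier_rows.append(
                (t.variant_id, locus_of[t.variant_id], t.total_score, t.rank_percentile, t.tier)
            )
    tier_table = pd.DataFrame(
        tier_rows,
        columns=["variant_id", "locus_id", "total_score", "percentile", "tier"],
    ).sort_values("variant_id", kind="stable")

    # --- stage 8: gene nomination ------------------------------------------
    n_microc_lines = len(dataset.microc)
    microc_tss = _pairs_majority(microc_tss_by_line, n_microc_lines)
    microc_body = _pairs_majority(microc_body_by_line, n_microc_lines)

    # ABC evidence: pair present in the ABC table with a consensus score >= 1
    abc_consensus: dict[str, int] = {}
    for vid in total_table["variant_id"]:
        vals = [abc_flags[(vid, cl)] for cl in dataset.cell_lines if (vid, cl) in abc_flags]
        abc_consensus[vid] = binomial_consensus(vals, cfg.consensus_p0)
    abc_pairs = {
        (str(r.variant_id), str(r.gene_id))
        for r in dataset.abc.itertuples(index=False)
        if abc_consensus.get(str(r.variant_id), 0) >= 1
    }

    tiers_map = dict(zip(tier_table["variant_id"], tier_table["tier"]))
    links = nominate_genes(
        tiers=tiers_map,
        variant_locus=variant_locus,
        evidence={
            "SMR_NORMAL": smr_links["normal"],
            "SMR_TUMOR": smr_links["tumor"],
            "ABC": abc_pairs,
            "MICROC_TSS": microc_tss,
        },
        microc_body=microc_body,
        genes=dataset.genes,
        variants={v.id: v for vs in candidates.values() for v in vs},
    )
    gene_links = pd.DataFrame(
        [
            {
                "gene_id": l.gene_id,
                "locus_id": l.locus_id,
                "variant_id": l.variant_id,
                "evidence": ",".join(sorted(l.evidence)) or ".",
                "status": l.status,
                "fallback": l.fallback_used or ".",
            }
            for l in links
        ],
        columns=["gene_id", "locus_id", "variant_id", "evidence", "status", "fallback"],
    )

    # --- stage 9: optional enrichments -------------------------------------
    enrichment = {}
    if enrich:
        avs_list = build_avs(loci)
        first_line = dataset.cell_lines[0]
        enrichment["avs_atac"] = avs_enrichment(
            avs_list,
            dataset.atac[first_line],
            dataset.background,
            n_perm=n_perm,
            seed=seed,
        )
        regions = [locus.window for locus in loci]
        enrichment["tf_count"] = tf_count_enrichment(
            regions,
            dataset.tf_sites,
            dataset.background,
            n_perm=n_perm,
            seed=seed,
        )

    report = report_summary(loci, candidates, tier_table, gene_links, dataset.genes)

    result = PipelineResult(
        loci=loci,
        candidates=candidates,
        credible_sets=credible_sets,
        score_table=score_table,
        total_table=total_table,
        tier_table=tier_table,
        gene_links=gene_links,
        report=report,
        enrichment=enrichment,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), meta)
    return result


def _write_outputs(result: PipelineResult, out: Path, meta: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    loci_df = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "lead_id": l.lead.id,
                "chrom": l.lead.chrom,
                "lead_pos": l.lead.pos,
                "lead_p": l.lead.gwas_p,
                "window_start": l.window.start,
                "window_end": l.window.end,
                "n_members": len(l.members),
            }
            for l in result.loci
        ]
    )
    write_table(loci_df, out / "loci.tsv", meta)
    cand_df = pd.DataFrame(
        [
            {"locus_id": lid, "variant_id": v.id, "pos": v.pos, "p": v.gwas_p}
            for lid, vs in sorted(result.candidates.items())
            for v in vs
        ]
    )
    write_table(cand_df, out / "candidates.tsv", meta)
    cs_df = pd.DataFrame(
        [
            {"locus_id": lid, "variant_id": vid}
            for lid, members in sorted(result.credible_sets.items())
            for vid in sorted(members)
        ],
        columns=["locus_id", "variant_id"],
    )
    write_table(cs_df, out / "credible_sets.tsv", meta)
    write_table(result.score_table, out / "scores.tsv", meta)
    write_table(result.total_table, out / "totals.tsv", meta)
    write_table(result.tier_table, out / "tiers.tsv", meta)
    write_table(result.gene_links, out / "gene_links.tsv", meta)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    if result.enrichment:
        enr_df = pd.DataFrame(
            [
                {
                    "analysis": name,
                    "observed": res.observed_tally,
                    "n_perm": res.n_perm,
                    "p_value": res.p_value,
                }
                for name, res in sorted(result.enrichment.items())
            ]
        )
        write_table(enr_df, out / "enrichment.tsv", meta)


def report_summary(
    loci: list[Locus],
    candidates: dict[str, list[Variant]],
    tier_table: pd.DataFrame,
    gene_links: pd.DataFrame,
    genes: list[GeneModel],
) -> dict:
    """Per-locus tier counts plus locus-level gene-link status.

    Reported count types: per-locus Tier 1/2/3 counts, loci lacking Tier 1
    variants, loci lacking both Tier 1 and Tier 2, loci with strong / only
    weak / no gene links, and the fraction of gene links whose gene is the
    closest gene to the linked variant.
    """
    per_locus: dict[str, dict[str, int]] = {}
    for locus in loci:
        grp = tier_table[tier_table["locus_id"] == locus.locus_id]
        counts = grp["tier"].value_counts().to_dict()
        per_locus[locus.locus_id] = {
            "tier1": int(counts.get(1, 0)),
            "tier2": int(counts.get(2, 0)),
            "tier3": int(counts.get(3, 0)),
        }
    no_tier1 = sorted(lid for lid, c in per_locus.items() if c["tier1"] == 0)
    no_tier12 = sorted(
        lid for lid, c in per_locus.items() if c["tier1"] == 0 and c["tier2"] == 0
    )

    status_by_locus: dict[str, str] = {}
    for locus in loci:
        grp = gene_links[gene_links["locus_id"] == locus.locus_id]
        if grp.empty:
            status_by_locus[locus.locus_id] = "none"
        elif (grp["status"] == "strong").any():
            status_by_locus[locus.locus_id] = "strong"
        else:
            status_by_locus[locus.locus_id] = "weak"

    variant_by_id = {v.id: v for vs in candidates.values() for v in vs}
    n_closest = 0
    for row in gene_links.itertuples(index=False):
        v = variant_by_id.get(row.variant_id)
        if v is not None and closest_gene(v, genes) == row.gene_id:
            n_closest += 1
    n_links = len(gene_links)

    tier_totals = tier_table["tier"].value_counts().to_dict()
    return {
        "n_loci": len(loci),
        "n_variants_tiered": int(len(tier_table)),
        "tier_counts": {
            "tier1": int(tier_totals.get(1, 0)),
            "tier2": int(tier_totals.get(2, 0)),
            "tier3": int(tier_totals.get(3, 0)),
        },
        "per_locus": per_locus,
        "loci_without_tier1": no_tier1,
        "n_loci_without_tier1": len(no_tier1),
        "loci_without_tier1_and_tier2": no_tier12,
        "n_loci_without_tier1_and_tier2": len(no_tier12),
        "link_status_counts": {
            s: sum(1 for x in status_by_locus.values() if x == s)
            for s in ("strong", "weak", "none")
        },
        "n_gene_links": n_links,
        "frac_links_closest_gene": (n_closest / n_links) if n_links else None,
    }
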
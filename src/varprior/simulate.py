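"""Synthetic dataset generator with a ground-truth manifest.

Generates every input the pipeline consumes — GWAS summary statistics, LD
summaries, fine-mapping posteriors, per-cell-line peak/segmentation/contact
tracks, MPRA and SMR tables, a 3D-disruption track, TF/ABC score tables,
gene models and a background variant pool — with planted causal variants
whose annotation support is controlled by ``signal_strength`` and a
``background_rate`` for spurious annotations. All files are written in the
declared plain-text formats so every run exercises the real IO paths.

Randomness: every artifact draws from its own named substream of the single
``SimConfig.seed``, so changing one artifact's parameters does not shift the
randomness of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    Interaction,
    Interval,
    ValidationError,
    write_interaction_track,
    write_interval_track,
    write_table,
)

__all__ = ["SimConfig", "TruthManifest", "simulate_dataset", "make_worked_fixture"]

# substream registry: artifact name -> fixed index mixed into the seed
_STREAMS = {
    "layout": 0,
    "alleles": 1,
    "gwas": 2,
    "ld": 3,
    "causal": 4,
    "plant": 5,
    "peaks": 6,
    "chromhmm": 7,
    "microc": 8,
    "mpra": 9,
    "finemap": 10,
    "smr": 11,
    "akita": 12,
    "tf": 13,
    "abc": 14,
    "background": 15,
}

#: Annotation terms planted per cell line vs globally.
_CELL_TERMS = ("MPRA", "CHROMHMM", "ATAC", "CTCF", "MICROC", "ABC", "TF")
_GLOBAL_TERMS = ("FINEMAP", "SMR_NORMAL", "SMR_TUMOR", "AKITA")

_TF_NAMES = ("CTCF", "SP1", "KLF5", "ZNF460", "PRDM9")


@dataclass
class SimConfig:
    n_loci: int = 8
    variants_per_locus: int = 25
    n_cell_lines: int = 4
    n_genes: int = 16
    genome_span_bp: int = 12_000_000
    frac_causal: float = 0.08
    signal_strength: float = 0.9
    background_rate: float = 0.05
    ld_decay_bp: int = 50_000
    n_background: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_loci", "variants_per_locus", "n_cell_lines", "n_genes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("frac_causal", "signal_strength"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.background_rate <= 1.0):
            raise ValidationError("background_rate must be in [0, 1]")
        if self.frac_causal > 0 and self.background_rate >= self.signal_strength:
            raise ValidationError(
                "background_rate must be < signal_strength for recoverable signal"
            )
        if self.n_genes < self.n_loci:
            raise ValidationError("need at least one gene per locus")
        if self.spacing < 600_000:
            raise ValidationError(
                f"genome_span_bp too small for {self.n_loci} loci: inter-locus "
                f"spacing {self.spacing} < 600000"
            )
        if self.variants_per_locus < 4:
            raise ValidationError("need >= 4 variants per locus")

    @property
    def spacing(self) -> int:
        return self.genome_span_bp // (self.n_loci + 1)

    @property
    def n_causal(self) -> int:
        return round(self.frac_causal * self.n_loci * self.variants_per_locus)

    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i + 1:02d}" for i in range(self.n_cell_lines)]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class TruthManifest:
    """Ground truth of the simulation: what was planted where."""

    causal_variants: set[str] = field(default_factory=set)
    target_gene_of: dict[str, str] = field(default_factory=dict)
    # variant -> term -> list of cell lines (or [None] for global terms)
    planted_evidence: dict[str, dict[str, list]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "causal_variants": sorted(self.causal_variants),
            "target_gene_of": dict(sorted(self.target_gene_of.items())),
            "planted_evidence": {
                v: {t: list(cls) for t, cls in sorted(terms.items())}
                for v, terms in sorted(self.planted_evidence.items())
            },
        }


@dataclass
class _SimVariant:
    id: str
    locus_idx: int
    pos: int
    offset: int
    is_lead: bool
    causal: bool = False
    neg_log10_p: float = 1.0
    r2: float = 0.0
    dprime: float = 0.0
    ref: str = "A"
    alt: str = "G"
    mpra_sign: int = 1


_CHROM = "chr1"


def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> tuple[dict, TruthManifest]:
    """Generate all pipeline inputs under ``out_dir``.

    Returns (paths, truth): a dict naming every written file, and the ground
    truth manifest. Fixed seed implies byte-identical files across runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    variants = _layout_variants(cfg)
    _assign_ld(cfg, variants)
    causal = _choose_causal(cfg, variants)
    _assign_gwas_p(cfg, variants)
    genes, target_of_locus, genes_in_locus = _layout_genes(cfg)
    plant = _plant_evidence(cfg, causal)

    truth = TruthManifest()
    for v in causal:
        truth.causal_variants.add(v.id)
        truth.target_gene_of[v.id] = target_of_locus[v.locus_idx]
        truth.planted_evidence[v.id] = {
            term: cls for term, cls in plant[v.id].items() if cls
        }

    paths: dict[str, object] = {}
    paths["gwas"] = _write_gwas(cfg, variants, out)
    paths["ld"] = _write_ld(cfg, variants, out)
    paths["finemap"] = _write_finemap(cfg, variants, plant, out)
    paths["mpra"] = _write_mpra(cfg, variants, plant, out)
    paths["genes"] = _write_genes(genes, out)
    paths["akita"] = _write_akita(cfg, variants, plant, out)
    paths["smr"] = _write_smr(cfg, variants, plant, target_of_locus, genes_in_locus, out)
    paths["abc"] = _write_abc(cfg, variants, plant, target_of_locus, out)
    paths["tf"] = _write_tf(cfg, variants, plant, out)
    paths["tf_sites"] = _write_tf_sites(cfg, variants, plant, out)
    paths["background"] = _write_background(cfg, out)
    paths["atac"], paths["ctcf"] = _write_peaks(cfg, variants, plant, out)
    paths["chromhmm"] = _write_chromhmm(cfg, variants, plant, out)
    paths["microc"] = _write_microc(cfg, variants, plant, target_of_locus, genes, out)

    truth_path = out / "truth.yaml"
    with open(truth_path, "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=True)
    paths["truth"] = str(truth_path)

    def _relative(entry):
        if isinstance(entry, dict):
            return {k: _relative(v) for k, v in entry.items()}
        return str(Path(entry).relative_to(out))

    index = {
        "chrom": _CHROM,
        "cell_lines": cfg.cell_lines,
        "config": {
            k: getattr(cfg, k)
            for k in (
                "n_loci",
                "variants_per_locus",
                "n_cell_lines",
                "n_genes",
                "genome_span_bp",
                "frac_causal",
                "signal_strength",
                "background_rate",
                "ld_decay_bp",
                "n_background",
                "seed",
            )
        },
        "files": {k: _relative(v) for k, v in paths.items()},
    }
    index_path = out / "dataset.yaml"
    with open(index_path, "w") as fh:
        yaml.safe_dump(index, fh, sort_keys=True)
    paths["dataset"] = str(index_path)
    return paths, truth


# ---------------------------------------------------------------------------
# layout, LD, association
# ---------------------------------------------------------------------------


def _locus_center(cfg: SimConfig, i: int) -> int:
    return (i + 1) * cfg.spacing


def _layout_variants(cfg: SimConfig) -> list[_SimVariant]:
    rng = cfg.rng("layout")
    allele_rng = cfg.rng("alleles")
    bases = np.array(["A", "C", "G", "T"])
    variants: list[_SimVariant] = []
    n_close = max(3, int(0.4 * (cfg.variants_per_locus - 1)))
    # variants are kept >= 1.2 kb apart so one variant's planted chromatin
    # features (peaks/segments/anchors, all <= 500 bp half-width) can never
    # bleed onto a neighbour — required for the clean background_rate=0 limit
    min_gap = 1_200
    for i in range(cfg.n_loci):
        center = _locus_center(cfg, i)
        offsets = {0}

        def admit(lo: int, hi: int, target: int) -> None:
            tries = 0
            while len(offsets) < target:
                cand = int(rng.integers(lo, hi + 1))
                if all(abs(cand - o) >= min_gap for o in offsets):
                    offsets.add(cand)
                tries += 1
                if tries > 200 * target:
                    raise ValidationError(
                        "cannot place variants with the required spacing; "
                        "reduce variants_per_locus"
                    )

        # close partners (strong LD, AVS- and causal-eligible)
        admit(-12_000, 12_000, 1 + n_close)
        # spread partners
        admit(-180_000, 180_000, cfg.variants_per_locus)
        ordered = [0] + sorted(o for o in offsets if o != 0)
        for j, off in enumerate(ordered):
            ref, alt = allele_rng.choice(bases, size=2, replace=False)
            variants.append(
                _SimVariant(
                    id=f"v{i:02d}_{j:03d}",
                    locus_idx=i,
                    pos=center + off,
                    offset=off,
                    is_lead=(off == 0),
                    ref=str(ref),
                    alt=str(alt),
                )
            )
    return variants


def _assign_ld(cfg: SimConfig, variants: list[_SimVariant]) -> None:
    rng = cfg.rng("ld")
    for v in variants:
        if v.is_lead:
            v.r2, v.dprime = 1.0, 1.0
            continue
        base = math.exp(-abs(v.offset) / cfg.ld_decay_bp)
        r2 = float(np.clip(base * (1.0 + rng.normal(0.0, 0.04)), 0.0, 1.0))
        dprime = float(np.clip(math.sqrt(r2) + rng.uniform(0.0, 0.08), r2, 1.0))
        v.r2, v.dprime = r2, dprime


def _choose_causal(cfg: SimConfig, variants: list[_SimVariant]) -> list[_SimVariant]:
    rng = cfg.rng("causal")
    n_causal = cfg.n_causal
    if n_causal > len(variants):
        raise ValidationError("more causal variants requested than variants exist")
    by_locus: dict[int, list[_SimVariant]] = {}
    for v in variants:
        if not v.is_lead and abs(v.offset) <= 12_000:
            by_locus.setdefault(v.locus_idx, []).append(v)
    chosen: list[_SimVariant] = []
    # round-robin over loci so the signal is spread
    locus_order = list(range(cfg.n_loci))
    k = 0
    while len(chosen) < n_causal:
        locus = locus_order[k % cfg.n_loci]
        pool = [v for v in by_locus.get(locus, []) if not v.causal]
        if pool:
            pick = pool[int(rng.integers(0, len(pool)))]
            pick.causal = True
            chosen.append(pick)
        k += 1
        if k > 10 * cfg.n_loci * cfg.variants_per_locus:
            raise ValidationError("could not place requested causal variants")
    return chosen


def _assign_gwas_p(cfg: SimConfig, variants: list[_SimVariant]) -> None:
    rng = cfg.rng("gwas")
    lead_strength = {
        i: float(rng.uniform(12.0, 25.0)) for i in range(cfg.n_loci)
    }
    for v in variants:
        u = lead_strength[v.locus_idx]
        if v.is_lead:
            v.neg_log10_p = u
        elif v.causal:
            # guaranteed within three orders of magnitude of the lead
            v.neg_log10_p = u - float(rng.uniform(0.5, 2.5))
        else:
            raw = v.r2 * u * float(rng.uniform(0.70, 0.95))
            v.neg_log10_p = float(np.clip(raw, 0.1, u - 0.25))


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------


def _layout_genes(cfg: SimConfig):
    genes: list[dict] = []
    target_of_locus: dict[int, str] = {}
    genes_in_locus: dict[int, int] = {i: 0 for i in range(cfg.n_loci)}
    for i in range(cfg.n_loci):
        center = _locus_center(cfg, i)
        tss = center + 40_000
        gid = f"G{i:02d}T"
        genes.append(
            {
                "gene_id": gid,
                "chrom": _CHROM,
                "start": tss - 1,
                "end": tss - 1 + 20_000,
                "tss": tss,
                "strand": "+",
            }
        )
        target_of_locus[i] = gid
        genes_in_locus[i] += 1
    extra = cfg.n_genes - cfg.n_loci
    for k in range(extra):
        i = k % cfg.n_loci
        center = _locus_center(cfg, i)
        tss = center - 120_000 - 25_000 * (k // cfg.n_loci)
        genes.append(
            {
                "gene_id": f"G{i:02d}X{k // cfg.n_loci}",
                "chrom": _CHROM,
                "start": tss - 1,
                "end": tss - 1 + 15_000,
                "tss": tss,
                "strand": "+",
            }
        )
        genes_in_locus[i] += 1
    return genes, target_of_locus, genes_in_locus


# ---------------------------------------------------------------------------
# evidence planting
# ---------------------------------------------------------------------------


def _plant_evidence(cfg: SimConfig, causal: list[_SimVariant]) -> dict:
    """Bernoulli(signal_strength) per causal variant per term (per cell line
    for cell-line terms). Returns variant id -> term -> list of planted cell
    lines ([None] for global terms, [] if the term was not planted)."""
    rng = cfg.rng("plant")
    plant: dict[str, dict[str, list]] = {}
    for v in sorted(causal, key=lambda v: v.id):
        terms: dict[str, list] = {}
        for term in _CELL_TERMS:
            terms[term] = [
                cl for cl in cfg.cell_lines if rng.random() < cfg.signal_strength
            ]
        for term in _GLOBAL_TERMS:
            terms[term] = [None] if rng.random() < cfg.signal_strength else []
        plant[v.id] = terms
    return plant


def _planted(plant: dict, vid: str, term: str, cell_line: Optional[str] = None) -> bool:
    terms = plant.get(vid)
    if not terms:
        return False
    cls = terms.get(term, [])
    if cell_line is None:
        return bool(cls)
    return cell_line in cls


# ---------------------------------------------------------------------------
# per-artifact writers
# ---------------------------------------------------------------------------


def _meta(cfg: SimConfig, stream: str) -> dict:
    return {"generator": "varprior.simulate", "seed": cfg.seed, "stream": stream}


def _write_gwas(cfg: SimConfig, variants, out: Path) -> str:
    df = pd.DataFrame(
        {
            "id": [v.id for v in variants],
            "chrom": _CHROM,
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "p": [10.0 ** -v.neg_log10_p for v in variants],
        }
    ).sort_values(["pos", "id"], kind="stable")
    path = out / "gwas.tsv"
    write_table(df, path, _meta(cfg, "gwas"))
    return str(path)


def _write_ld(cfg: SimConfig, variants, out: Path) -> str:
    leads = {v.locus_idx: v.id for v in variants if v.is_lead}
    df = pd.DataFrame(
        {
            "variant_id": [v.id for v in variants],
            "lead_id": [leads[v.locus_idx] for v in variants],
            "r2": [v.r2 for v in variants],
            "dprime": [v.dprime for v in variants],
        }
    ).sort_values("variant_id", kind="stable")
    path = out / "ld.tsv"
    write_table(df, path, _meta(cfg, "ld"))
    return str(path)


def _write_finemap(cfg: SimConfig, variants, plant, out: Path) -> str:
    rng = cfg.rng("finemap")
    rows = []
    by_locus: dict[int, list[_SimVariant]] = {}
    for v in variants:
        by_locus.setdefault(v.locus_idx, []).append(v)
    for i in sorted(by_locus):
        members = by_locus[i]
        planted = [v for v in members if _planted(plant, v.id, "FINEMAP")]
        others = [v for v in members if v not in planted]
        pips: dict[str, float] = {}
        if planted:
            share = 0.97 / len(planted)
            for v in planted:
                pips[v.id] = share
        for v in others:
            if rng.random() < cfg.background_rate:
                pips[v.id] = float(rng.uniform(0.002, 0.02))
            else:
                pips[v.id] = float(rng.uniform(0.0, 0.0008))
        total = sum(pips.values())
        if total > 1.0:  # keep per-locus posterior mass valid
            scale = 0.999 / total
            pips = {k: p * scale for k, p in pips.items()}
        for v in members:
            rows.append({"variant_id": v.id, "pip": pips[v.id]})
    df = pd.DataFrame(rows).sort_values("variant_id", kind="stable")
    path = out / "finemap.tsv"
    write_table(df, path, _meta(cfg, "finemap"))
    return str(path)


def _write_mpra(cfg: SimConfig, variants, plant, out: Path) -> str:
    rng = cfg.rng("mpra")
    rows = []
    for v in variants:
        v.mpra_sign = 1 if rng.random() < 0.5 else -1
        for cl in cfg.cell_lines:
            if _planted(plant, v.id, "MPRA", cl):
                fdr = 10.0 ** -float(rng.uniform(3.5, 6.0))
                log_ratio = v.mpra_sign * float(rng.uniform(0.5, 1.5))
            elif rng.random() < cfg.background_rate:
                fdr = float(rng.uniform(2e-3, 0.045))
                log_ratio = (1 if rng.random() < 0.5 else -1) * float(
                    rng.uniform(0.1, 0.5)
                )
            else:
                fdr = float(rng.uniform(0.2, 1.0))
                log_ratio = float(rng.normal(0.0, 0.1))
            rows.append(
                {
                    "variant_id": v.id,
                    "cell_line": cl,
                    "log_ratio": log_ratio,
                    "fdr": fdr,
                }
            )
    df = pd.DataFrame(rows).sort_values(["variant_id", "cell_line"], kind="stable")
    path = out / "mpra.tsv"
    write_table(df, path, _meta(cfg, "mpra"))
    return str(path)


def _write_genes(genes, out: Path) -> str:
    df = pd.DataFrame(genes).sort_values("gene_id", kind="stable")
    path = out / "genes.tsv"
    write_table(df, path, {"generator": "varprior.simulate"})
    return str(path)


def _write_akita(cfg: SimConfig, variants, plant, out: Path) -> str:
    """Disruption track built so that planted neighbourhoods are guaranteed in
    the global top decile and unplanted ones are guaranteed below the hit
    threshold: background in (0.02, 0.40), decoy elevated blocks (away from
    all variants) in (0.80, 0.95), planted windows in (0.96, 1.0). Decoy
    blocks contribute ~1/3 of positions so the 80th/90th percentiles always
    land in the elevated range."""
    rng = cfg.rng("akita")
    scores: dict[int, float] = {}
    for i in range(cfg.n_loci):
        center = _locus_center(cfg, i)
        for pos in range(center - 200_000, center + 200_001, 50):
            scores[pos] = float(rng.uniform(0.02, 0.40))
        for pos in range(center + 205_000, center + 245_001, 10):
            scores[pos] = float(rng.uniform(0.80, 0.95))
    for v in variants:
        if _planted(plant, v.id, "AKITA"):
            for pos in range(v.pos - 100, v.pos + 101, 25):
                scores[pos] = float(rng.uniform(0.96, 1.0))
        elif rng.random() < cfg.background_rate:
            for pos in range(v.pos - 100, v.pos + 101, 25):
                scores[pos] = float(rng.uniform(0.85, 0.95))
    df = pd.DataFrame(
        {"chrom": _CHROM, "pos": sorted(scores), "score": [scores[p] for p in sorted(scores)]}
    )
    path = out / "akita.tsv"
    write_table(df, path, _meta(cfg, "akita"))
    return str(path)


def _write_smr(cfg: SimConfig, variants, plant, target_of_locus, genes_in_locus, out: Path) -> str:
    rng = cfg.rng("smr")
    rows = []
    for v in variants:
        locus_id = f"L{v.locus_idx + 1:03d}"
        n_genes = max(1, genes_in_locus[v.locus_idx])
        for tissue, term in (("normal", "SMR_NORMAL"), ("tumor", "SMR_TUMOR")):
            if _planted(plant, v.id, term):
                rows.append(
                    {
                        "gene_id": target_of_locus[v.locus_idx],
                        "variant_id": v.id,
                        "locus_id": locus_id,
                        "tissue": tissue,
                        "p_smr": float(rng.uniform(1e-5, 0.04)) / n_genes,
                        "p_heidi": float(rng.uniform(0.1, 0.9)),
                        "beta": v.mpra_sign * float(rng.uniform(0.2, 0.8)),
                    }
                )
            elif rng.random() < cfg.background_rate:
                rows.append(
                    {
                        "gene_id": target_of_locus[v.locus_idx],
                        "variant_id": v.id,
                        "locus_id": locus_id,
                        "tissue": tissue,
                        "p_smr": float(rng.uniform(1e-4, 0.04)) / n_genes,
                        "p_heidi": float(rng.uniform(0.1, 0.9)),
                        "beta": float(rng.normal(0.0, 0.3)),
                    }
                )
    # decoys exercising each filter: HEIDI failure and Bonferroni failure
    for i in range(cfg.n_loci):
        lead_id = f"v{i:02d}_000"
        locus_id = f"L{i + 1:03d}"
        rows.append(
            {
                "gene_id": target_of_locus[i],
                "variant_id": lead_id,
                "locus_id": locus_id,
                "tissue": "normal",
                "p_smr": float(rng.uniform(1e-5, 1e-3)),
                "p_heidi": float(rng.uniform(0.001, 0.04)),
                "beta": float(rng.normal(0.0, 0.3)),
            }
        )
        rows.append(
            {
                "gene_id": target_of_locus[i],
                "variant_id": lead_id,
                "locus_id": locus_id,
                "tissue": "tumor",
                "p_smr": float(rng.uniform(0.3, 0.9)),
                "p_heidi": float(rng.uniform(0.1, 0.9)),
                "beta": float(rng.normal(0.0, 0.3)),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["locus_id", "variant_id", "tissue", "gene_id"], kind="stable"
    )
    path = out / "smr.tsv"
    write_table(df, path, _meta(cfg, "smr"))
    return str(path)


def _decoy_scores(rng: np.random.Generator, n: int, prefix: str, cell_line: str):
    return [
        {"variant_id": f"{prefix}{k:04d}", "cell_line": cell_line,
         "score": float(rng.uniform(0.0, 0.5))}
        for k in range(n)
    ]


def _write_abc(cfg: SimConfig, variants, plant, target_of_locus, out: Path) -> str:
    rng = cfg.rng("abc")
    n_decoy = max(200, 15 * max(1, cfg.n_causal))
    rows = []
    for cl in cfg.cell_lines:
        for d in _decoy_scores(rng, n_decoy, "site", cl):
            d["gene_id"] = "Gdecoy"
            rows.append(d)
        for v in variants:
            if _planted(plant, v.id, "ABC", cl):
                rows.append(
                    {
                        "variant_id": v.id,
                        "cell_line": cl,
                        "gene_id": target_of_locus[v.locus_idx],
                        "score": float(rng.uniform(0.9, 1.0)),
                    }
                )
            elif rng.random() < cfg.background_rate:
                rows.append(
                    {
                        "variant_id": v.id,
                        "cell_line": cl,
                        "gene_id": target_of_locus[v.locus_idx],
                        "score": float(rng.uniform(0.4, 0.6)),
                    }
                )
    df = pd.DataFrame(rows)[["variant_id", "gene_id", "cell_line", "score"]].sort_values(
        ["variant_id", "cell_line", "gene_id"], kind="stable"
    )
    path = out / "abc.tsv"
    write_table(df, path, _meta(cfg, "abc"))
    return str(path)


def _write_tf(cfg: SimConfig, variants, plant, out: Path) -> str:
    rng = cfg.rng("tf")
    n_decoy = max(200, 15 * max(1, cfg.n_causal))
    rows = []
    for cl in cfg.cell_lines:
        for d in _decoy_scores(rng, n_decoy, "site", cl):
            d["tf"] = _TF_NAMES[int(rng.integers(0, len(_TF_NAMES)))]
            rows.append(d)
        for v in variants:
            if _planted(plant, v.id, "TF", cl):
                rows.append(
                    {
                        "variant_id": v.id,
                        "cell_line": cl,
                        "tf": _TF_NAMES[v.locus_idx % len(_TF_NAMES)],
                        "score": float(rng.uniform(0.9, 1.0)),
                    }
                )
            elif rng.random() < cfg.background_rate:
                rows.append(
                    {
                        "variant_id": v.id,
                        "cell_line": cl,
                        "tf": _TF_NAMES[int(rng.integers(0, len(_TF_NAMES)))],
                        "score": float(rng.uniform(0.4, 0.6)),
                    }
                )
    df = pd.DataFrame(rows)[["variant_id", "cell_line", "tf", "score"]].sort_values(
        ["variant_id", "cell_line", "tf"], kind="stable"
    )
    path = out / "tf.tsv"
    write_table(df, path, _meta(cfg, "tf"))
    return str(path)


def _write_tf_sites(cfg: SimConfig, variants, plant, out: Path) -> str:
    sites = []
    for v in variants:
        for cl in cfg.cell_lines:
            if _planted(plant, v.id, "TF", cl):
                sites.append(
                    Interval(
                        _CHROM,
                        v.pos - 1 - 100,
                        v.pos + 100,
                        label=_TF_NAMES[v.locus_idx % len(_TF_NAMES)],
                    )
                )
                break
    sites.sort(key=lambda iv: (iv.chrom, iv.start))
    path = out / "tf_sites.bed"
    write_interval_track(sites, path, "bed4_label")
    return str(path)


def _write_background(cfg: SimConfig, out: Path) -> str:
    rng = cfg.rng("background")
    pos = np.sort(
        rng.choice(
            np.arange(10_000, cfg.genome_span_bp - 10_000),
            size=cfg.n_background,
            replace=False,
        )
    )
    df = pd.DataFrame(
        {
            "id": [f"bg{k:04d}" for k in range(cfg.n_background)],
            "chrom": _CHROM,
            "pos": pos.astype(int),
            "p": rng.uniform(0.5, 1.0, size=cfg.n_background),
        }
    )
    path = out / "background.tsv"
    write_table(df, path, _meta(cfg, "background"))
    return str(path)


def _write_peaks(cfg: SimConfig, variants, plant, out: Path):
    rng = cfg.rng("peaks")
    atac_paths: dict[str, str] = {}
    ctcf_paths: dict[str, str] = {}
    for term, store, fname in (("ATAC", atac_paths, "atac"), ("CTCF", ctcf_paths, "ctcf")):
        for cl in cfg.cell_lines:
            peaks = []
            for v in variants:
                if _planted(plant, v.id, term, cl) or (
                    rng.random() < cfg.background_rate
                ):
                    half = int(rng.integers(100, 250))
                    peaks.append(Interval(_CHROM, v.pos - 1 - half, v.pos - 1 + half + 1))
            # decoy peaks in variant-free territory between loci
            for i in range(cfg.n_loci):
                center = _locus_center(cfg, i)
                start = center + 300_000 + int(rng.integers(0, 50_000))
                peaks.append(Interval(_CHROM, start, start + 400))
            peaks.sort(key=lambda iv: (iv.chrom, iv.start))
            path = out / f"{fname}_{cl}.bed"
            write_interval_track(peaks, path, "bed3")
            store[cl] = str(path)
    return atac_paths, ctcf_paths


def _paint(span: int, layers: list[tuple[list[Interval], str]]) -> list[Interval]:
    """Tile [0, span) with labels; later layers override earlier ones."""
    points = {0, span}
    for ivs, _ in layers:
        for iv in ivs:
            points.add(max(0, iv.start))
            points.add(min(span, iv.end))
    bounds = sorted(points)
    out: list[Interval] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a >= b:
            continue
        mid = (a + b) // 2
        label = "Quies"
        for ivs, lbl in layers:
            if any(iv.start <= mid < iv.end for iv in ivs):
                label = lbl
        out.append(Interval(_CHROM, a, b, label=label))
    # merge adjacent same-label segments for compactness
    merged: list[Interval] = []
    for seg in out:
        if merged and merged[-1].label == seg.label and merged[-1].end == seg.start:
            merged[-1] = Interval(_CHROM, merged[-1].start, seg.end, label=seg.label)
        else:
            merged.append(seg)
    return merged


def _write_chromhmm(cfg: SimConfig, variants, plant, out: Path) -> dict[str, str]:
    rng = cfg.rng("chromhmm")
    paths: dict[str, str] = {}
    for cl in cfg.cell_lines:
        weak, strong = [], []
        for v in variants:
            if _planted(plant, v.id, "CHROMHMM", cl):
                strong.append(Interval(_CHROM, max(0, v.pos - 1 - 500), v.pos + 500))
            elif rng.random() < cfg.background_rate:
                weak.append(Interval(_CHROM, max(0, v.pos - 1 - 500), v.pos + 500))
        segments = _paint(cfg.genome_span_bp, [(weak, "EnhWk"), (strong, "EnhA")])
        path = out / f"chromhmm_{cl}.bed"
        write_interval_track(segments, path, "bed4_label")
        paths[cl] = str(path)
    return paths


def _write_microc(cfg: SimConfig, variants, plant, target_of_locus, genes, out: Path):
    rng = cfg.rng("microc")
    gene_by_id = {g["gene_id"]: g for g in genes}
    paths: dict[str, str] = {}
    for cl in cfg.cell_lines:
        contacts: list[Interaction] = []
        for v in variants:
            anchor_v = Interval(_CHROM, max(0, v.pos - 1 - 500), v.pos + 500)
            if _planted(plant, v.id, "MICROC", cl):
                g = gene_by_id[target_of_locus[v.locus_idx]]
                tss0 = g["tss"] - 1
                anchor_g = Interval(_CHROM, tss0 - 500, tss0 + 501)
                contacts.append(
                    Interaction(anchor_v, anchor_g, 2.0 + float(rng.exponential(2.0)))
                )
            elif rng.random() < cfg.background_rate:
                # gene-body (non-TSS) contact: a weak hit by construction
                g = gene_by_id[target_of_locus[v.locus_idx]]
                body_mid = g["start"] + 8_000
                anchor_g = Interval(_CHROM, body_mid, body_mid + 1_000)
                contacts.append(
                    Interaction(anchor_v, anchor_g, 2.0 + float(rng.exponential(1.0)))
                )
            elif rng.random() < 0.05:
                # sub-threshold decoy, must be ignored by the significance filter
                far = Interval(_CHROM, v.pos + 50_000, v.pos + 51_000)
                contacts.append(Interaction(anchor_v, far, float(rng.uniform(0.0, 1.9))))
        contacts.sort(key=lambda x: (x.anchor_a.start, x.anchor_b.start))
        path = out / f"microc_{cl}.tsv"
        write_interaction_track(contacts, path)
        paths[cl] = str(path)
    return paths


# ---------------------------------------------------------------------------
# worked fixture
# ---------------------------------------------------------------------------


def make_worked_fixture(out_dir: str | Path, seed: int = 20_240_901):
    """A 3-locus dataset in which one fully-annotated variant per locus
    dominates its locus (strong MPRA, open chromatin, TSS contact, TF
    binding) while partners carry partial annotations — so tiering makes the
    annotated variant Tier 1 and gene linking recovers its planted target."""
    cfg = SimConfig(
        n_loci=3,
        variants_per_locus=5,
        n_cell_lines=4,
        n_genes=6,
        genome_span_bp=4_000_000,
        frac_causal=0.2,
        signal_strength=1.0,
        background_rate=0.25,
        n_background=200,
        seed=seed,
    )
    paths, truth = simulate_dataset(cfg, out_dir)
    return cfg, paths, truth
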
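# varprior

Integrative prioritization of functional variants and effector genes at GWAS
risk loci.

The package implements, as a tested and reusable pipeline:

- **Risk-locus definition** — greedy distance clumping of genome-wide
  significant variants (P < 5×10⁻⁸, leads ≥ 500 kb apart, ±250 kb windows).
- **Candidate-variant selection** — variants within three orders of magnitude
  of the lead P, or rescued by
  −log₁₀(P) > 0.7 × −log₁₀(P_lead) with r² > 0.2 and P < 10⁻⁵.
- **Credible sets** — ranked-PIP prefix reaching 0.95 coverage with a
  minimum per-variant PIP of 0.001.
- **Annotation scoring** — per-variant, per-annotation, per-cell-line scores
  in {0, 1, 2} over MPRA FDR, fine-mapping PIP/credible-set membership,
  chromatin states, ATAC/CTCF peaks, SMR links (normal and tumor), 3D
  disruption neighbourhoods, and significant long-range contacts.
- **Consensus and tiering** — strict-majority consensus across cell lines for
  track-based terms, binomial-tail consensus for rank-based analyses
  (ABC, TF), summed scores, and Tier 1/2/3 bands (top 20% / middle /
  bottom 50%, ties promoted to the better tier).
- **Gene nomination** — strong links from ≥ 2 evidence sources
  (SMR normal/tumor, ABC, contact-to-TSS) over Tier 1 variants, with
  ordered fallbacks: contact-to-gene-body, Tier 2 variants, intronic host
  gene.
- **Permutation enrichment** — associated-variant-set (r² ≥ 0.8, D′ ≥ 0.8)
  peak-overlap enrichment and bound-TF count enrichment, both with
  size-matched null draws and plain proportion-based empirical p-values.
- **Synthetic data** — a generator that emulates every input format with
  planted causal variants, configurable signal strength, and a ground-truth
  manifest, so the whole chain is testable with no external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact oracles for
the binomial consensus and credible sets, tiering quantile properties,
permutation-p calibration under a true null, and planted-signal recovery).

## CLI

```sh
# generate a synthetic dataset with ground truth
varprior simulate --seed 1 --out sim/

# run the whole chain: loci -> candidates -> credible sets -> scores ->
# consensus -> tiers -> gene links -> report
varprior run-all --dataset sim/ --seed 1 --out run/

# individual stages
varprior define-loci --gwas sim/gwas.tsv --out loci.tsv
varprior select-variants --gwas sim/gwas.tsv --ld sim/ld.tsv --out cand.tsv
varprior credible-sets --finemap sim/finemap.tsv --out cs.tsv
varprior tier --totals run/totals.tsv --out tiers.tsv
varprior enrich --dataset sim/ --kind avs --n-perm 2000 --seed 1 --out enr.tsv
```

All interval inputs are BED-style (0-based half-open); variant positions are
1-based points; contact files are 7-column BEDPE-like
(chromA startA endA chromB startB endB neg_log10_p). Output tables are TSV
with `#`-prefixed metadata lines recording version, config hash and seed.
Fixed seeds give byte-identical outputs.

## Layout

```
src/varprior/core.py        domain types, coordinate bridge, track IO
src/varprior/loci.py        locus definition, candidate selection, credible sets
src/varprior/scoring.py     the eight annotation scorers + ScoringConfig
src/varprior/consensus.py   majority/binomial consensus, summing, tiers
src/varprior/genes.py       SMR filters, concordance, gene nomination
src/varprior/enrichment.py  AVS and TF-count permutation tests
src/varprior/simulate.py    synthetic data generator + truth manifest
src/varprior/pipeline.py    dataset loading and run-all orchestration
src/varprior/cli.py         click CLI
```
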
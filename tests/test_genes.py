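import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varprior.core import GeneModel, Interval, ValidationError, Variant
from varprior.genes import (
    GeneLink,
    SMRRecord,
    closest_gene,
    direction_concordance,
    eqtl_bonferroni_threshold,
    filter_smr,
    harmonize_beta,
    nominate_genes,
    truncate_significant,
)
from varprior.scoring import MPRARecord


def smr(p_smr, p_heidi, gene="g1", variant="v1", locus="L1", tissue="normal", beta=0.3):
    return SMRRecord(gene, variant, locus, tissue, p_smr, p_heidi, beta)


class TestFilterSMR:
    def test_bonferroni_pass(self):
        assert filter_smr([smr(0.01, 0.2)], {"L1": 4}) == {("v1", "g1", "normal")}

    def test_bonferroni_fail(self):
        assert filter_smr([smr(0.02, 0.2)], {"L1": 4}) == set()

    def test_heidi_fail(self):
        assert filter_smr([smr(0.001, 0.01)], {"L1": 4}) == set()

    def test_missing_locus_rejected_with_warning(self, caplog):
        assert filter_smr([smr(0.001, 0.5, locus="L9")], {"L1": 4}) == set()

    @given(
        p_smr=st.floats(1e-8, 1.0),
        p_heidi=st.floats(1e-8, 1.0),
        delta=st.floats(0.0, 0.5),
    )
    @settings(max_examples=150)
    def test_monotone(self, p_smr, p_heidi, delta):
        base = filter_smr([smr(p_smr, p_heidi)], {"L1": 3})
        better_smr = max(1e-9, p_smr - delta * p_smr)
        better_heidi = min(1.0, p_heidi + delta)
        improved = filter_smr([smr(better_smr, better_heidi)], {"L1": 3})
        if base:
            assert improved  # improving either P never turns a pass into a fail


class TestBonferroniThreshold:
    def test_paper_family_size(self):
        thr = eqtl_bonferroni_threshold(665, 0.05)
        assert thr == pytest.approx(7.5188e-5, rel=1e-4)
        assert truncate_significant(thr, 3) == pytest.approx(7.51e-5, rel=1e-12)

    def test_identity(self):
        assert eqtl_bonferroni_threshold(1, 0.05) == 0.05

    def test_hundred(self):
        assert eqtl_bonferroni_threshold(100, 0.05) == pytest.approx(5e-4)

    def test_zero_genes_error(self):
        with pytest.raises(ValueError):
            eqtl_bonferroni_threshold(0)

    def test_truncation_truncates_not_rounds(self):
        assert truncate_significant(0.0999, 2) == pytest.approx(0.099)
        assert truncate_significant(1999.0, 3) == pytest.approx(1990.0)


class TestDirectionConcordance:
    def _mpra(self, lr):
        return MPRARecord("v1", "HT29", lr, 0.01)

    def test_same_sign(self):
        assert direction_concordance(self._mpra(0.8), smr(0.01, 0.5, beta=0.3))

    def test_opposite_sign(self):
        assert not direction_concordance(self._mpra(0.8), smr(0.01, 0.5, beta=-0.3))

    def test_harmonization_flip(self):
        # eQTL effect reported for the MPRA reference allele: flip, then concordant
        beta = harmonize_beta(-0.3, eqtl_effect_allele="A", mpra_ref="A", mpra_alt="G")
        assert beta == 0.3
        assert direction_concordance(self._mpra(0.8), smr(0.01, 0.5, beta=beta))

    def test_harmonize_no_flip(self):
        assert harmonize_beta(0.4, "G", "A", "G") == 0.4

    def test_harmonize_unknown_allele(self):
        with pytest.raises(ValidationError):
            harmonize_beta(0.4, "T", "A", "G")

    def test_zero_effect_is_false(self, caplog):
        assert not direction_concordance(self._mpra(0.0), smr(0.01, 0.5, beta=0.3))


GENES = [
    GeneModel("gA", "chr1", Interval("chr1", 900, 2000), tss_pos=1000),
    GeneModel("gB", "chr1", Interval("chr1", 5_000, 9_000), tss_pos=5_001),
]


def _nominate(tiers, evidence, microc_body=None, variants=None, **kw):
    return nominate_genes(
        tiers=tiers,
        variant_locus={v: "L1" for v in tiers},
        evidence=evidence,
        microc_body=microc_body or set(),
        genes=GENES,
        variants=variants or {},
        **kw,
    )


class TestNominateGenes:
    def test_two_sources_strong(self):
        links = _nominate(
            {"v1": 1},
            {"SMR_NORMAL": {("v1", "gA")}, "MICROC_TSS": {("v1", "gA")}},
        )
        (l,) = links
        assert l.status == "strong" and l.evidence == {"SMR_NORMAL", "MICROC_TSS"}

    def test_single_source_not_strong_body_fallback(self):
        links = _nominate(
            {"v1": 1},
            {"ABC": {("v1", "gA")}},
            microc_body={("v1", "gB")},
        )
        (l,) = links
        assert l.status == "weak" and l.fallback_used == "microc_body" and l.gene_id == "gB"

    def test_tier2_fallback_when_no_tier1(self):
        links = _nominate(
            {"v1": 2},
            {"SMR_NORMAL": {("v1", "gA")}, "ABC": {("v1", "gA")}},
        )
        (l,) = links
        assert l.status == "weak" and l.fallback_used == "tier2"
        assert l.evidence == {"SMR_NORMAL", "ABC"}

    def test_intronic_fallback(self):
        v = Variant("v1", "chr1", 1500)  # inside gA body
        links = _nominate({"v1": 1}, {}, variants={"v1": v})
        (l,) = links
        assert l.status == "weak" and l.fallback_used == "intronic" and l.gene_id == "gA"

    def test_no_link_is_legitimate(self):
        v = Variant("v1", "chr1", 100_000)  # in no gene body
        assert _nominate({"v1": 1}, {}, variants={"v1": v}) == []

    def test_fallback_order_body_preempts_intronic(self):
        v = Variant("v1", "chr1", 1500)
        links = _nominate({"v1": 1}, {}, microc_body={("v1", "gB")}, variants={"v1": v})
        (l,) = links
        assert l.fallback_used == "microc_body"

    def test_strong_preempts_all_fallbacks(self):
        v = Variant("v1", "chr1", 1500)
        links = _nominate(
            {"v1": 1},
            {"SMR_NORMAL": {("v1", "gA")}, "SMR_TUMOR": {("v1", "gA")}},
            microc_body={("v1", "gB")},
            variants={"v1": v},
        )
        assert [l.status for l in links] == ["strong"]

    def test_evidence_unioned_across_tier1_variants(self):
        links = _nominate(
            {"v1": 1, "v2": 1},
            {"SMR_NORMAL": {("v1", "gA")}, "MICROC_TSS": {("v2", "gA")}},
        )
        (l,) = links
        assert l.status == "strong"

    def test_same_variant_strictness(self):
        links = _nominate(
            {"v1": 1, "v2": 1},
            {"SMR_NORMAL": {("v1", "gA")}, "MICROC_TSS": {("v2", "gA")}},
            same_variant=True,
        )
        assert links == []

    def test_tier3_never_considered(self):
        links = _nominate(
            {"v1": 3},
            {"SMR_NORMAL": {("v1", "gA")}, "MICROC_TSS": {("v1", "gA")}},
        )
        assert links == []

    def test_row_order_independence(self):
        ev1 = {"SMR_NORMAL": {("v1", "gA"), ("v2", "gB")}, "ABC": {("v2", "gB"), ("v1", "gA")}}
        ev2 = {"ABC": {("v1", "gA"), ("v2", "gB")}, "SMR_NORMAL": {("v2", "gB"), ("v1", "gA")}}
        a = _nominate({"v1": 1, "v2": 1}, ev1)
        b = _nominate({"v1": 1, "v2": 1}, ev2)
        assert a == b

    def test_unknown_evidence_source_rejected(self):
        with pytest.raises(ValueError):
            _nominate({"v1": 1}, {"NOT_A_SOURCE": {("v1", "gA")}})

    def test_strong_link_invariant_enforced(self):
        with pytest.raises(ValidationError):
            GeneLink("g", "L1", "v", frozenset({"ABC"}), "strong")
        with pytest.raises(ValidationError):
            GeneLink("g", "L1", "v", frozenset(), "weak", fallback_used=None)


class TestClosestGene:
    def test_nearest_tss(self):
        v = Variant("v", "chr1", 4_000)
        assert closest_gene(v, GENES) == "gB"

    def test_no_gene_on_chrom(self):
        assert closest_gene(Variant("v", "chr9", 4_000), GENES) is None
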
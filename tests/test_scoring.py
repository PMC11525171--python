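import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varprior.core import GeneModel, Interaction, Interval, ValidationError, Variant
from varprior.loci import FineMapRecord
from varprior.scoring import (
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

CFG = ScoringConfig()


class TestMPRA:
    @pytest.mark.parametrize(
        "fdr,expected",
        [
            (5e-4, 2),
            (1e-3, 2),  # strong boundary inclusive
            (0.05, 1),  # hit boundary inclusive
            (0.002, 1),
            (0.2, 0),
            (1.0, 0),
        ],
    )
    def test_thresholds(self, fdr, expected):
        assert score_mpra(MPRARecord("v", "HT29", 0.5, fdr), CFG).value == expected

    def test_cell_line_carried(self):
        s = score_mpra(MPRARecord("v", "SW403", -0.2, 0.5), CFG)
        assert s.cell_line == "SW403" and s.term == "MPRA"

    @given(a=st.floats(1e-12, 1.0), b=st.floats(1e-12, 1.0))
    def test_monotone_in_fdr(self, a, b):
        lo, hi = sorted([a, b])
        s_lo = score_mpra(MPRARecord("v", "c", 0.1, lo), CFG).value
        s_hi = score_mpra(MPRARecord("v", "c", 0.1, hi), CFG).value
        assert s_lo >= s_hi


class TestFinemap:
    def test_strong(self):
        assert score_finemap(FineMapRecord("v", 0.7), True, CFG).value == 2

    def test_hit_via_set_membership(self):
        assert score_finemap(FineMapRecord("v", 0.1), True, CFG).value == 1

    def test_no_hit(self):
        assert score_finemap(FineMapRecord("v", 0.0004), False, CFG).value == 0

    def test_membership_not_pip_decides_hit(self):
        # pip > 0 but outside the set: the default (credible-set) reading is 0
        assert score_finemap(FineMapRecord("v", 0.2), False, CFG).value == 0

    def test_literal_pip_switch(self):
        cfg = ScoringConfig(finemap_literal_pip=True)
        assert score_finemap(FineMapRecord("v", 0.2), False, cfg).value == 1
        assert score_finemap(FineMapRecord("v", 0.0), False, cfg).value == 0


class TestChromHMM:
    SEGS = [
        Interval("chr1", 0, 100, label="EnhA"),
        Interval("chr1", 100, 200, label="EnhWk"),
        Interval("chr1", 200, 300, label="Quies"),
    ]

    @pytest.mark.parametrize("pos,expected", [(50, 2), (150, 1), (250, 0)])
    def test_state_mapping(self, pos, expected):
        v = Variant("v", "chr1", pos)
        assert score_chromhmm(v, self.SEGS, CFG, "CL01").value == expected

    def test_uncovered_scores_zero(self, caplog):
        v = Variant("v", "chr1", 9999)
        assert score_chromhmm(v, self.SEGS, CFG, "CL01").value == 0

    def test_unmapped_label_scores_zero(self):
        segs = [Interval("chr1", 0, 100, label="MysteryState")]
        assert score_chromhmm(Variant("v", "chr1", 50), segs, CFG, "CL01").value == 0


class TestPeakOverlap:
    PEAKS = [Interval("chr1", 100, 200)]

    def test_inside(self):
        assert score_peak_overlap(Variant("v", "chr1", 150), self.PEAKS, "ATAC", "c").value == 2

    def test_outside(self):
        assert score_peak_overlap(Variant("v", "chr1", 500), self.PEAKS, "CTCF", "c").value == 0

    def test_half_open_end(self):
        # 1-based 201 is 0-based 200 == end -> outside
        assert score_peak_overlap(Variant("v", "chr1", 201), self.PEAKS, "ATAC", "c").value == 0

    def test_never_one(self):
        for pos in (1, 101, 150, 200, 201, 999):
            assert score_peak_overlap(
                Variant("v", "chr1", pos), self.PEAKS, "ATAC", "c"
            ).value in (0, 2)

    def test_bad_term(self):
        with pytest.raises(ValueError):
            score_peak_overlap(Variant("v", "chr1", 1), [], "MPRA", "c")


class TestSMR:
    LINKS_NORMAL = {("v1", "g1")}
    LINKS_TUMOR = {("v2", "g2")}

    def test_normal_link(self):
        assert score_smr("v1", self.LINKS_NORMAL, "normal").value == 2

    def test_tissue_separation(self):
        assert score_smr("v2", self.LINKS_NORMAL, "normal").value == 0
        assert score_smr("v2", self.LINKS_TUMOR, "tumor").value == 2

    def test_no_links(self):
        assert score_smr("v9", set(), "normal").value == 0


def akita_oracle(v, positions, scores, cfg=CFG):
    """Independent full-scan oracle: sorts all scores to find the inclusive
    top-decile cut-offs, then walks every position to build the window."""
    n = len(scores)
    ranked = sorted(scores)

    def quant(q):  # numpy 'linear' quantile, reimplemented by hand
        h = (n - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return ranked[lo] + (h - lo) * (ranked[hi] - ranked[lo])

    window = [s for p, s in zip(positions, scores) if abs(p - v.pos) <= cfg.akita_window_bp]
    if not window:
        return 0
    f90 = sum(s >= quant(1 - cfg.akita_top_strong) for s in window) / len(window)
    f80 = sum(s >= quant(1 - cfg.akita_top_hit) for s in window) / len(window)
    if f90 > cfg.akita_frac:
        return 2
    if f80 > cfg.akita_frac:
        return 1
    return 0


class TestAkita:
    def test_strong_fraction(self):
        # 2000 positions 1..2000; window = 1..201 around pos 101 (201 scored).
        # 60 of them carry top-decile scores -> f90 ~ 0.299 > 0.25 -> 2
        positions = list(range(1, 2001))
        scores = [0.1] * 2000
        for i in range(60):
            scores[i] = 10.0
        for i in range(1800, 1940):  # pad the global top decile (200 total)
            scores[i] = 10.0
        track = DisruptionTrack("chr1", positions, scores)
        v = Variant("v", "chr1", 101)
        assert score_akita(v, track, CFG).value == 2
        assert akita_oracle(v, positions, scores) == 2

    def test_hit_only_fraction(self):
        # top 10% = scores >= 9; top 20% includes 5s; window has 10% nines
        # and 30% fives -> f90 = 0.10, f80 = 0.40 > 0.25 -> score 1
        positions = list(range(1, 1001))
        scores = [0.1] * 1000
        window_idx = list(range(0, 201))  # pos 1..201, variant at 101
        for i in window_idx[:20]:
            scores[i] = 10.0
        for i in window_idx[20:80]:
            scores[i] = 5.0
        for i in range(800, 880):
            scores[i] = 10.0
        for i in range(880, 1000):
            scores[i] = 5.0
        track = DisruptionTrack("chr1", positions, scores)
        v = Variant("v", "chr1", 101)
        got = score_akita(v, track, CFG).value
        assert got == akita_oracle(v, positions, scores) == 1

    def test_all_below(self):
        positions = list(range(1, 1001))
        scores = [0.1] * 500 + [5.0] * 500
        track = DisruptionTrack("chr1", positions, scores)
        v = Variant("v", "chr1", 101)  # window entirely in the 0.1 region
        assert score_akita(v, track, CFG).value == 0

    def test_empty_window_scores_zero(self):
        track = DisruptionTrack("chr1", [5000], [1.0])
        assert score_akita(Variant("v", "chr1", 100), track, CFG).value == 0

    def test_missing_track_scores_zero(self):
        assert score_akita(Variant("v", "chr1", 100), None, CFG).value == 0

    def test_matches_oracle_on_random_tracks(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 400))
            positions = np.sort(rng.choice(np.arange(1, 10_001), size=n, replace=False))
            scores = rng.uniform(0, 1, size=n)
            track = DisruptionTrack("chr1", positions, scores)
            pos = int(rng.integers(1, 10_001))
            v = Variant("v", "chr1", pos)
            assert (
                score_akita(v, track, CFG).value
                == akita_oracle(v, list(positions), list(scores))
            )

    def test_track_invariants(self):
        with pytest.raises(ValidationError):
            DisruptionTrack("chr1", [1, 1], [0.5, 0.5])
        with pytest.raises(ValidationError):
            DisruptionTrack("chr1", [1, 2], [0.5, -0.5])


def _gene(gid="g1", tss=50_001, start=50_000, end=70_000):
    return GeneModel(gid, "chr1", Interval("chr1", start, end), tss_pos=tss)


class TestMicroC:
    V = Variant("v", "chr1", 500)

    def _interaction(self, b_start, b_end, nlp=3.0, swap=False):
        a = Interval("chr1", 0, 1000)
        b = Interval("chr1", b_start, b_end)
        return Interaction(b, a, nlp) if swap else Interaction(a, b, nlp)

    def test_tss_in_distal_anchor(self):
        x = self._interaction(49_500, 51_000)
        assert score_microc(self.V, [x], [_gene()], CFG, "c").value == 2

    def test_gene_body_only(self):
        x = self._interaction(60_000, 61_000)  # inside body, away from TSS
        assert score_microc(self.V, [x], [_gene()], CFG, "c").value == 1

    def test_below_significance_ignored(self):
        x = self._interaction(49_500, 51_000, nlp=1.5)
        assert score_microc(self.V, [x], [_gene()], CFG, "c").value == 0

    def test_anchor_symmetry(self):
        for b_start, b_end, expected in [(49_500, 51_000, 2), (60_000, 61_000, 1)]:
            plain = self._interaction(b_start, b_end)
            swapped = self._interaction(b_start, b_end, swap=True)
            assert (
                score_microc(self.V, [plain], [_gene()], CFG, "c").value
                == score_microc(self.V, [swapped], [_gene()], CFG, "c").value
                == expected
            )

    def test_variant_in_neither_anchor(self):
        x = Interaction(Interval("chr1", 5000, 6000), Interval("chr1", 49_500, 51_000), 3.0)
        assert score_microc(self.V, [x], [_gene()], CFG, "c").value == 0

    def test_tss_beats_body_across_interactions(self):
        body_only = self._interaction(60_000, 61_000)
        tss = self._interaction(49_500, 51_000)
        assert score_microc(self.V, [body_only, tss], [_gene()], CFG, "c").value == 2

    def test_tss_pad(self):
        cfg = ScoringConfig(tss_pad_bp=1_000)
        x = self._interaction(50_500, 52_000)  # TSS 500 bp before the anchor
        assert score_microc(self.V, [x], [_gene()], CFG, "c").value == 1
        assert score_microc(self.V, [x], [_gene()], cfg, "c").value == 2


@given(
    fdr=st.floats(1e-9, 1.0),
    pip=st.floats(0, 1),
    in_set=st.booleans(),
)
@settings(max_examples=200)
def test_every_score_in_range(fdr, pip, in_set):
    assert score_mpra(MPRARecord("v", "c", 0.1, fdr), CFG).value in (0, 1, 2)
    assert score_finemap(FineMapRecord("v", pip), in_set, CFG).value in (0, 1, 2)
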
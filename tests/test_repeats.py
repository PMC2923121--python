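"""Repeat annotation: .out parsing, position annotation, consensus scanning
and chimeric-element reconstruction."""

import numpy as np
import pytest

from alusv import synthetic as syn
from alusv.junction import BreakpointCall, ReferenceRegion, revcomp
from alusv.repeats import (
    AluConsensus,
    OrientationError,
    RepeatFeature,
    RepeatParseError,
    annotate_position,
    features_to_bed,
    read_repeatmasker_out,
    reconstruct_chimera,
    scan_with_consensus,
    write_repeatmasker_out,
)

HEADER = (
    "   SW  perc perc perc  query      position in query    matching repeat\n"
    "score  div. del. ins.  sequence   begin end (left) strand repeat class "
    "begin end (left) ID\n"
    "\n"
)


class TestRepeatMaskerOut:
    def test_header_only_is_empty(self, tmp_path):
        p = tmp_path / "empty.out"
        p.write_text(HEADER)
        assert read_repeatmasker_out(p) == []

    def test_plus_and_complement_strands(self, tmp_path):
        rows = (
            " 1234  8.3  0.0  0.0  locus  5000  5310 (0) +  AluY "
            "SINE/Alu  1 311 (0) 1\n"
            "  987 12.1  0.0  0.0  locus  1200  1500 (0) C  AluSx1 "
            "SINE/Alu  (0) 301 1 2\n"
        )
        p = tmp_path / "two.out"
        p.write_text(HEADER + rows)
        feats = read_repeatmasker_out(p)
        assert [f.name for f in feats] == ["AluSx1", "AluY"]  # sorted by start
        assert feats[1].orientation == "sense"
        assert feats[0].orientation == "antisense"
        assert (feats[1].g_start, feats[1].g_end) == (5000, 5310)

    def test_ltr_class_preserved_verbatim(self, tmp_path):
        p = tmp_path / "mer.out"
        p.write_text(
            HEADER
            + "  500 15.0  0.0  0.0  locus  800  999 (0) +  MER83 "
            "LTR/ERV1  1 200 (0) 1\n"
        )
        feats = read_repeatmasker_out(p)
        assert feats[0].class_family == "LTR/ERV1"

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text(HEADER + "too few columns\n")
        with pytest.raises(RepeatParseError, match="line 4"):
            read_repeatmasker_out(p)

    def test_write_read_roundtrip(self, tmp_path):
        feats = [
            RepeatFeature("AluY", "SINE/Alu", 100, 410, "sense", score=1000),
            RepeatFeature("MER83", "LTR/ERV1", 900, 1100, "antisense", score=300),
        ]
        p = tmp_path / "rt.out"
        write_repeatmasker_out(feats, p)
        back = read_repeatmasker_out(p)
        assert [
            (f.name, f.class_family, f.g_start, f.g_end, f.orientation)
            for f in back
        ] == [
            (f.name, f.class_family, f.g_start, f.g_end, f.orientation)
            for f in feats
        ]

    def test_bed_export_is_zero_based_half_open(self):
        feats = [RepeatFeature("AluY", "SINE/Alu", 100, 410, "sense")]
        line = features_to_bed(feats).splitlines()[0].split("\t")
        assert (line[1], line[2], line[5]) == ("99", "410", "+")


class TestAnnotatePosition:
    def test_inside_and_outside(self):
        feats = [
            RepeatFeature("AluJo", "SINE/Alu", 100, 300, "sense"),
            RepeatFeature("AluY", "SINE/Alu", 500, 800, "antisense"),
        ]
        assert annotate_position(feats, 200).name == "AluJo"
        assert annotate_position(feats, 400) is None

    def test_agrees_with_naive_scan(self, default_locus, rng):
        feats = default_locus.repeats
        n = len(default_locus.seq)
        for g in rng.integers(1, n, size=10_000):
            g = int(g)
            naive = next((f for f in feats if f.g_start <= g <= f.g_end), None)
            got = annotate_position(feats, g)
            assert (got.name if got else None) == (naive.name if naive else None)


class TestScanWithConsensus:
    def test_exact_copy_full_length(self, rng):
        cons = syn.make_alu_consensus(rng, "AluSim")
        backbone = syn._random_dna(rng, 1000)
        region = ReferenceRegion(backbone[:300] + cons.seq + backbone[300:], 1)
        hits = scan_with_consensus(region, [cons])
        assert len(hits) == 1
        h = hits[0]
        assert h.orientation == "sense"
        assert h.g_start == 301
        assert h.g_end == 300 + len(cons.seq)

    def test_reverse_complement_with_divergence(self, rng):
        cons = syn.make_alu_consensus(rng, "AluSim")
        diverged = syn._substitute(cons.seq, 10.0, rng)
        backbone = syn._random_dna(rng, 1200)
        start = 400
        region = ReferenceRegion(
            backbone[:start] + revcomp(diverged) + backbone[start:], 1
        )
        hits = scan_with_consensus(region, [cons])
        assert len(hits) == 1
        h = hits[0]
        assert h.orientation == "antisense"
        assert abs(h.g_start - (start + 1)) <= 5
        assert abs(h.g_end - (start + len(cons.seq))) <= 5

    def test_no_hits_on_repeat_free_backbone(self):
        """Random 2 kb backbones yield no hit at the default threshold in
        >= 99/100 seeded trials."""
        rng = np.random.default_rng(99)
        cons = syn.make_alu_consensus(rng, "AluSim")
        false_hits = 0
        for _ in range(100):
            region = ReferenceRegion(syn._random_dna(rng, 2000), 1)
            false_hits += bool(scan_with_consensus(region, [cons]))
        assert false_hits <= 1

    def test_planted_benchmark_recovery(self):
        """>= 95% of planted 10%-diverged copies recovered with boundary
        error <= 5 bp."""
        rng = np.random.default_rng(3)
        master = syn.make_alu_consensus(rng, "AluSim")
        seqlist = list(syn._random_dna(rng, 12000))
        truth = []
        pos = 250
        for _ in range(20):
            div = syn._substitute(master.seq, 10.0, rng)
            anti = rng.random() < 0.5
            s = revcomp(div) if anti else div
            seqlist[pos - 1: pos - 1 + len(s)] = list(s)
            truth.append((pos, pos + len(s) - 1,
                          "antisense" if anti else "sense"))
            pos += len(s) + int(rng.integers(120, 300))
        region = ReferenceRegion("".join(seqlist), 1)
        hits = scan_with_consensus(region, [master])
        ok = 0
        for a, b, orient in truth:
            match = [h for h in hits if not (h.g_end < a or h.g_start > b)]
            if match:
                h = max(match, key=lambda x: x.score)
                if (abs(h.g_start - a) <= 5 and abs(h.g_end - b) <= 5
                        and h.orientation == orient):
                    ok += 1
        assert ok / len(truth) >= 0.95

    def test_monomer_map_projection(self, rng):
        cons = syn.make_alu_consensus(rng, "AluSim")
        region = ReferenceRegion(
            syn._random_dna(rng, 200) + cons.seq + syn._random_dna(rng, 200), 1
        )
        h = scan_with_consensus(region, [cons])[0]
        assert h.monomer_map is not None
        lm = h.monomer_map["left_monomer"]
        rm = h.monomer_map["right_monomer"]
        assert lm[0] == 201
        assert rm[1] - rm[0] > lm[1] - lm[0]  # right monomer carries the insert


def _dimer_pair(rng, length=320):
    cons = syn.make_alu_consensus(rng, "AluSim")
    L = len(cons.seq)
    mm = lambda start: {
        "left_monomer": (start, start + cons.left_monomer_end - 1),
        "linker": (start + cons.left_monomer_end, start + cons.linker_end - 1),
        "right_monomer": (start + cons.linker_end, start + cons.tail_start - 1),
        "tail": (start + cons.tail_start, start + L - 1),
    }
    p5 = RepeatFeature("AluSx1", "SINE/Alu", 1000, 1000 + L - 1, "sense", mm(1000))
    p3 = RepeatFeature("AluSx3", "SINE/Alu", 9000, 9000 + L - 1, "sense", mm(9000))
    return cons, p5, p3


class TestReconstructChimera:
    def test_identical_dimers_complete(self, rng):
        cons, p5, p3 = _dimer_pair(rng)
        off = 150  # same element offset in both parents
        call = BreakpointCall(
            left_break_g=1000 + off - 1, right_break_g=9000 + off,
            mh_len=25, mh_seq="N" * 0 or "", insert_seq="", ambiguity=26,
        )
        rep = reconstruct_chimera(p5, p3, call)
        assert rep.status == "complete_dimer_recombinant"
        assert rep.recombinant_length == len(cons.seq)

    def test_monomer_by_dimer_right_monomer_crossover(self, rng):
        cons, _, p3 = _dimer_pair(rng)
        flam = RepeatFeature(
            "FLAM_A", "SINE/Alu", 1000, 1132, "sense",
            {"left_monomer": (1000, 1124), "tail": (1125, 1132)},
        )
        # crossover inside the dimeric parent's right monomer
        rm_lo, rm_hi = p3.monomer_map["right_monomer"]
        call = BreakpointCall(
            left_break_g=1060, right_break_g=(rm_lo + rm_hi) // 2,
            mh_len=20, mh_seq="", insert_seq="", ambiguity=21,
        )
        rep = reconstruct_chimera(flam, p3, call)
        assert rep.status == "complete_monomer_recombinant"
        assert rep.crossover_monomer == "right_monomer"

    def test_linker_crossover_is_partial(self, rng):
        cons, _, p3 = _dimer_pair(rng)
        flam = RepeatFeature(
            "FLAM_A", "SINE/Alu", 1000, 1132, "sense",
            {"left_monomer": (1000, 1124), "tail": (1125, 1132)},
        )
        lk_lo, lk_hi = p3.monomer_map["linker"]
        call = BreakpointCall(
            left_break_g=1060, right_break_g=(lk_lo + lk_hi) // 2,
            mh_len=20, mh_seq="", insert_seq="", ambiguity=21,
        )
        assert reconstruct_chimera(flam, p3, call).status == "partial"

    def test_opposite_orientation_rejected(self, rng):
        cons, p5, p3 = _dimer_pair(rng)
        p3.orientation = "antisense"
        call = BreakpointCall(1100, 9100, 20, "", "", 21)
        with pytest.raises(OrientationError):
            reconstruct_chimera(p5, p3, call)

    def test_offset_crossovers_are_partial(self, rng):
        """A recombinant much shorter/longer than an element is partial."""
        cons, p5, p3 = _dimer_pair(rng)
        call = BreakpointCall(
            left_break_g=1000 + 60, right_break_g=9000 + 250,
            mh_len=20, mh_seq="", insert_seq="", ambiguity=21,
        )
        assert reconstruct_chimera(p5, p3, call).status == "partial"
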
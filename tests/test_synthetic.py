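"""The synthetic-locus generator: consensus anatomy, locus construction,
rearrangement truth, amplicons and MLPA signals."""

import numpy as np
import pytest

from alusv import synthetic as syn
from alusv.junction import ReferenceRegion, locate_junction


class TestAluConsensus:
    @pytest.mark.parametrize("seed", range(6))
    def test_anatomy(self, seed):
        rng = np.random.default_rng(seed)
        cons = syn.make_alu_consensus(rng)
        L = len(cons.seq)
        assert 280 <= L <= 330
        left = cons.seq[: cons.left_monomer_end]
        right = cons.seq[cons.linker_end: cons.tail_start]
        assert len(right) - len(left) == 31
        linker = cons.seq[cons.left_monomer_end: cons.linker_end]
        assert linker.count("A") / len(linker) >= 0.8

    def test_subfamilies_share_a_master(self):
        """Two subfamilies derived from the same master stay highly similar;
        two independent masters do not."""
        rng = np.random.default_rng(0)
        master = syn.make_alu_consensus(rng)
        s1 = syn.derive_subfamily(master, "A", rng, 3.0)
        s2 = syn.derive_subfamily(master, "B", rng, 3.0)
        ident_same = np.mean([a == b for a, b in zip(s1.seq, s2.seq)])
        other = syn.make_alu_consensus(np.random.default_rng(999))
        n = min(len(s1.seq), len(other.seq))
        ident_other = np.mean([a == b for a, b in zip(s1.seq[:n], other.seq[:n])])
        assert ident_same >= 0.90
        assert ident_other < 0.60

    def test_monomer_consensus_is_monomeric(self):
        rng = np.random.default_rng(0)
        master = syn.make_alu_consensus(rng)
        flam = syn.make_monomer_consensus(master, rng)
        assert not flam.is_dimeric
        assert 120 <= len(flam.seq) <= 145


class TestBuildLocus:
    def test_deterministic_for_fixed_seed(self):
        spec = syn.default_locus_spec(4)
        l1, l2 = syn.build_locus(spec), syn.build_locus(spec)
        assert l1.seq == l2.seq
        assert [(f.name, f.g_start) for f in l1.repeats] == [
            (f.name, f.g_start) for f in l2.repeats
        ]

    def test_default_intronic_repeat_density(self, default_locus):
        """The default locus emulates an Alu-dense gene: ~90 copies covering
        55-75% of intronic sequence."""
        ex = default_locus.model.exons
        intronic = sum(b.g_start - a.g_end - 1 for a, b in zip(ex, ex[1:]))
        covered = 0
        for a, b in zip(ex, ex[1:]):
            for f in default_locus.repeats:
                lo, hi = max(f.g_start, a.g_end + 1), min(f.g_end, b.g_start - 1)
                if hi >= lo:
                    covered += hi - lo + 1
        assert 0.55 <= covered / intronic <= 0.75
        assert len(default_locus.repeats) >= 60

    def test_zero_repeats_is_plain_backbone(self):
        spec = syn.default_locus_spec(1)
        spec = syn.LocusSpec(
            seed=1, exon_lengths=spec.exon_lengths,
            intron_lengths=spec.intron_lengths, planted_repeats=(),
        )
        locus = syn.build_locus(spec)
        assert locus.repeats == []

    def test_overlapping_planted_repeats_rejected(self):
        spec0 = syn.default_locus_spec(1)
        reps = (
            syn.PlantedRepeat("AluSim1", 5000),
            syn.PlantedRepeat("AluSim2", 5100),
        )
        spec = syn.LocusSpec(
            seed=1, exon_lengths=spec0.exon_lengths,
            intron_lengths=spec0.intron_lengths, planted_repeats=reps,
        )
        with pytest.raises(syn.SpecError, match="overlap"):
            syn.build_locus(spec)


def _same_orientation_pair(locus, rng, min_gap=800):
    feats = locus.repeats
    for _ in range(200):
        i, j = sorted(rng.choice(len(feats), size=2, replace=False))
        a, b = feats[i], feats[j]
        if a.orientation == b.orientation and b.g_start - a.g_end >= min_gap:
            return a, b
    raise RuntimeError("no pair")


class TestApplyNahr:
    def test_identical_pair_full_window_microhomology(self):
        """Two identical (0% divergence) copies: the junction microhomology
        equals the chosen shared window and the chimera is a complete
        dimer recombinant."""
        spec0 = syn.default_locus_spec(2)
        reps = (
            syn.PlantedRepeat("AluSim1", 6000, divergence_pct=0.0),
            syn.PlantedRepeat("AluSim1", 16000, divergence_pct=0.0),
        )
        spec = syn.LocusSpec(
            seed=2, exon_lengths=spec0.exon_lengths,
            intron_lengths=spec0.intron_lengths, planted_repeats=reps,
        )
        locus = syn.build_locus(spec)
        rng = np.random.default_rng(0)
        ev = syn.apply_nahr(locus, tuple(locus.repeats), "deletion", rng)
        t = ev.truth
        assert t.mechanism == "NAHR"
        assert t.mh_len >= 20
        assert t.chimera_status == "complete_dimer_recombinant"
        # recovery: the planted breakpoints lie within the recovered
        # ambiguity interval (with identical copies the observable window
        # is bounded by the amplicon flanks)
        read = syn.simulate_junction_amplicon(ev, flank=400, rng=rng)
        left, right = syn.junction_regions(ev)
        call = locate_junction(read, left, right)
        assert call.mh_len >= 300
        assert (call.left_break_g <= t.left_break_g
                <= call.left_break_g + call.mh_len)
        assert (call.right_break_g <= t.right_break_g
                <= call.right_break_g + call.mh_len)

    def test_opposite_orientation_pair_rejected(self, default_locus, rng):
        feats = default_locus.repeats
        pair = None
        for _ in range(200):
            i, j = sorted(rng.choice(len(feats), size=2, replace=False))
            a, b = feats[i], feats[j]
            if a.orientation != b.orientation and b.g_start - a.g_end > 500:
                pair = (a, b)
                break
        with pytest.raises(syn.IncompatiblePairError):
            syn.apply_nahr(default_locus, pair, "deletion", rng)

    def test_duplication_allele_length(self, default_locus, rng):
        a, b = _same_orientation_pair(default_locus, rng)
        for _ in range(30):
            try:
                ev = syn.apply_nahr(default_locus, (a, b), "duplication", rng)
                break
            except syn.IncompatiblePairError:
                a, b = _same_orientation_pair(default_locus, rng)
        t = ev.truth
        seg_len = t.left_break_g - t.right_break_g + 1
        assert len(ev.allele) == len(ev.ref_seq) + seg_len

    def test_reconstruction_identity(self, default_locus, rng):
        """Applying the truth's breakpoints to the reference regenerates the
        emitted allele byte-for-byte."""
        for _ in range(10):
            a, b = _same_orientation_pair(default_locus, rng)
            try:
                ev = syn.apply_nahr(default_locus, (a, b), "deletion", rng)
            except syn.IncompatiblePairError:
                continue
            t = ev.truth
            rebuilt = (ev.ref_seq[: t.left_break_g] + t.insert_seq
                       + ev.ref_seq[t.right_break_g - 1:])
            assert rebuilt == ev.allele


class TestApplyNhej:
    def test_blunt_junction_ambiguity_one(self, default_locus, rng):
        ev = syn.apply_nhej(default_locus, 10000, 20000, rng, mh=0)
        read = syn.simulate_junction_amplicon(ev, flank=300, rng=rng)
        left, right = syn.junction_regions(ev)
        call = locate_junction(read, left, right)
        assert call.ambiguity == 1
        assert call.mh_len == 0
        assert (call.left_break_g, call.right_break_g) == (10000, 20000)

    @pytest.mark.parametrize("mh", range(8))
    def test_exact_microhomology_recovered(self, default_locus, mh):
        """Requested microhomology 0-7 bp is recovered exactly (10 seeds
        each)."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            j5 = 8000 + 977 * seed
            ev = syn.apply_nhej(default_locus, j5, j5 + 9000, rng, mh=mh)
            read = syn.simulate_junction_amplicon(ev, flank=300, rng=rng)
            left, right = syn.junction_regions(ev)
            call = locate_junction(read, left, right)
            assert call.mh_len == mh, (mh, seed)
            assert call.left_break_g == ev.truth.left_break_g

    def test_fifteen_bp_insert_recovered(self, default_locus, rng):
        ev = syn.apply_nhej(default_locus, 12000, 25000, rng, insert_len=15)
        read = syn.simulate_junction_amplicon(ev, flank=300, rng=rng)
        left, right = syn.junction_regions(ev)
        call = locate_junction(read, left, right)
        assert len(call.insert_seq) == 15
        assert call.insert_seq == ev.truth.insert_seq

    def test_mh_and_insert_mutually_exclusive(self, default_locus, rng):
        with pytest.raises(ValueError):
            syn.apply_nhej(default_locus, 10000, 20000, rng, mh=3, insert_len=5)

    def test_edits_recorded_and_local(self, default_locus, rng):
        ev = syn.apply_nhej(default_locus, 10000, 20000, rng, mh=5)
        assert all(
            abs(g - 10000) <= 10 or abs(g - 20000) <= 10
            for g, _ in ev.truth.edits
        )

    def test_duplication_via_reversed_breaks(self, default_locus, rng):
        ev = syn.apply_nhej(default_locus, 20000, 10000, rng, mh=2)
        assert ev.truth.kind == "duplication"
        assert len(ev.allele) == len(ev.ref_seq) + (20000 - 10000 + 1)


class TestAmplicon:
    def test_error_free_is_exact_slice(self, default_locus, rng):
        ev = syn.apply_nhej(default_locus, 10000, 20000, rng, mh=0)
        read = syn.simulate_junction_amplicon(ev, flank=250, rng=rng)
        lb = ev.truth.left_break_g
        assert read == ev.allele[lb - 250: lb + 250]

    def test_flank_below_min_anchor_rejected(self, default_locus, rng):
        ev = syn.apply_nhej(default_locus, 10000, 20000, rng, mh=0)
        with pytest.raises(ValueError):
            syn.simulate_junction_amplicon(ev, flank=10, rng=rng)

    def test_sequencing_errors_tolerated_with_mismatch_budget(self, default_locus):
        """error_rate 0.002 junctions still localize with a 2-mismatch
        budget in >= 95/100 seeded trials."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            j5 = 8000 + 199 * seed
            ev = syn.apply_nhej(default_locus, j5, j5 + 9000, rng, mh=2)
            read = syn.simulate_junction_amplicon(
                ev, flank=300, rng=rng, error_rate=0.002)
            left, right = syn.junction_regions(ev)
            try:
                call = locate_junction(read, left, right, max_mismatch=2)
                # an error adjacent to the junction shifts the inferred
                # breakpoint by a base or two even for a perfect method
                within = (call.left_break_g - 5 <= ev.truth.left_break_g
                          <= call.left_break_g + call.mh_len + 5)
                ok += within
            except Exception:
                pass
        assert ok >= 95


class TestSimulateMlpa:
    def test_noise_free_unaffected_gives_unity_dq(self, default_locus):
        from alusv.mlpa import dosage_quotients

        rng = np.random.default_rng(0)
        ctrl = syn.simulate_mlpa(default_locus, None, rng, sample_id="C",
                                 sigma=0.0)
        test = syn.simulate_mlpa(default_locus, None, rng, sample_id="T",
                                 sigma=0.0)
        dq = dosage_quotients(test, ctrl)
        assert np.allclose(dq.dq, 1.0)

    def test_noise_free_het_deletion_gives_half(self, default_locus):
        from alusv.mlpa import dosage_quotients

        rng = np.random.default_rng(0)
        ev = syn.apply_nhej(
            default_locus,
            default_locus.model.exons[8].g_start - 400,
            default_locus.model.exons[13].g_end + 400,
            rng, mh=0,
        )
        ctrl = syn.simulate_mlpa(default_locus, None, rng, "C", sigma=0.0)
        test = syn.simulate_mlpa(default_locus, ev.truth, rng, "T", sigma=0.0)
        dq = dosage_quotients(test, ctrl).set_index("target").dq
        for exon in range(9, 15):
            assert dq[exon] == 0.5
        assert dq[1] == 1.0
        assert dq[18] == 1.0
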
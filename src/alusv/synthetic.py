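"""Seeded synthetic loci, rearrangements, junction amplicons and MLPA tables.

The generator emulates a gene-scale locus dense in Alu-like dimeric repeats:
an 18-exon, ~45 kb gene whose introns carry on the order of ninety repeat
copies covering roughly two thirds of the intronic sequence.  All repeat
copies derive from one master dimeric consensus (left monomer ~132 bp; right
monomer = the left-monomer sequence carrying a 31 bp insert; A-rich middle
linker; 3' A-rich tail), with pseudo-subfamilies created by seeded
substitutions — emulating subfamilies of different ages without importing an
external repeat library.  NAHR events recombine two homologous copies inside
a shared perfect-identity window; NHEJ events join two breaks with an exact
requested microhomology (0–7 bp, created by local reference editing so
recovery tests are sharp) or a short non-templated insertion.  Every emitted
allele comes with a complete truth record, and all output is a pure function
of (spec, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align

from .gene_model import ExonInterval, GeneModel
from .junction import ReferenceRegion, revcomp
from .mlpa import CONTROL, PROMOTER, ProbeSignal
from .repeats import AluConsensus, RepeatFeature, reconstruct_chimera

__all__ = [
    "LocusSpec",
    "PlantedRepeat",
    "Probe",
    "Locus",
    "RearrangementTruth",
    "EventResult",
    "SpecError",
    "IncompatiblePairError",
    "PlacementError",
    "make_alu_consensus",
    "make_monomer_consensus",
    "derive_subfamily",
    "build_locus",
    "default_locus_spec",
    "apply_nahr",
    "apply_nhej",
    "simulate_junction_amplicon",
    "simulate_mlpa",
    "junction_regions",
    "affected_segment",
]

BASES = np.array(list("ACGT"))

# master consensus anatomy (bp)
LEFT_MONOMER_LEN = 132
RIGHT_INSERT_LEN = 31
RIGHT_INSERT_AT = 40  # offset within the monomer where the insert sits


class SpecError(ValueError):
    """Invalid locus specification (e.g. overlapping planted repeats)."""


class IncompatiblePairError(ValueError):
    """Repeat pair lacks a qualifying identity window or orientation."""


class PlacementError(ValueError):
    """Requested NHEJ junction geometry cannot be realized."""


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _substitute(seq: str, pct: float, rng: np.random.Generator) -> str:
    """Substitute round(pct%) of positions with a different base."""
    n = len(seq)
    k = int(round(n * pct / 100.0))
    if k == 0:
        return seq
    pos = rng.choice(n, size=min(k, n), replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _a_rich(rng: np.random.Generator, n: int, a_frac: float = 0.9) -> str:
    """An A-rich tract with an exact (floored) non-A fraction, so the
    A-fraction bound holds by construction."""
    out = ["A"] * n
    k = int(n * (1.0 - a_frac))
    for p in rng.choice(n, size=k, replace=False):
        out[p] = "CGT"[rng.integers(0, 3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# consensus construction
# ---------------------------------------------------------------------------

def make_alu_consensus(rng: np.random.Generator, name: str = "AluSim") -> AluConsensus:
    """A dimeric Alu-like consensus: left monomer, A-rich linker, right
    monomer (left-derived with a 31 bp insert and a few substitutions),
    3' A-rich tail.  Total length lands in [315, 330]."""
    left = _random_dna(rng, LEFT_MONOMER_LEN)
    linker = _a_rich(rng, int(rng.integers(10, 16)))
    insert = _random_dna(rng, RIGHT_INSERT_LEN)
    right = left[:RIGHT_INSERT_AT] + insert + left[RIGHT_INSERT_AT:]
    right = _substitute(right, 3.0, rng)
    tail = _a_rich(rng, int(rng.integers(10, 21)))
    seq = left + linker + right + tail
    lme = LEFT_MONOMER_LEN
    linker_end = lme + len(linker)
    tail_start = linker_end + len(right)
    return AluConsensus(name, seq, lme, linker_end, tail_start)


def make_monomer_consensus(
    master: AluConsensus, rng: np.random.Generator, name: str = "FLAM_sim"
) -> AluConsensus:
    """A free-left-monomer-like (FLAM) consensus: the master's left monomer
    followed by a short A tail (~133 bp total)."""
    left = master.seq[: master.left_monomer_end][:125]
    tail = _a_rich(rng, 8)
    seq = left + tail
    return AluConsensus(name, seq, len(left), len(left), len(left))


def derive_subfamily(
    master: AluConsensus, name: str, rng: np.random.Generator, divergence_pct: float
) -> AluConsensus:
    """A pseudo-subfamily: the master consensus with seeded substitutions."""
    return dataclasses.replace(master, name=name, seq=_substitute(master.seq, divergence_pct, rng))


# AluConsensus in repeats.py has no tail_start; carry it via a light subclass
# is avoided — instead tail boundary is the fourth positional field below.
# (kept as a helper so monomer maps know where the tail begins)

def _consensus_parts(cons: AluConsensus) -> list[tuple[str, int, int]]:
    """(part, start, end_exclusive) anatomy of a consensus in element coords."""
    tail_start = getattr(cons, "tail_start", None)
    if tail_start is None:
        tail_start = len(cons.seq)
    if cons.is_dimeric:
        return [
            ("left_monomer", 0, cons.left_monomer_end),
            ("linker", cons.left_monomer_end, cons.linker_end),
            ("right_monomer", cons.linker_end, tail_start),
            ("tail", tail_start, len(cons.seq)),
        ]
    return [
        ("left_monomer", 0, cons.left_monomer_end),
        ("tail", cons.left_monomer_end, len(cons.seq)),
    ]


# ---------------------------------------------------------------------------
# locus specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRepeat:
    """Recipe for one planted repeat copy.  ``g_start`` is the 1-based
    genomic position of the copy's first base (gene-forward)."""

    name: str
    g_start: int
    orientation: str = "sense"  # sense / antisense
    divergence_pct: float = 5.0
    trunc5: int = 0
    trunc3: int = 0
    class_family: str = "SINE/Alu"


@dataclass(frozen=True)
class Probe:
    probe_id: str
    target: object  # exon index, "promoter", or "control"
    g_pos: Optional[int]


@dataclass(frozen=True)
class LocusSpec:
    """Full recipe for a synthetic locus (deterministic given ``seed``)."""

    seed: int
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    upstream_flank: int = 3000
    downstream_flank: int = 3000
    utr5_len: int = 60
    utr3_exonic: int = 2400
    subfamilies: tuple[str, ...] = ("AluSim1", "AluSim2", "AluSim3", "AluSim4")
    subfamily_divergence_pct: float = 2.0
    copy_divergence_range: tuple[float, float] = (2.0, 8.0)
    target_intronic_density: float = 0.65
    planted_repeats: Optional[tuple[PlantedRepeat, ...]] = None
    n_control_probes: int = 8

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise SpecError("need exactly n_exons - 1 intron lengths")
        if not (0 <= self.target_intronic_density <= 0.9):
            raise SpecError("unrealistic intronic repeat density")


def default_locus_spec(seed: int) -> LocusSpec:
    """The default study conditions: an 18-exon, ~45 kb gene-forward locus
    whose introns are ~65% covered by Alu-like repeats (~90 copies)."""
    rng = np.random.default_rng(seed)
    exon_lengths = (200, 123, 123, 381, 123, 123, 120, 126, 172, 228,
                    120, 139, 155, 140, 171, 150, 150, 2600)
    intron_lengths = tuple(int(rng.integers(1800, 3000)) for _ in range(17))
    return LocusSpec(seed=seed, exon_lengths=exon_lengths,
                     intron_lengths=intron_lengths)


@dataclass
class Locus:
    spec: LocusSpec
    seq: str
    model: GeneModel
    repeats: list[RepeatFeature]
    library: dict[str, AluConsensus]
    master: AluConsensus
    probes: list[Probe]

    @property
    def region(self) -> ReferenceRegion:
        return ReferenceRegion(self.seq, 1)


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------

def _monomer_map_for(
    cons: AluConsensus,
    g_start: int,
    orientation: str,
    trunc5: int,
    kept_len: int,
) -> Optional[dict[str, tuple[int, int]]]:
    """Genomic monomer map of a planted (possibly truncated) copy."""
    L0 = len(cons.seq)
    kept_lo, kept_hi = trunc5, trunc5 + kept_len - 1  # element coords kept
    mono: dict[str, tuple[int, int]] = {}
    for part, a, b_excl in _consensus_parts(cons):
        lo, hi = max(a, kept_lo), min(b_excl - 1, kept_hi)
        if hi - lo + 1 < 3:
            continue
        # element-kept coords
        lo_k, hi_k = lo - trunc5, hi - trunc5
        if orientation == "sense":
            mono[part] = (g_start + lo_k, g_start + hi_k)
        else:
            mono[part] = (g_start + kept_len - 1 - hi_k, g_start + kept_len - 1 - lo_k)
    return mono or None


def _plant(
    seq: list[str],
    rep: PlantedRepeat,
    cons: AluConsensus,
    rng: np.random.Generator,
) -> RepeatFeature:
    variant = _substitute(cons.seq, rep.divergence_pct, rng)
    kept = variant[rep.trunc5: len(variant) - rep.trunc3]
    if len(kept) < 30:
        raise SpecError(f"{rep.name}: truncation leaves <30 bp")
    planted = revcomp(kept) if rep.orientation == "antisense" else kept
    i0 = rep.g_start - 1
    if i0 < 0 or i0 + len(planted) > len(seq):
        raise SpecError(f"{rep.name} at {rep.g_start} outside the backbone")
    seq[i0: i0 + len(planted)] = list(planted)
    return RepeatFeature(
        name=rep.name,
        class_family=rep.class_family,
        g_start=rep.g_start,
        g_end=rep.g_start + len(planted) - 1,
        orientation=rep.orientation,
        monomer_map=_monomer_map_for(cons, rep.g_start, rep.orientation,
                                     rep.trunc5, len(planted)),
        score=float(len(planted)),
    )


def _auto_plant_specs(
    spec: LocusSpec,
    exons: list[ExonInterval],
    library: dict[str, AluConsensus],
    rng: np.random.Generator,
) -> list[PlantedRepeat]:
    """Fill introns with repeat copies up to the target density."""
    out: list[PlantedRepeat] = []
    names = [n for n in library if library[n].is_dimeric]
    margin = 25
    for a, b in zip(exons, exons[1:]):
        intron_lo, intron_hi = a.g_end + 1, b.g_start - 1
        intron_len = intron_hi - intron_lo + 1
        budget = int(intron_len * spec.target_intronic_density)
        cursor = intron_lo + margin + int(rng.integers(0, 60))
        placed = 0
        while placed < budget:
            name = names[rng.integers(0, len(names))]
            L = len(library[name].seq)
            if cursor + L > intron_hi - margin or placed + L > budget + L // 2:
                break
            out.append(
                PlantedRepeat(
                    name=name,
                    g_start=cursor,
                    orientation="sense" if rng.random() < 0.5 else "antisense",
                    divergence_pct=float(
                        rng.uniform(*spec.copy_divergence_range)
                    ),
                )
            )
            placed += L
            cursor += L + int(rng.integers(20, 120))
    return out


def build_locus(spec: LocusSpec) -> Locus:
    """Deterministically realize a LocusSpec into sequence + gene model +
    truth repeat annotations + probe map."""
    rng = np.random.default_rng(spec.seed)
    n_ex = len(spec.exon_lengths)
    total = (
        spec.upstream_flank
        + sum(spec.exon_lengths)
        + sum(spec.intron_lengths)
        + spec.downstream_flank
    )
    seq = list(_random_dna(rng, total))

    # exon coordinates
    exons = []
    g = spec.upstream_flank + 1
    for i, (elen) in enumerate(spec.exon_lengths, start=1):
        exons.append(ExonInterval(i, g, g + elen - 1))
        g += elen
        if i <= len(spec.intron_lengths):
            g += spec.intron_lengths[i - 1]
    if spec.utr5_len >= spec.exon_lengths[0]:
        raise SpecError("utr5_len must fit inside exon 1")
    if spec.utr3_exonic >= spec.exon_lengths[-1]:
        raise SpecError("utr3_exonic must fit inside the last exon")
    translation_start_g = exons[0].g_start + spec.utr5_len
    stop_end_g = exons[-1].g_end - spec.utr3_exonic
    model = GeneModel("SYNTH1", f"synthlocus_seed{spec.seed}", exons,
                      translation_start_g, stop_end_g)

    # consensus library: one master per run, subfamilies by seeded drift
    master = make_alu_consensus(rng, "AluSimMaster")
    library: dict[str, AluConsensus] = {}
    for name in spec.subfamilies:
        library[name] = derive_subfamily(master, name, rng,
                                         spec.subfamily_divergence_pct)
    library["FLAM_sim"] = make_monomer_consensus(master, rng)

    plant_specs = spec.planted_repeats
    if plant_specs is None:
        plant_specs = tuple(_auto_plant_specs(spec, exons, library, rng))

    # overlap validation
    ordered = sorted(plant_specs, key=lambda r: r.g_start)
    feats: list[RepeatFeature] = []
    for rep in ordered:
        cons = library.get(rep.name)
        if cons is None:
            raise SpecError(f"unknown consensus {rep.name!r}")
        feats.append(_plant(seq, rep, cons, rng))
    for f1, f2 in zip(feats, feats[1:]):
        if f2.g_start <= f1.g_end:
            raise SpecError(
                f"planted repeats overlap: {f1.name}@{f1.g_start} and "
                f"{f2.name}@{f2.g_start}"
            )

    probes: list[Probe] = [
        Probe("P_PROM", PROMOTER, exons[0].g_start - 150),
    ]
    for e in exons:
        # probes target the coding portion of an exon (long UTRs are not
        # representative of the exon's dosage)
        lo = max(e.g_start, translation_start_g)
        hi = min(e.g_end, stop_end_g)
        pos = (lo + hi) // 2 if lo <= hi else (e.g_start + e.g_end) // 2
        probes.append(Probe(f"P{e.index:02d}", e.index, pos))
    for c in range(1, spec.n_control_probes + 1):
        probes.append(Probe(f"C{c}", CONTROL, None))

    return Locus(spec, "".join(seq), model, feats, library, master, probes)


# ---------------------------------------------------------------------------
# rearrangement truth
# ---------------------------------------------------------------------------

@dataclass
class RearrangementTruth:
    kind: str  # deletion / duplication
    mechanism: str  # NAHR / NHEJ
    left_break_g: int  # last retained base 5' of the junction, leftmost
    right_break_g: int  # first retained base 3' of the junction, leftmost
    mh_len: int
    mh_seq: str
    insert_seq: str
    parent5: Optional[str]
    parent3: Optional[str]
    chimera_status: str
    crossover_monomer: str = "n/a"
    edits: tuple[tuple[int, str], ...] = ()  # (g, new_base) reference edits


@dataclass
class EventResult:
    """One simulated rearrangement: the (possibly locally edited) reference,
    the rearranged allele, and the truth record."""

    ref_seq: str
    allele: str
    truth: RearrangementTruth

    @property
    def ref_region(self) -> ReferenceRegion:
        return ReferenceRegion(self.ref_seq, 1)


def _assemble_allele(ref: str, left_break_g: int, right_break_g: int,
                     insert: str) -> str:
    """ref[1..left_break] + insert + ref[right_break..].  right < left gives
    a tandem duplication of [right_break..left_break]."""
    return ref[:left_break_g] + insert + ref[right_break_g - 1:]


def _perfect_windows(
    sa: str, sb: str, min_len: int
) -> list[tuple[int, int, int]]:
    """Maximal perfect-identity windows >= min_len between two sequences,
    found along the best local alignment.  Returns (a_idx, b_idx, length)
    triples in 0-based slice coordinates."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -2
    try:
        aln = aligner.align(sa, sb)[0]
    except (IndexError, ValueError):
        return []
    windows = []
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        run = 0
        for i in range(te - ts):
            if sa[ts + i] == sb[qs + i]:
                run += 1
            else:
                if run >= min_len:
                    windows.append((ts + i - run, qs + i - run, run))
                run = 0
        if run >= min_len:
            windows.append((te - run, qe - run, run))
    return windows


def apply_nahr(
    locus: Locus,
    repeat_pair: tuple[RepeatFeature, RepeatFeature],
    kind: str,
    rng: np.random.Generator,
    crossover_region: Optional[tuple[int, int]] = None,
    min_window: int = 20,
) -> EventResult:
    """Recombine two homologous repeat copies.

    The crossover window is drawn from the maximal shared perfect-identity
    windows (>= min_window bp) between the gene-forward sequences of the two
    copies; *crossover_region* optionally restricts the window to a genomic
    sub-interval of the downstream copy (e.g. its right monomer).  A
    deletion removes the intervening segment, fusing the 5' part of the
    upstream copy to the 3' part of the downstream copy; a duplication
    inserts the segment in tandem.  The junction microhomology equals the
    chosen window length by construction.
    """
    rep_a, rep_b = repeat_pair  # genomic order: a upstream of b
    if rep_a.g_start > rep_b.g_start:
        rep_a, rep_b = rep_b, rep_a
    if rep_a.orientation != rep_b.orientation:
        raise IncompatiblePairError(
            f"{rep_a.name} and {rep_b.name} are in opposite orientation"
        )
    if kind not in ("deletion", "duplication"):
        raise ValueError(f"kind must be deletion/duplication, got {kind!r}")
    ref = locus.seq
    sa = ref[rep_a.g_start - 1: rep_a.g_end]
    b_lo, b_hi = rep_b.g_start, rep_b.g_end
    if crossover_region is not None:
        b_lo, b_hi = max(b_lo, crossover_region[0]), min(b_hi, crossover_region[1])
        if b_hi - b_lo + 1 < min_window:
            raise IncompatiblePairError("crossover region shorter than min_window")
    sb = ref[b_lo - 1: b_hi]
    windows = _perfect_windows(sa, sb, min_window)
    # keep windows clear of the extreme element edges so the leftmost
    # breakpoint still falls inside both parents, and reject A-rich tracts
    # (linker/tail poly-A runs have no usable alignment register)
    usable = []
    for a_idx, b_idx, wlen in windows:
        if a_idx == 0 or (b_lo + b_idx) == rep_b.g_start:
            a_idx, b_idx, wlen = a_idx + 1, b_idx + 1, wlen - 1
        if wlen < min_window:
            continue
        wseq = sa[a_idx: a_idx + wlen]
        if max(wseq.count(b) for b in "ACGT") > 0.7 * wlen:
            continue
        usable.append((a_idx, b_idx, wlen))
    if not usable:
        raise IncompatiblePairError(
            f"no shared perfect-identity window >= {min_window} bp between "
            f"{rep_a.name} and {rep_b.name}"
        )
    a_idx, b_idx, wlen = usable[int(rng.integers(0, len(usable)))]
    wa_g = rep_a.g_start + a_idx  # window start in upstream copy
    wb_g = b_lo + b_idx           # window start in downstream copy
    mh_seq = ref[wa_g - 1: wa_g - 1 + wlen]

    if kind == "deletion":
        left_break, right_break = wa_g - 1, wb_g
        parent5, parent3 = rep_a, rep_b
    else:
        left_break, right_break = wb_g - 1, wa_g
        parent5, parent3 = rep_b, rep_a
    allele = _assemble_allele(ref, left_break, right_break, "")

    from .junction import BreakpointCall  # local import avoids cycle at import time

    call = BreakpointCall(
        left_break_g=left_break,
        right_break_g=right_break,
        mh_len=wlen,
        mh_seq=mh_seq,
        insert_seq="",
        ambiguity=wlen + 1,
    )
    chim = reconstruct_chimera(parent5, parent3, call)
    truth = RearrangementTruth(
        kind=kind,
        mechanism="NAHR",
        left_break_g=left_break,
        right_break_g=right_break,
        mh_len=wlen,
        mh_seq=mh_seq,
        insert_seq="",
        parent5=parent5.name,
        parent3=parent3.name,
        chimera_status=chim.status,
        crossover_monomer=chim.crossover_monomer,
    )
    return EventResult(ref, allele, truth)


def apply_nhej(
    locus: Locus,
    left_break_g: int,
    right_break_g: int,
    rng: np.random.Generator,
    mh: int = 0,
    insert_len: int = 0,
) -> EventResult:
    """Join two double-strand-break ends with an exact microhomology of
    ``mh`` bp (0-7) or a random non-templated insertion of ``insert_len``
    bp.  right_break_g > left_break_g yields a deletion; right_break_g <=
    left_break_g a tandem duplication.  The reference is locally edited so
    the requested microhomology is exact; edits are recorded in the truth.
    """
    if mh and insert_len:
        raise ValueError("microhomology and insertion are mutually exclusive")
    if not (0 <= mh <= 7):
        raise ValueError("mh must be within 0-7")
    if not (0 <= insert_len <= 20):
        raise ValueError("insert_len must be within 0-20")
    j5, j3 = left_break_g, right_break_g
    if abs(j3 - j5) <= mh + 2:
        raise PlacementError("breaks too close for the requested microhomology")
    seq = list(locus.seq)
    n = len(seq)
    needed = [j5 + mh + 1, j3 + mh, j5, j3 - 2]
    if min(needed) < 1 or max(needed) > n:
        raise PlacementError("junction too close to the sequence ends")

    edits: list[tuple[int, str]] = []

    def set_base(g: int, base: str) -> None:
        if seq[g - 1] != base:
            seq[g - 1] = base
            edits.append((g, base))

    def different(g: int, avoid: str) -> None:
        if seq[g - 1] == avoid:
            repl = next(b for b in "ACGT" if b != avoid and b != seq[g - 1])
            set_base(g, repl)

    # create the exact rightward microhomology run, then pin both ends
    for i in range(1, mh + 1):
        set_base(j5 + i, seq[j3 - 1 + i - 1])
    different(j5 + mh + 1, seq[j3 + mh - 1])
    different(j3 - 1, seq[j5 - 1])

    insert = ""
    if insert_len:
        insert = _random_dna(rng, insert_len)
        # pin the insert ends so the recovered insert length is exact
        # (a 1 bp insert must differ from the flanking base on both sides)
        if insert_len == 1:
            allowed = [b for b in "ACGT" if b not in (seq[j5], seq[j3 - 2])]
            insert = allowed[int(rng.integers(0, len(allowed)))]
        else:
            if insert[0] == seq[j5]:  # seq[j5] is base at g=j5+1
                insert = ("ACGT".replace(seq[j5], "")[int(rng.integers(0, 3))]
                          + insert[1:])
            if insert[-1] == seq[j3 - 2]:
                insert = insert[:-1] + "ACGT".replace(seq[j3 - 2], "")[
                    int(rng.integers(0, 3))
                ]
    elif mh == 0:
        different(j5 + 1, seq[j3 - 1])  # blunt: no accidental slide right

    ref = "".join(seq)
    mh_seq = ref[j5: j5 + mh]
    allele = _assemble_allele(ref, j5, j3, insert)
    truth = RearrangementTruth(
        kind="deletion" if j3 > j5 else "duplication",
        mechanism="NHEJ",
        left_break_g=j5,
        right_break_g=j3,
        mh_len=mh,
        mh_seq=mh_seq,
        insert_seq=insert,
        parent5=None,
        parent3=None,
        chimera_status="none",
        edits=tuple(edits),
    )
    return EventResult(ref, allele, truth)


# ---------------------------------------------------------------------------
# downstream observables
# ---------------------------------------------------------------------------

def simulate_junction_amplicon(
    event: EventResult,
    flank: int,
    rng: np.random.Generator,
    error_rate: float = 0.0,
    min_anchor: int = 20,
) -> str:
    """A junction-spanning slice of the rearranged allele with symmetric
    flanks, optionally carrying random substitution errors."""
    if flank < min_anchor:
        raise ValueError(f"flank {flank} shorter than min_anchor {min_anchor}")
    t = event.truth
    lo = t.left_break_g - flank  # 0-based start of slice in allele coords
    hi = t.left_break_g + len(t.insert_seq) + flank
    if lo < 0 or hi > len(event.allele):
        raise PlacementError("flank exceeds allele bounds")
    read = list(event.allele[lo:hi])
    if error_rate > 0:
        for i in range(len(read)):
            if rng.random() < error_rate:
                read[i] = "ACGT".replace(read[i], "")[int(rng.integers(0, 3))]
    return "".join(read)


def junction_regions(
    event: EventResult, pad: int = 600
) -> tuple[ReferenceRegion, ReferenceRegion]:
    """Reference windows around the two breakpoints, for locate_junction."""
    t = event.truth
    ref = event.ref_seq
    n = len(ref)
    l_lo = max(1, t.left_break_g - pad)
    l_hi = min(n, t.left_break_g + pad)
    r_lo = max(1, t.right_break_g - pad)
    r_hi = min(n, t.right_break_g + pad)
    return (
        ReferenceRegion(ref[l_lo - 1: l_hi], l_lo),
        ReferenceRegion(ref[r_lo - 1: r_hi], r_lo),
    )


def affected_segment(truth: RearrangementTruth) -> tuple[int, int]:
    """Genomic interval at altered copy number (deleted or duplicated)."""
    if truth.kind == "deletion":
        return truth.left_break_g + 1, truth.right_break_g - 1
    return truth.right_break_g, truth.left_break_g


def simulate_mlpa(
    locus: Locus,
    truth: Optional[RearrangementTruth],
    rng: np.random.Generator,
    sample_id: str = "S1",
    base_signal: float = 1000.0,
    sigma: float = 0.05,
) -> list[ProbeSignal]:
    """Per-probe signals: base_signal * (copies/2) * (1 + eps),
    eps ~ Normal(0, sigma).  Copy number comes from the truth's affected
    segment (1 for a heterozygous deletion, 3 for a duplication)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    seg = affected_segment(truth) if truth is not None else None
    out = []
    for probe in locus.probes:
        copies = 2
        if seg is not None and probe.g_pos is not None:
            if seg[0] <= probe.g_pos <= seg[1]:
                copies = 1 if truth.kind == "deletion" else 3
        eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        signal = max(0.0, base_signal * (copies / 2.0) * (1.0 + eps))
        out.append(ProbeSignal(sample_id, probe.probe_id, probe.target, signal))
    return out
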
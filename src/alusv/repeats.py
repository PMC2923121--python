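"""Repeat annotation: RepeatMasker .out parsing, breakpoint annotation,
consensus-library scanning, and chimeric (recombinant) element reconstruction.

An Alu element is a ~300 bp dimer: left monomer, A-rich linker, right
monomer (the left-monomer sequence plus a 31 bp insert), and a 3' A-rich
tail.  NAHR between two homologous elements fuses the 5' part of one to the
3' part of the other, leaving a chimeric element at the junction; when the
crossover offsets line up the chimera is itself a complete element (a
"complete recombinant").  Monomeric family members (FLAM — the free left
Alu monomer — or 5'-truncated elements) can recombine with a full dimer,
yielding a complete *monomer* recombinant when the crossover sits in the
dimer's homologous monomer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

from Bio import Align

from .junction import BreakpointCall, ReferenceRegion, revcomp

__all__ = [
    "RepeatFeature",
    "AluConsensus",
    "ChimeraReport",
    "RepeatParseError",
    "OrientationError",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "annotate_position",
    "scan_with_consensus",
    "reconstruct_chimera",
    "features_to_bed",
]

Orientation = Literal["sense", "antisense"]

MONOMER_KEYS = ("left_monomer", "linker", "right_monomer", "tail")


class RepeatParseError(ValueError):
    """Malformed repeat annotation input."""


class OrientationError(ValueError):
    """Parents of a putative chimera are in incompatible relative orientation."""


@dataclass
class RepeatFeature:
    """One repeat element occurrence on the gene-forward reference.

    ``orientation`` is relative to the gene's transcriptional direction
    (sense/antisense), not genome strand.  ``monomer_map``, when present,
    partitions [g_start, g_end] into left_monomer / linker / right_monomer /
    tail sub-intervals (monomeric elements carry only left_monomer and tail).
    """

    name: str
    class_family: str
    g_start: int
    g_end: int
    orientation: Orientation
    monomer_map: Optional[dict[str, tuple[int, int]]] = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.g_start > self.g_end:
            raise ValueError(f"{self.name}: g_start > g_end")
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.monomer_map:
            ivs = sorted(self.monomer_map.values())
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if a2 <= b1:
                    raise ValueError(f"{self.name}: monomer_map intervals overlap")

    @property
    def length(self) -> int:
        return self.g_end - self.g_start + 1

    @property
    def is_dimeric(self) -> bool:
        return bool(self.monomer_map) and "right_monomer" in self.monomer_map

    @property
    def top_class(self) -> str:
        """Top level of the class/family string ('SINE/Alu' -> 'SINE')."""
        return self.class_family.split("/")[0]

    def covers(self, g: int) -> bool:
        return self.g_start <= g <= self.g_end

    def monomer_of(self, g: int) -> str:
        """Which structural part a genomic position falls in ('n/a' when no
        monomer map is available or g is outside every part)."""
        if not self.monomer_map:
            return "n/a"
        for key, (a, b) in self.monomer_map.items():
            if a <= g <= b:
                return key
        return "n/a"


@dataclass(frozen=True)
class AluConsensus:
    """A dimeric (or monomeric) consensus: sequence plus the 0-based
    exclusive end indices of the left monomer and of the A-rich linker
    (and, when known, the start of the 3' A tail).  For a monomeric
    consensus left_monomer_end == linker_end."""

    name: str
    seq: str
    left_monomer_end: int
    linker_end: int
    tail_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.left_monomer_end <= self.linker_end < len(self.seq)):
            raise ValueError(f"{self.name}: inconsistent monomer boundaries")

    @property
    def is_dimeric(self) -> bool:
        return self.linker_end > self.left_monomer_end


ChimeraStatus = Literal[
    "complete_dimer_recombinant", "complete_monomer_recombinant", "partial", "none"
]


@dataclass
class ChimeraReport:
    """Reconstruction of the recombinant element left at a NAHR junction."""

    parent5: RepeatFeature
    parent3: RepeatFeature
    crossover_g5: int
    crossover_g3: int
    recombinant_length: int
    status: ChimeraStatus
    crossover_monomer: str  # left_monomer / right_monomer / linker / tail / n/a


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path: str | Path, gene_forward: bool = True) -> list[RepeatFeature]:
    """Parse a RepeatMasker .out file into RepeatFeatures sorted by g_start.

    The standard layout has 3 header lines followed by whitespace-separated
    rows; the strand column is '+' or 'C'.  '+' maps to sense and 'C' to
    antisense when the annotated sequence is already in gene-forward
    orientation (*gene_forward*, default); for a minus-strand gene pass
    gene_forward=False to flip the composition.
    """
    lines = Path(path).read_text().splitlines()
    feats: list[RepeatFeature] = []
    for ln, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 14:
            raise RepeatParseError(f"line {ln}: expected >= 14 columns, got {len(f)}")
        score = float(f[0])
        g_start, g_end = int(f[5]), int(f[6])
        strand = f[8]
        if strand not in ("+", "C"):
            raise RepeatParseError(f"line {ln}: bad strand column {strand!r}")
        plus = strand == "+"
        if not gene_forward:
            plus = not plus
        name, class_family = f[9], f[10]
        # repeat-internal coordinates, when parseable, seed no monomer map
        # here (consensus anatomy is unknown for arbitrary libraries)
        feats.append(
            RepeatFeature(
                name=name,
                class_family=class_family,
                g_start=g_start,
                g_end=g_end,
                orientation="sense" if plus else "antisense",
                score=score,
            )
        )
    feats.sort(key=lambda r: (r.g_start, r.g_end))
    return feats


def write_repeatmasker_out(
    features: Sequence[RepeatFeature], path: str | Path, query_name: str = "locus"
) -> None:
    """Write features in RepeatMasker .out layout (roundtrips with the reader)."""
    rows = []
    for i, r in enumerate(sorted(features, key=lambda x: (x.g_start, x.g_end)), 1):
        strand = "+" if r.orientation == "sense" else "C"
        rows.append(
            f"{r.score:5.0f}  0.0  0.0  0.0  {query_name} "
            f"{r.g_start:8d} {r.g_end:8d} (0) {strand} {r.name:15s} "
            f"{r.class_family:20s} 1 {r.length} (0) {i}"
        )
    Path(path).write_text(_OUT_HEADER + "\n".join(rows) + "\n")


def features_to_bed(features: Sequence[RepeatFeature], chrom: str = "locus") -> str:
    """BED6 text (0-based half-open) for a feature list."""
    out = []
    for r in sorted(features, key=lambda x: (x.g_start, x.g_end)):
        strand = "+" if r.orientation == "sense" else "-"
        out.append(
            f"{chrom}\t{r.g_start - 1}\t{r.g_end}\t{r.name}\t{r.score:.0f}\t{strand}"
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# position annotation
# ---------------------------------------------------------------------------

def annotate_position(
    features: Sequence[RepeatFeature], g: int
) -> Optional[RepeatFeature]:
    """The repeat feature covering genomic position g, or None.

    When two annotations abut exactly at g the earlier-starting one wins
    (a ``tie`` attribute is set on the returned feature).
    """
    hits = [r for r in features if r.covers(g)]
    if not hits:
        return None
    hits.sort(key=lambda r: (r.g_start, r.g_end))
    if len(hits) > 1:
        hits[0].tie = True  # type: ignore[attr-defined]
    return hits[0]


# ---------------------------------------------------------------------------
# consensus scanning (local alignment)
# ---------------------------------------------------------------------------

def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _project_monomer_map(
    cons: AluConsensus,
    aln,
    region: ReferenceRegion,
    antisense: bool,
    target_seq_len: int,
) -> tuple[int, int, Optional[dict[str, tuple[int, int]]]]:
    """Genomic extent of an alignment hit plus the projected monomer map.

    *aln* aligns the (possibly reverse-complemented) region against the
    consensus; alignment coordinates on the target are converted back to
    gene-forward genomic positions."""
    t_start = int(aln.aligned[0][0][0])
    t_end = int(aln.aligned[0][-1][1])  # exclusive
    q_start = int(aln.aligned[1][0][0])
    q_end = int(aln.aligned[1][-1][1])

    def to_g(t_idx: int) -> int:
        # t_idx is 0-based on the oriented target
        if antisense:
            t_idx = target_seq_len - 1 - t_idx
        return region.g_of(t_idx)

    g_lo = min(to_g(t_start), to_g(t_end - 1))
    g_hi = max(to_g(t_start), to_g(t_end - 1))
    # local alignment clips diverged element ends; project the unaligned
    # consensus stubs so the reported extent estimates the full element
    stub5, stub3 = q_start, len(cons.seq) - q_end
    if antisense:
        stub5, stub3 = stub3, stub5
    g_lo = max(region.g_offset, g_lo - stub5)
    g_hi = min(region.g_of(len(region.seq) - 1), g_hi + stub3)

    # map each consensus boundary through the aligned blocks
    def cons_to_t(q_idx: int) -> Optional[int]:
        for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
            if qs <= q_idx < qe:
                return ts + (q_idx - qs)
        return None

    bounds = []
    anatomy = [
        ("left_monomer", 0, cons.left_monomer_end),
        ("linker", cons.left_monomer_end, cons.linker_end),
        ("right_monomer", cons.linker_end, len(cons.seq)),
    ]
    if not cons.is_dimeric:
        anatomy = [("left_monomer", 0, len(cons.seq))]
    mono: dict[str, tuple[int, int]] = {}
    for key, a, b in anatomy:
        a_eff, b_eff = max(a, q_start), min(b, q_end)
        if b_eff - a_eff < 5:
            continue
        ta = cons_to_t(a_eff)
        tb = cons_to_t(b_eff - 1)
        if ta is None or tb is None:
            continue
        ga, gb = sorted((to_g(ta), to_g(tb)))
        mono[key] = (ga, gb)
    return g_lo, g_hi, (mono or None)


def scan_with_consensus(
    region: ReferenceRegion,
    library: Sequence[AluConsensus],
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    min_score: float = 60.0,
    class_family: str = "SINE/Alu",
) -> list[RepeatFeature]:
    """Smith–Waterman scan of a reference region against a consensus library.

    Each consensus is aligned locally in both orientations; hits with score
    >= *min_score* are collected and overlaps resolved greedily by score.
    The region is scanned in overlapping windows and accepted hits are masked
    so that tandem copies are all recovered.
    """
    if not library:
        raise ValueError("empty consensus library")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    max_cons = max(len(c.seq) for c in library)
    win = max(4 * max_cons, 1200)
    step = win // 2

    candidates: list[RepeatFeature] = []
    n = len(region.seq)
    for w_start in range(0, max(1, n - max_cons // 2), step):
        w_seq = region.seq[w_start: w_start + win]
        if len(w_seq) < 30:
            continue
        masked = w_seq
        for _round in range(8):
            best = None
            for cons in library:
                for antisense in (False, True):
                    target = revcomp(masked) if antisense else masked
                    alns = aligner.align(target, cons.seq)
                    try:
                        aln = alns[0]
                    except (IndexError, ValueError):
                        continue
                    if aln.score < min_score:
                        continue
                    if best is None or aln.score > best[0]:
                        best = (aln.score, cons, antisense, aln, len(target))
            if best is None:
                break
            score, cons, antisense, aln, tlen = best
            sub_region = ReferenceRegion(w_seq, region.g_of(w_start))
            g_lo, g_hi, mono = _project_monomer_map(
                cons, aln, sub_region, antisense, tlen
            )
            candidates.append(
                RepeatFeature(
                    name=cons.name,
                    class_family=class_family,
                    g_start=g_lo,
                    g_end=g_hi,
                    orientation="antisense" if antisense else "sense",
                    monomer_map=mono,
                    score=score,
                )
            )
            # mask the hit (in window coordinates) and rescan
            lo_i = g_lo - region.g_of(w_start)
            hi_i = g_hi - region.g_of(w_start)
            masked = masked[:lo_i] + "N" * (hi_i - lo_i + 1) + masked[hi_i + 1:]

    # greedy overlap resolution by score
    candidates.sort(key=lambda r: -r.score)
    accepted: list[RepeatFeature] = []
    for cand in candidates:
        if any(
            not (cand.g_end < a.g_start or cand.g_start > a.g_end) for a in accepted
        ):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda r: r.g_start)
    return accepted


# ---------------------------------------------------------------------------
# chimera reconstruction
# ---------------------------------------------------------------------------

def reconstruct_chimera(
    parent5: RepeatFeature,
    parent3: RepeatFeature,
    call: BreakpointCall,
    length_tolerance: int = 25,
) -> ChimeraReport:
    """Reconstruct the recombinant element formed at a NAHR junction.

    The recombinant is the 5' part of *parent5* up to the crossover joined
    to the 3' part of *parent3* after it.  Status:

    * ``complete_dimer_recombinant`` — both parents dimeric and the
      recombinant length matches a full element length (within
      *length_tolerance* of the dimeric parents' mean length);
    * ``complete_monomer_recombinant`` — exactly one parent monomeric and
      the crossover sits inside one of the dimeric parent's monomers (the
      homolog of the monomeric parent), completing the fused monomer unit;
    * ``partial`` otherwise.

    Parents must be in the same orientation as each other; an inverted pair
    raises :class:`OrientationError` (inverted-repeat NAHR yields
    inversions, which this pipeline does not model).
    """
    if parent5.orientation != parent3.orientation:
        raise OrientationError(
            f"{parent5.name} ({parent5.orientation}) x {parent3.name} "
            f"({parent3.orientation}): incompatible relative orientation"
        )
    x5 = call.left_break_g
    x3 = call.right_break_g
    if not parent5.covers(x5) or not parent3.covers(x3):
        return ChimeraReport(
            parent5, parent3, x5, x3, 0, "none", "n/a"
        )
    # chimera = parent5 bases strictly before the crossover window plus
    # parent3 bases from the window on (the shared window is counted once)
    recomb_len = (x5 - parent5.g_start + 1) + (parent3.g_end - x3 + 1)
    dimeric5, dimeric3 = parent5.is_dimeric, parent3.is_dimeric

    # read the crossover monomer off a dimeric parent's map (prefer parent3,
    # where the retained 3' part lives, matching how right-monomer crossovers
    # are described for monomer x dimer events)
    if dimeric3 and parent3.monomer_map:
        xmono = parent3.monomer_of(x3)
    elif dimeric5 and parent5.monomer_map:
        xmono = parent5.monomer_of(x5)
    else:
        xmono = "n/a"

    if dimeric5 and dimeric3:
        ref_len = (parent5.length + parent3.length) / 2
        if abs(recomb_len - ref_len) <= length_tolerance:
            status: ChimeraStatus = "complete_dimer_recombinant"
        else:
            status = "partial"
    elif dimeric5 != dimeric3:
        # monomer x dimer: the crossover must sit inside one of the dimeric
        # parent's monomers (its homolog of the monomeric parent) for the
        # fused monomer unit to be complete
        if xmono in ("left_monomer", "right_monomer"):
            status = "complete_monomer_recombinant"
        else:
            status = "partial"
    else:
        # two monomeric parents: complete when monomer-sized
        ref_len = (parent5.length + parent3.length) / 2
        status = (
            "complete_monomer_recombinant"
            if abs(recomb_len - ref_len) <= length_tolerance
            else "partial"
        )
    return ChimeraReport(parent5, parent3, x5, x3, recomb_len, status, xmono)
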
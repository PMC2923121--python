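"""Breakpoint localization from junction-spanning amplicon sequences.

A junction read is the Sanger-style sequence of a PCR product spanning a
deletion or duplication junction.  Its 5' end matches the reference upstream
of the event, its 3' end matches the reference downstream; where the two
matches overlap the junction carries *microhomology* — a short tract present
on both sides of the break, which makes the exact breakpoint placement
ambiguous over ``mh_len + 1`` equivalent positions.  Where a gap remains the
junction carries non-templated inserted sequence instead.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReferenceRegion",
    "BreakpointCall",
    "JunctionError",
    "NoJunctionError",
    "MultiMappingError",
    "locate_junction",
    "microhomology_at",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALPHABET = set("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class JunctionError(ValueError):
    """Junction characterization failure."""


class NoJunctionError(JunctionError):
    """The read contains no junction (or anchors are too short)."""


class MultiMappingError(JunctionError):
    """An anchor maps to several reference positions."""

    def __init__(self, msg: str, candidates: list[int]):
        super().__init__(f"{msg}; candidate offsets: {candidates}")
        self.candidates = candidates


@dataclass(frozen=True)
class ReferenceRegion:
    """A slice of reference sequence anchored at genomic position g_offset
    (1-based position of seq[0])."""

    seq: str
    g_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError("empty reference region")
        s = self.seq.upper()
        if set(s) - _ALPHABET:
            raise ValueError("reference alphabet restricted to ACGTN")
        object.__setattr__(self, "seq", s)

    def g_of(self, idx: int) -> int:
        """Genomic position of 0-based index idx."""
        return self.g_offset + idx

    def idx_of(self, g: int) -> int:
        return g - self.g_offset

    def slice_g(self, g_start: int, g_end: int) -> str:
        """Inclusive genomic slice."""
        return self.seq[self.idx_of(g_start): self.idx_of(g_end) + 1]


@dataclass(frozen=True)
class BreakpointCall:
    """Leftmost-aligned breakpoint pair for one junction.

    ``left_break_g``: last retained reference position 5' of the junction;
    ``right_break_g``: first retained reference position 3' of it.  With
    microhomology the placement can slide right by up to ``mh_len`` bases;
    ``ambiguity`` counts the equivalent placements (mh_len + 1 when there is
    no insertion).
    """

    left_break_g: int
    right_break_g: int
    mh_len: int
    mh_seq: str
    insert_seq: str
    ambiguity: int
    orientation: str = "forward"  # orientation of the read that was used
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.mh_len < 0:
            raise ValueError("negative microhomology length")
        if self.insert_seq and self.mh_len != 0:
            raise ValueError("insertion and microhomology are mutually exclusive")
        if self.ambiguity < 1:
            raise ValueError("ambiguity must be >= 1")


def _extend_forward(read: str, ref: str, read_i: int, ref_i: int, budget: int) -> int:
    """Length of the maximal extension of an exact/near-exact match rightward
    from (read_i, ref_i), spending at most *budget* isolated mismatches.
    'N' in the reference never matches.  Returns the matched length."""
    n = 0
    miss = 0
    best = 0
    while read_i + n < len(read) and ref_i + n < len(ref):
        a, b = read[read_i + n], ref[ref_i + n]
        if a == b and b != "N":
            n += 1
            best = n
        elif miss < budget:
            miss += 1
            n += 1
        else:
            break
    return best


def _extend_backward(read: str, ref: str, read_i: int, ref_i: int, budget: int) -> int:
    """Mirror of _extend_forward, leftward from (read_i, ref_i) inclusive."""
    n = 0
    miss = 0
    best = 0
    while read_i - n >= 0 and ref_i - n >= 0:
        a, b = read[read_i - n], ref[ref_i - n]
        if a == b and b != "N":
            n += 1
            best = n
        elif miss < budget:
            miss += 1
            n += 1
        else:
            break
    return best


def _find_anchor(seed: str, ref: str) -> list[int]:
    """All start offsets of exact occurrences of seed in ref."""
    hits = []
    start = ref.find(seed)
    while start != -1:
        hits.append(start)
        start = ref.find(seed, start + 1)
    return hits


def _locate_oriented(
    junction_seq: str,
    left_region: ReferenceRegion,
    right_region: ReferenceRegion,
    min_anchor: int,
    max_mismatch: int,
    orientation: str,
) -> BreakpointCall:
    read = junction_seq
    L = len(read)
    if L < 2 * min_anchor:
        raise NoJunctionError(
            f"read length {L} shorter than two anchors of {min_anchor}"
        )
    # seeds are tiled (up to 3 tiles per end) so an isolated sequencing
    # error inside the terminal tile does not lose the anchor when a
    # mismatch budget is in force
    n_tiles = 1 if max_mismatch == 0 else 3

    def candidates(tile_starts, region_seq, from_end):
        out = set()
        for k in tile_starts:
            if from_end:
                seed = read[L - k - min_anchor: L - k] if k else read[-min_anchor:]
            else:
                seed = read[k: k + min_anchor]
            for h in _find_anchor(seed, region_seq):
                # ref position where read[0] (or read[L-1]) would sit
                anchor = h - k if not from_end else h + min_anchor - 1 + k
                if 0 <= anchor < len(region_seq):
                    out.add(anchor)
        return sorted(out)

    tiles = [t * min_anchor for t in range(n_tiles)]
    hits5 = candidates(tiles, left_region.seq, from_end=False)
    if not hits5:
        raise NoJunctionError(f"5' anchor ({min_anchor} bp) not found in left region")
    hits3 = candidates(tiles, right_region.seq, from_end=True)
    if not hits3:
        raise NoJunctionError(f"3' anchor ({min_anchor} bp) not found in right region")

    # a seed repeated inside a repeat-dense region is disambiguated by
    # maximal extension: the true placement extends to the junction, a
    # paralogous copy diverges quickly; a tie is a genuine multi-mapping
    def best_unique(hits, extents, side):
        top = max(extents)
        winners = [h for h, e in zip(hits, extents) if e == top]
        if len(winners) > 1:
            raise MultiMappingError(f"{side} anchor multi-maps", winners)
        return winners[0], top

    ext5 = [_extend_forward(read, left_region.seq, 0, h, max_mismatch)
            for h in hits5]
    a5, pref = best_unique(hits5, ext5, "5'")
    ext3 = [_extend_backward(read, right_region.seq, L - 1, h, max_mismatch)
            for h in hits3]
    a3_end, suf = best_unique(hits3, ext3, "3'")
    a3 = a3_end - min_anchor + 1  # kept for reference-index arithmetic below
    if pref < min_anchor or suf < min_anchor:
        raise NoJunctionError("anchor extension shorter than min_anchor")

    # reference indices: prefix occupies left_region[a5 : a5+pref]
    # suffix occupies right_region[a3+min_anchor-suf : a3+min_anchor]
    s3 = a3 + min_anchor - suf

    if pref + suf >= L:
        mh = pref + suf - L
        same_region = left_region == right_region
        # leftmost placement: shrink the prefix to L - suf
        left_end_idx = a5 + (L - suf) - 1       # last retained base, left region
        right_start_idx = s3                     # first retained base, right region
        left_break_g = left_region.g_of(left_end_idx)
        right_break_g = right_region.g_of(right_start_idx)
        if same_region and right_break_g == left_break_g + 1:
            raise NoJunctionError(
                "read is a contiguous reference slice; no junction present"
            )
        mh_seq = read[L - suf: L - suf + mh]
        return BreakpointCall(
            left_break_g=left_break_g,
            right_break_g=right_break_g,
            mh_len=mh,
            mh_seq=mh_seq,
            insert_seq="",
            ambiguity=mh + 1,
            orientation=orientation,
        )
    insert = read[pref: L - suf]
    return BreakpointCall(
        left_break_g=left_region.g_of(a5 + pref - 1),
        right_break_g=right_region.g_of(s3),
        mh_len=0,
        mh_seq="",
        insert_seq=insert,
        ambiguity=1,
        orientation=orientation,
    )


def locate_junction(
    junction_seq: str,
    left_region: ReferenceRegion,
    right_region: ReferenceRegion,
    min_anchor: int = 20,
    max_mismatch: int = 0,
) -> BreakpointCall:
    """Characterize one junction read against two reference regions.

    The read must begin with >= min_anchor bases matching *left_region* and
    end with >= min_anchor bases matching *right_region* (exactly, or with
    up to *max_mismatch* isolated substitutions tolerated during anchor
    extension).  Both orientations of the read are tried; the forward
    orientation wins ties.

    Returns the leftmost-aligned :class:`BreakpointCall`.  The reconstruction
    identity holds: left flank up to ``left_break_g`` + ``insert_seq`` +
    right flank from ``right_break_g`` reproduces the read exactly.
    """
    junction_seq = junction_seq.upper()
    errors: list[JunctionError] = []
    for orientation, read in (
        ("forward", junction_seq),
        ("reverse", revcomp(junction_seq)),
    ):
        try:
            return _locate_oriented(
                read, left_region, right_region, min_anchor, max_mismatch,
                orientation,
            )
        except JunctionError as exc:
            errors.append(exc)
    for exc in errors:  # a genuine ambiguity outranks a plain no-call
        if isinstance(exc, MultiMappingError):
            raise exc
    raise NoJunctionError(" / ".join(str(e) for e in errors))


def reconstruct(
    call: BreakpointCall,
    left_region: ReferenceRegion,
    right_region: ReferenceRegion,
    left_flank: int,
    right_flank: int,
) -> str:
    """Rebuild the junction sequence implied by *call* with the given flank
    lengths (bases retained on each side of the break)."""
    li = left_region.idx_of(call.left_break_g)
    ri = right_region.idx_of(call.right_break_g)
    left = left_region.seq[max(0, li - left_flank + 1): li + 1]
    right = right_region.seq[ri: ri + right_flank]
    return left + call.insert_seq + right


def microhomology_at(
    reference: ReferenceRegion, left_break_g: int, right_break_g: int
) -> tuple[int, str]:
    """Microhomology of a (left_break, right_break) deletion placement.

    Slides the breakpoint right while ``ref[left+1..] == ref[right..]`` and
    left while ``ref[..left] == ref[..right-1]``; the total slide is the
    microhomology length and the concatenated slid sequence is returned.
    'N' never matches.
    """
    seq = reference.seq
    li = reference.idx_of(left_break_g)
    ri = reference.idx_of(right_break_g)
    if not (0 <= li < len(seq)) or not (0 <= ri < len(seq)):
        raise JunctionError("breakpoints outside the reference region")
    if left_break_g >= right_break_g:
        raise JunctionError("left_break_g must precede right_break_g")
    r = 0
    while (li + 1 + r < len(seq) and ri + r < len(seq)
           and seq[li + 1 + r] == seq[ri + r] and seq[ri + r] != "N"):
        r += 1
    l = 0
    while (li - l >= 0 and ri - 1 - l >= 0
           and seq[li - l] == seq[ri - 1 - l] and seq[li - l] != "N"):
        l += 1
    mh_seq = seq[li - l + 1: li + 1] + seq[li + 1: li + 1 + r]
    return r + l, mh_seq
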
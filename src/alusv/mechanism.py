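"""NAHR / NHEJ classification of characterized rearrangements.

Two repair pathways dominate gross deletions and duplications at repeat-dense
loci.  Non-allelic homologous recombination (NAHR) recombines two highly
similar but non-allelic repeats, so both breakpoints fall inside repeat
elements of the same class in direct relative orientation, the junction
shows extensive flanking sequence identity, and a chimeric element is left
at the join.  Non-homologous end joining (NHEJ) ligates double-strand-break
ends with at most a few bases of microhomology — or a short non-templated
insertion — and requires no repeat homology at all.

The classifier encodes that dichotomy with three explicit thresholds
(homology identity %, homology length, NHEJ microhomology ceiling); the
published case series this pipeline models classified junctions by
inspection, so the defaults are configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .junction import BreakpointCall, ReferenceRegion
from .repeats import ChimeraReport, OrientationError, RepeatFeature, reconstruct_chimera

__all__ = ["MechanismParams", "MechanismCall", "classify", "summarize_events"]


@dataclass(frozen=True)
class MechanismParams:
    """Classification thresholds.

    min_identity_pct / min_identity_len:
        the local alignment of the two parent repeats around the crossover
        must reach this identity over this many aligned bases for NAHR.
    max_nhej_mh:
        microhomology ceiling (bp) for an NHEJ call.
    flank_window:
        bases taken on each side of the crossover within each parent for the
        homology alignment.
    """

    min_identity_pct: float = 80.0
    min_identity_len: int = 20
    max_nhej_mh: int = 7
    flank_window: int = 100


@dataclass
class MechanismCall:
    label: str  # NAHR / NHEJ / unresolved
    mh_len: int
    flank_identity_pct: float
    flank_identity_len: int
    parent5: Optional[str]
    parent3: Optional[str]
    same_class: bool
    chimera: Optional[ChimeraReport] = None


def _flank_identity(
    ref: ReferenceRegion,
    call: BreakpointCall,
    window: int,
    min_len: int,
    min_pct: float,
) -> tuple[float, int, bool]:
    """Homology evidence *in register with the junction*.

    The junction makes ``left_break`` and ``right_break - 1`` homologous
    positions (sliding the breakpoint exchanges one for the other), so
    position left_break+i is compared with right_break-1+i over
    i in [-window, +window].  NAHR fuses homologous offsets, hence a true
    crossover shows a long high-identity stretch in this register, while an
    NHEJ break that merely happens to fall inside two repeat copies is out
    of register and scores near the 25% background.  The decisive quantity
    is the best min_len-wide stretch (a 31 bp monomer-insert or an indel
    between the copies breaks the register further out, which must not
    drown a genuine crossover); the reported identity/length describe that
    stretch greedily extended while it stays above min_pct.  'N' never
    matches.
    """
    lb, rb = call.left_break_g, call.right_break_g - 1
    lo = max(-window, ref.g_offset - lb, ref.g_offset - rb)
    hi = min(window, ref.g_offset + len(ref.seq) - 1 - lb,
             ref.g_offset + len(ref.seq) - 1 - rb)
    n = hi - lo + 1
    if n < min_len:
        return 0.0, 0, False
    match = []
    for i in range(lo, hi + 1):
        a = ref.seq[lb + i - ref.g_offset]
        b = ref.seq[rb + i - ref.g_offset]
        match.append(1 if (a == b and a != "N") else 0)
    # best window of width min_len
    cur = sum(match[:min_len])
    best, best_at = cur, 0
    for i in range(min_len, n):
        cur += match[i] - match[i - min_len]
        if cur > best:
            best, best_at = cur, i - min_len + 1
    ok = 100.0 * best / min_len >= min_pct
    # greedy extension of the best window while identity holds
    a, b = best_at, best_at + min_len - 1
    hits = best
    while True:
        grown = False
        if a > 0 and 100.0 * (hits + match[a - 1]) / (b - a + 2) >= min_pct:
            a -= 1
            hits += match[a]
            grown = True
        if b < n - 1 and 100.0 * (hits + match[b + 1]) / (b - a + 2) >= min_pct:
            b += 1
            hits += match[b]
            grown = True
        if not grown:
            break
    length = b - a + 1
    return 100.0 * hits / length, length, ok


def classify(
    call: BreakpointCall,
    annot5: Optional[RepeatFeature],
    annot3: Optional[RepeatFeature],
    ref: ReferenceRegion,
    params: MechanismParams = MechanismParams(),
) -> MechanismCall:
    """Classify one characterized junction as NAHR, NHEJ or unresolved.

    NAHR requires: both breakpoints inside repeat features, parents in the
    same relative orientation and same top-level repeat class, and flanking
    parent homology >= min_identity_pct over >= min_identity_len.  NHEJ is
    the fallback for junctions with microhomology <= max_nhej_mh (with or
    without an insertion).  Degenerate evidence yields ``unresolved``.
    """
    identity, ident_len = 0.0, 0
    same_class = False
    chimera = None
    if annot5 is not None and annot3 is not None:
        # class/family level, not subfamily: AluSx1 x AluSx3 are both SINE/Alu
        same_class = annot5.class_family == annot3.class_family
        orientation_ok = annot5.orientation == annot3.orientation
        if orientation_ok and same_class:
            identity, ident_len, homologous = _flank_identity(
                ref, call, params.flank_window,
                params.min_identity_len, params.min_identity_pct,
            )
            if homologous:
                try:
                    chimera = reconstruct_chimera(annot5, annot3, call)
                except OrientationError:
                    chimera = None
                return MechanismCall(
                    label="NAHR",
                    mh_len=call.mh_len,
                    flank_identity_pct=identity,
                    flank_identity_len=ident_len,
                    parent5=annot5.name,
                    parent3=annot3.name,
                    same_class=True,
                    chimera=chimera,
                )
    if call.mh_len <= params.max_nhej_mh:
        return MechanismCall(
            label="NHEJ",
            mh_len=call.mh_len,
            flank_identity_pct=identity,
            flank_identity_len=ident_len,
            parent5=annot5.name if annot5 else None,
            parent3=annot3.name if annot3 else None,
            same_class=same_class,
            chimera=None,
        )
    return MechanismCall(
        label="unresolved",
        mh_len=call.mh_len,
        flank_identity_pct=identity,
        flank_identity_len=ident_len,
        parent5=annot5.name if annot5 else None,
        parent3=annot3.name if annot3 else None,
        same_class=same_class,
        chimera=None,
    )


def summarize_events(events: Sequence[tuple[str, MechanismCall]]) -> dict:
    """Tally mechanism labels, overall and per rearrangement kind.

    *events* is a sequence of (event_label, MechanismCall); the event label's
    trailing 'del'/'dup' gives the rearrangement kind.  Output ordering is
    deterministic.
    """
    by_label: Counter[str] = Counter()
    by_kind: dict[str, Counter[str]] = {"del": Counter(), "dup": Counter(), "other": Counter()}
    for name, mc in events:
        by_label[mc.label] += 1
        kind = "del" if name.endswith("del") else "dup" if name.endswith("dup") else "other"
        by_kind[kind][mc.label] += 1
    order = ["NAHR", "NHEJ", "unresolved"]
    return {
        "total": {k: by_label.get(k, 0) for k in order},
        "by_kind": {
            kind: {k: c.get(k, 0) for k in order}
            for kind, c in by_kind.items()
            if sum(c.values())
        },
    }
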
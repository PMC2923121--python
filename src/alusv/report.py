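"""Per-event reports: compose junction localization, repeat annotation,
mechanism classification, span naming and size arithmetic into one record,
plus cohort screening-percentage arithmetic."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .gene_model import (
    GeneModel,
    format_c_position,
    g_to_c,
    interval_size,
    name_rearrangement_span,
)
from .junction import BreakpointCall, ReferenceRegion, locate_junction
from .mechanism import MechanismCall, MechanismParams, classify
from .repeats import RepeatFeature, annotate_position

__all__ = [
    "EventReport",
    "characterize_event",
    "cohort_summary",
    "reports_to_tsv",
    "reports_from_tsv",
]


@dataclass
class EventReport:
    """One characterized rearrangement, mirroring the fields a clinical
    case series tabulates: exon-span label, HGVS c. description, size,
    mechanism, junction-flanking repeats."""

    label: str
    hgvs_c: str
    size_bp: int
    mechanism: str
    repeat5: str  # "Name/Class/Family" or "-"
    repeat3: str
    mh_len: int
    insert_len: int
    evidence: Optional[MechanismCall] = None
    call: Optional[BreakpointCall] = None
    proband_count: Optional[int] = None


def _fmt_repeat(feat: Optional[RepeatFeature]) -> str:
    if feat is None:
        return "-"
    return f"{feat.name}/{feat.class_family}"


def characterize_event(
    model: GeneModel,
    reference: ReferenceRegion,
    repeats: Sequence[RepeatFeature],
    junction_read: str,
    left_region: Optional[ReferenceRegion] = None,
    right_region: Optional[ReferenceRegion] = None,
    params: MechanismParams = MechanismParams(),
    min_anchor: int = 20,
    max_mismatch: int = 0,
    proband_count: Optional[int] = None,
) -> EventReport:
    """Full characterization of one junction read.

    ``left_region``/``right_region`` narrow the anchor search (in practice
    the long-range PCR primer positions define them); they default to the
    whole reference.  The rearrangement kind falls out of breakpoint order:
    a junction that jumps forward is a deletion, one that jumps backward a
    tandem duplication.
    """
    left_region = left_region or reference
    right_region = right_region or reference
    call = locate_junction(
        junction_read, left_region, right_region,
        min_anchor=min_anchor, max_mismatch=max_mismatch,
    )
    # breakpoints are ambiguous over the microhomology interval; annotate
    # with the first placement that hits a repeat
    def annotate_interval(g: int) -> Optional[RepeatFeature]:
        for cand in (g, g + call.mh_len, g + call.mh_len // 2):
            feat = annotate_position(repeats, cand)
            if feat is not None:
                return feat
        return None

    annot5 = annotate_interval(call.left_break_g)
    annot3 = annotate_interval(call.right_break_g)
    mech = classify(call, annot5, annot3, reference, params)
    if call.right_break_g > call.left_break_g:
        kind = "del"
        seg = (call.left_break_g + 1, call.right_break_g - 1)
    else:
        kind = "dup"
        seg = (call.right_break_g, call.left_break_g)
    label = name_rearrangement_span(model, seg[0], seg[1], kind)
    c1 = g_to_c(model, seg[0])
    c2 = g_to_c(model, seg[1])
    hgvs = f"c.{format_c_position(c1)}_{format_c_position(c2)}{kind}"
    size = interval_size(model, c1, c2)
    return EventReport(
        label=label,
        hgvs_c=hgvs,
        size_bp=size,
        mechanism=mech.label,
        repeat5=_fmt_repeat(annot5),
        repeat3=_fmt_repeat(annot3),
        mh_len=call.mh_len,
        insert_len=len(call.insert_seq),
        evidence=mech,
        call=call,
        proband_count=proband_count,
    )


def cohort_summary(counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Screening-step percentages: 100 * count / total, rounded half-up to
    one decimal (the convention of printed cohort tables)."""
    if total <= 0:
        raise ValueError("total must be positive")
    out = {}
    for key, count in counts.items():
        if count < 0:
            raise ValueError(f"negative count for {key}")
        pct = Decimal(100 * count) / Decimal(total)
        out[key] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out


_TSV_COLUMNS = [
    "label", "hgvs_c", "size_bp", "mechanism", "repeat5", "repeat3",
    "mh_len", "insert_len", "proband_count",
]


def reports_to_tsv(reports: Sequence[EventReport]) -> str:
    df = pd.DataFrame(
        [
            {c: getattr(r, c) for c in _TSV_COLUMNS}
            for r in reports
        ],
        columns=_TSV_COLUMNS,
    )
    return df.to_csv(sep="\t", index=False)


def reports_from_tsv(text: str) -> list[EventReport]:
    import io

    df = pd.read_csv(io.StringIO(text), sep="\t")
    out = []
    for row in df.itertuples():
        out.append(
            EventReport(
                label=row.label,
                hgvs_c=row.hgvs_c,
                size_bp=int(row.size_bp),
                mechanism=row.mechanism,
                repeat5=row.repeat5,
                repeat3=row.repeat3,
                mh_len=int(row.mh_len),
                insert_len=int(row.insert_len),
                proband_count=None if pd.isna(row.proband_count)
                else int(row.proband_count),
            )
        )
    return out
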
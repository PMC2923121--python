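"""MLPA dosage-quotient copy-number calling.

Multiplex ligation-dependent probe amplification quantifies target copy
number from relative probe signals.  Each sample's exon-probe signals are
normalized to the sum of its control-probe signals; the dosage quotient (DQ)
of a probe is that ratio divided by the median ratio across reference
(control) samples.  DQ ~ 1.0 means two copies, ~0.5 a heterozygous deletion
and ~1.5 a heterozygous duplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .gene_model import GeneModel

__all__ = [
    "ProbeSignal",
    "DosageCall",
    "MlpaError",
    "NonContiguousError",
    "dosage_quotients",
    "call_copy_number",
    "label_event",
    "read_probe_table",
    "write_dq_table",
]

CONTROL = "control"
PROMOTER = "promoter"


class MlpaError(ValueError):
    """MLPA normalization/calling failure."""


class NonContiguousError(MlpaError):
    """Affected exons are non-contiguous or mix del and dup states."""


@dataclass(frozen=True)
class ProbeSignal:
    """One probe's raw signal in one sample.  ``target`` is an exon index
    (int), ``"promoter"``, or ``"control"`` for reference probes."""

    sample_id: str
    probe_id: str
    target: object
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise MlpaError(f"negative signal for {self.probe_id}")


@dataclass(frozen=True)
class DosageCall:
    exon: object  # exon index or "promoter"
    dq: float
    state: str  # normal / het_deletion / het_duplication
    flag: str = ""  # e.g. "possible_homozygous"


def _to_frame(signals: Sequence[ProbeSignal]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(s.sample_id, s.probe_id, s.target, s.signal) for s in signals],
        columns=["sample_id", "probe_id", "target", "signal"],
    )
    if df.duplicated(["sample_id", "probe_id"]).any():
        raise MlpaError("duplicate (sample, probe) signal")
    return df


def dosage_quotients(
    test: Sequence[ProbeSignal], controls: Sequence[ProbeSignal]
) -> pd.DataFrame:
    """Per-probe dosage quotients of one test sample against control samples.

    Within each sample the ratio R(probe) = signal / sum(control-probe
    signals); DQ(probe) = R_test(probe) / median over control samples of
    R_control(probe).  Returns a DataFrame with columns probe_id, target, dq
    (control-target probes excluded from the output).
    """
    tdf = _to_frame(test)
    cdf = _to_frame(controls)
    if tdf.sample_id.nunique() != 1:
        raise MlpaError("test signals must come from a single sample")
    n_ctrl_probes = (tdf.target == CONTROL).sum()
    if n_ctrl_probes < 2:
        raise MlpaError(f"need >= 2 control-target probes, found {n_ctrl_probes}")
    if cdf.sample_id.nunique() < 1:
        raise MlpaError("need >= 1 control sample")

    probes = tdf[["probe_id", "target"]].drop_duplicates()
    for sample, grp in cdf.groupby("sample_id"):
        missing = set(probes.probe_id) - set(grp.probe_id)
        if missing:
            raise MlpaError(
                f"control sample {sample} missing probe(s): {sorted(missing)}"
            )

    def ratios(df: pd.DataFrame) -> pd.Series:
        ctrl_sum = df.loc[df.target == CONTROL, "signal"].sum()
        if ctrl_sum <= 0:
            raise MlpaError("zero control-probe signal sum; cannot normalize")
        return df.set_index("probe_id").signal / ctrl_sum

    r_test = ratios(tdf)
    r_ctrl = pd.DataFrame(
        {sid: ratios(grp) for sid, grp in cdf.groupby("sample_id")}
    )
    med = r_ctrl.median(axis=1)
    if (med <= 0).any():
        raise MlpaError("zero median control ratio")
    dq = (r_test / med).rename("dq")
    out = probes.merge(dq, left_on="probe_id", right_index=True)
    out = out[out.target != CONTROL].reset_index(drop=True)
    return out


def call_copy_number(
    dq_table: pd.DataFrame, lower: float = 0.75, upper: float = 1.25
) -> list[DosageCall]:
    """Threshold DQ values into copy-number states (strict inequalities:
    dq == lower is still normal).  DQ near 0 or near 2 is flagged as a
    possible homozygous change but keeps the heterozygous state label."""
    if not (0 < lower < 1 < upper):
        raise MlpaError(f"need 0 < lower < 1 < upper, got {lower}, {upper}")
    calls = []
    for row in dq_table.itertuples():
        dq = float(row.dq)
        if dq < lower:
            state = "het_deletion"
            flag = "possible_homozygous" if dq < 0.25 else ""
        elif dq > upper:
            state = "het_duplication"
            flag = "possible_homozygous" if dq > 1.75 else ""
        else:
            state, flag = "normal", ""
        calls.append(DosageCall(exon=row.target, dq=dq, state=state, flag=flag))
    return calls


def label_event(
    calls: Sequence[DosageCall], model: Optional[GeneModel] = None
) -> Optional[str]:
    """Collapse per-exon dosage calls into an event label.

    Contiguous same-state affected exons give ``exonX_Ydel``/``dup`` (or
    ``exonXdel`` for a single exon); a low promoter probe prepends
    ``promoter_`` and the label then names only the last affected exon.
    All-normal input returns None.  Non-contiguous or mixed del+dup calls
    raise :class:`NonContiguousError` for manual review.
    """
    affected = [c for c in calls if c.state != "normal"]
    if not affected:
        return None
    states = {c.state for c in affected}
    if len(states) > 1:
        raise NonContiguousError(f"mixed states {sorted(states)}; manual review")
    kind = "del" if states == {"het_deletion"} else "dup"
    promoter_low = any(c.exon == PROMOTER for c in affected)
    exon_idx = sorted(int(c.exon) for c in affected if c.exon != PROMOTER)
    if not exon_idx:
        return f"promoter_{kind}" if promoter_low else None
    if exon_idx != list(range(exon_idx[0], exon_idx[-1] + 1)):
        raise NonContiguousError(
            f"affected exons {exon_idx} are non-contiguous; manual review"
        )
    if promoter_low:
        if exon_idx[0] != 1:
            raise NonContiguousError(
                "promoter probe low but exon 1 unaffected; manual review"
            )
        return f"promoter_exon{exon_idx[-1]}{kind}"
    if len(exon_idx) == 1:
        return f"exon{exon_idx[0]}{kind}"
    return f"exon{exon_idx[0]}_{exon_idx[-1]}{kind}"


# -- TSV I/O ---------------------------------------------------------------

def read_probe_table(path: str | Path) -> list[ProbeSignal]:
    """Read a probe-signal TSV: sample_id, probe_id, target, signal."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "probe_id": str})
    needed = {"sample_id", "probe_id", "target", "signal"}
    if not needed <= set(df.columns):
        raise MlpaError(f"{path}: columns must include {sorted(needed)}")

    def parse_target(t: object) -> object:
        s = str(t)
        return s if s in (CONTROL, PROMOTER) else int(s)

    return [
        ProbeSignal(r.sample_id, r.probe_id, parse_target(r.target), float(r.signal))
        for r in df.itertuples()
    ]


def write_dq_table(
    dq_table: pd.DataFrame, calls: Sequence[DosageCall], path: str | Path
) -> None:
    out = dq_table.copy()
    out["state"] = [c.state for c in calls]
    out["flag"] = [c.flag for c in calls]
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
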
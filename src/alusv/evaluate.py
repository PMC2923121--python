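"""Seeded end-to-end evaluation batteries.

These drive the full pipeline over simulated data and measure recovery:
breakpoint localization within the microhomology ambiguity interval,
NAHR/NHEJ classification accuracy, and MLPA exon-state accuracy.  They are
used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic as syn
from .junction import JunctionError
from .mechanism import summarize_events
from .mlpa import call_copy_number, dosage_quotients
from .report import characterize_event

__all__ = [
    "RecoveryMetrics",
    "sample_event",
    "recovery_battery",
    "ldlr_event_battery",
    "mlpa_battery",
]


@dataclass
class RecoveryMetrics:
    n_events: int
    breakpoint_recovery: float  # fraction within the ambiguity interval
    mechanism_accuracy: float


def sample_event(locus: syn.Locus, rng: np.random.Generator,
                 want_nahr: bool) -> syn.EventResult:
    """One random NAHR (homologous same-orientation pair) or NHEJ event."""
    feats = locus.repeats
    if want_nahr:
        for _ in range(120):
            i, j = sorted(rng.choice(len(feats), size=2, replace=False))
            a, b = feats[i], feats[j]
            if a.orientation != b.orientation or b.g_start - a.g_end < 800:
                continue
            kind = "deletion" if rng.random() < 0.6 else "duplication"
            try:
                return syn.apply_nahr(locus, (a, b), kind, rng)
            except syn.IncompatiblePairError:
                continue
        raise RuntimeError("no homologous repeat pair found")
    lo, hi = locus.model.g_first + 300, locus.model.g_last - 300
    j5 = int(rng.integers(lo, hi - 1500))
    j3 = j5 + int(rng.integers(1000, hi - j5))
    if rng.random() < 0.7:
        return syn.apply_nhej(locus, j5, j3, rng, mh=int(rng.integers(0, 5)))
    return syn.apply_nhej(locus, j5, j3, rng,
                          insert_len=int(rng.integers(1, 16)))


def recovery_battery(seed: int, n_events: int = 200,
                     flank: int = 300) -> RecoveryMetrics:
    """Mixed battery of simulated events on the default synthetic locus:
    rearrange, amplify the junction, then run the full characterization
    chain and score it against the simulator truth."""
    locus = syn.build_locus(syn.default_locus_spec(seed))
    rng = np.random.default_rng(seed + 1)
    bp_ok = mech_ok = 0
    for k in range(n_events):
        ev = sample_event(locus, rng, want_nahr=(k % 2 == 0))
        t = ev.truth
        read = syn.simulate_junction_amplicon(ev, flank=flank, rng=rng)
        left, right = syn.junction_regions(ev)
        try:
            rep = characterize_event(
                locus.model, ev.ref_region, locus.repeats, read,
                left_region=left, right_region=right,
            )
        except JunctionError:
            continue
        c = rep.call
        bp_ok += (
            c.left_break_g <= t.left_break_g <= c.left_break_g + c.mh_len
            and c.right_break_g <= t.right_break_g <= c.right_break_g + c.mh_len
        )
        mech_ok += rep.mechanism == t.mechanism
    return RecoveryMetrics(n_events, bp_ok / n_events, mech_ok / n_events)


def ldlr_event_battery(seed: int):
    """Characterize the eight surrogate-LDLR events; returns
    (per-event reports, mechanism tally, truths-by-label)."""
    from .ldlr import build_ldlr_like_fixture

    rng = np.random.default_rng(seed + 2)
    locus, events = build_ldlr_like_fixture(seed)
    reports, tally_in, truths = [], [], {}
    for ev, res in events:
        read = syn.simulate_junction_amplicon(res, flank=300, rng=rng)
        left, right = syn.junction_regions(res)
        rep = characterize_event(
            locus.model, res.ref_region, locus.repeats, read,
            left_region=left, right_region=right, proband_count=ev.probands,
        )
        reports.append(rep)
        tally_in.append((rep.label, rep.evidence))
        truths[ev.label] = res.truth
    return reports, summarize_events(tally_in), truths


def mlpa_battery(seed: int, n_samples: int = 100, sigma: float = 0.05) -> float:
    """Exon-state accuracy over noisy MLPA simulations of the eight
    surrogate-LDLR event types."""
    from .ldlr import build_ldlr_like_fixture

    locus, events = build_ldlr_like_fixture(seed)
    rng = np.random.default_rng(seed + 3)
    ctrl = [s for k in range(4)
            for s in syn.simulate_mlpa(locus, None, rng, sample_id=f"C{k}",
                                       sigma=sigma)]
    probe_pos = {p.target: p.g_pos for p in locus.probes
                 if p.target != "control"}
    ok = n = 0
    for k in range(n_samples):
        ev, res = events[k % len(events)]
        seg = syn.affected_segment(res.truth)
        test = syn.simulate_mlpa(locus, res.truth, rng, sample_id="T",
                                 sigma=sigma)
        for c in call_copy_number(dosage_quotients(test, ctrl)):
            want = "normal"
            if seg[0] <= probe_pos[c.exon] <= seg[1]:
                want = ("het_deletion" if res.truth.kind == "deletion"
                        else "het_duplication")
            n += 1
            ok += c.state == want
    return ok / n
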
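"""HGVS-style cDNA<->genomic coordinate arithmetic on a single-gene model.

The gene model is a list of exon intervals in gene-forward orientation plus
two CDS anchors: the genomic position of the A of the ATG and the genomic
position of the last base of the stop codon.  All coordinates are 1-based
inclusive.  cDNA ("c.") positions follow the standard convention:

* ``c.1`` is the A of the start codon; coding positions count exonic CDS
  bases only, through the last base of the stop codon.
* ``c.-n`` counts exonic 5'UTR bases upstream of the start codon and, once
  the transcript is exhausted, continues contiguously into upstream genomic
  sequence (promoter positions such as ``c.-1823`` are therefore legal).
* ``c.*n`` counts exonic bases after the stop codon and continues
  contiguously past the last exon's end.
* ``c.N+k`` / ``c.N-k`` are intronic offsets from the nearest exon boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "ExonInterval",
    "GeneModel",
    "CPosition",
    "GeneModelError",
    "CPositionParseError",
    "CoordinateError",
    "parse_c_position",
    "format_c_position",
    "c_to_g",
    "g_to_c",
    "interval_size",
    "name_rearrangement_span",
    "read_gene_model",
    "write_gene_model",
]


class GeneModelError(ValueError):
    """Invalid gene model structure."""


class CPositionParseError(ValueError):
    """Malformed c.-position text."""


class CoordinateError(ValueError):
    """A c. or g. position that cannot be mapped on the given model."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon, 1-based inclusive genomic interval in gene-forward frame."""

    index: int
    g_start: int
    g_end: int

    def __post_init__(self) -> None:
        if self.g_start > self.g_end:
            raise GeneModelError(
                f"exon {self.index}: g_start {self.g_start} > g_end {self.g_end}"
            )

    @property
    def length(self) -> int:
        return self.g_end - self.g_start + 1


Anchor = Literal["coding", "utr5", "utr3"]


@dataclass(frozen=True)
class CPosition:
    """A parsed HGVS-style c. position.

    ``base`` is the positive coding/utr3 base number, or for ``utr5`` the
    magnitude of the negative offset (``c.-1823`` -> base 1823).
    ``intron_offset`` is signed; 0 for exonic positions.
    """

    anchor: Anchor
    base: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise CPositionParseError(f"base must be >= 1, got {self.base}")
        if self.anchor not in ("coding", "utr5", "utr3"):
            raise CPositionParseError(f"unknown anchor {self.anchor!r}")

    def __str__(self) -> str:
        return format_c_position(self)


_C_POS_RE = re.compile(r"^(\*)?(-)?(\d+)(?:([+-])(\d+))?$")


def parse_c_position(text: str) -> CPosition:
    """Parse an HGVS-style c.-position string such as ``"190+566"``,
    ``"-1823"``, ``"*1216"`` or ``"c.695-67"``.

    A leading ``c.`` and any whitespace are stripped; the remainder must be
    ``[*-]?<base>([+-]<offset>)?``.
    """
    s = re.sub(r"\s+", "", text)
    if s.startswith("c."):
        s = s[2:]
    m = _C_POS_RE.match(s)
    if not m:
        raise CPositionParseError(f"malformed c.position: {text!r}")
    star, minus, base_s, off_sign, off_s = m.groups()
    if star and minus:
        raise CPositionParseError(f"cannot combine '*' and '-': {text!r}")
    base = int(base_s)
    if base == 0:
        raise CPositionParseError(f"c.0 does not exist: {text!r}")
    offset = 0
    if off_sign is not None:
        offset = int(off_s)
        if offset == 0:
            raise CPositionParseError(f"zero intron offset forbidden: {text!r}")
        if off_sign == "-":
            offset = -offset
    anchor: Anchor = "utr3" if star else ("utr5" if minus else "coding")
    return CPosition(anchor, base, offset)


def format_c_position(pos: CPosition) -> str:
    """Canonical (no-space, no ``c.`` prefix) rendering of a CPosition."""
    if pos.anchor == "utr5":
        s = f"-{pos.base}"
    elif pos.anchor == "utr3":
        s = f"*{pos.base}"
    else:
        s = str(pos.base)
    if pos.intron_offset:
        s += f"{pos.intron_offset:+d}"
    return s


class GeneModel:
    """Exon structure plus CDS anchors of one gene, gene-forward frame.

    Parameters
    ----------
    gene_name, reference_id :
        Free-text identifiers carried through to output.
    exons :
        Exon intervals; indices must run 1..n, strictly ordered and
        non-overlapping in genomic coordinates.
    translation_start_g :
        Genomic position of the A of the start codon (must be exonic).
    stop_end_g :
        Genomic position of the last base of the stop codon (exonic,
        downstream of the start in transcript order).
    """

    def __init__(
        self,
        gene_name: str,
        reference_id: str,
        exons: Iterable[ExonInterval],
        translation_start_g: int,
        stop_end_g: int,
    ) -> None:
        self.gene_name = gene_name
        self.reference_id = reference_id
        self.exons = sorted(exons, key=lambda e: e.g_start)
        if not self.exons:
            raise GeneModelError("gene model needs at least one exon")
        if [e.index for e in self.exons] != list(range(1, len(self.exons) + 1)):
            raise GeneModelError("exon indices must be consecutive from 1 in genomic order")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.g_start <= a.g_end:
                raise GeneModelError(f"exons {a.index} and {b.index} overlap or touch")
        self.translation_start_g = translation_start_g
        self.stop_end_g = stop_end_g
        # transcript-order index of every exonic genomic position
        self._tx_of_g: dict[int, int] = {}
        self._g_of_tx: list[int] = []
        for e in self.exons:
            for g in range(e.g_start, e.g_end + 1):
                self._tx_of_g[g] = len(self._g_of_tx)
                self._g_of_tx.append(g)
        if translation_start_g not in self._tx_of_g:
            raise GeneModelError("translation_start_g is not exonic")
        if stop_end_g not in self._tx_of_g:
            raise GeneModelError("stop_end_g is not exonic")
        self._tss_tx = self._tx_of_g[translation_start_g]
        self._stop_tx = self._tx_of_g[stop_end_g]
        if self._stop_tx <= self._tss_tx:
            raise GeneModelError("stop_end_g not downstream of translation_start_g")

    # -- helpers -----------------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def g_first(self) -> int:
        return self.exons[0].g_start

    @property
    def g_last(self) -> int:
        return self.exons[-1].g_end

    @property
    def cds_len(self) -> int:
        """Number of coding bases, start codon through stop codon inclusive."""
        return self._stop_tx - self._tss_tx + 1

    def exon_of_g(self, g: int) -> ExonInterval | None:
        for e in self.exons:
            if e.g_start <= g <= e.g_end:
                return e
        return None

    def _exonic_c_of_tx(self, tx: int) -> CPosition:
        if tx < self._tss_tx:
            return CPosition("utr5", self._tss_tx - tx)
        if tx > self._stop_tx:
            return CPosition("utr3", tx - self._stop_tx)
        return CPosition("coding", tx - self._tss_tx + 1)


def c_to_g(model: GeneModel, pos: CPosition | str) -> int:
    """Map a c. position to its 1-based genomic coordinate on *model*."""
    if isinstance(pos, str):
        pos = parse_c_position(pos)
    # anchored exonic base first
    if pos.anchor == "coding":
        tx = model._tss_tx + pos.base - 1
        if tx >= len(model._g_of_tx) or tx > model._stop_tx:
            raise CoordinateError(
                f"coding base {pos.base} beyond CDS length {model.cds_len}"
            )
        g = model._g_of_tx[tx]
    elif pos.anchor == "utr5":
        tx = model._tss_tx - pos.base
        if tx >= 0:
            g = model._g_of_tx[tx]
        else:
            # contiguous into upstream genomic sequence beyond exon 1
            g = model.g_first + tx  # tx negative
    else:  # utr3
        tx = model._stop_tx + pos.base
        if tx < len(model._g_of_tx):
            g = model._g_of_tx[tx]
        else:
            g = model.g_last + (tx - (len(model._g_of_tx) - 1))
    if pos.intron_offset == 0:
        return g
    # intron offsets only legal from an exon boundary of an exonic anchor
    exon = model.exon_of_g(g)
    if exon is None:
        raise CoordinateError(
            f"intron offset from non-exonic anchor {format_c_position(pos)}"
        )
    if pos.intron_offset > 0:
        if g != exon.g_end:
            raise CoordinateError(
                f"'+' offset anchored off a non-terminal exonic base: {pos}"
            )
        if exon.index == model.n_exons:
            raise CoordinateError("'+' offset from the last exon has no intron")
        intron_len = model.exons[exon.index].g_start - exon.g_end - 1
        if pos.intron_offset > intron_len:
            raise CoordinateError(
                f"offset +{pos.intron_offset} exceeds intron {exon.index} "
                f"length {intron_len}"
            )
        return g + pos.intron_offset
    else:
        if g != exon.g_start:
            raise CoordinateError(
                f"'-' offset anchored off a non-initial exonic base: {pos}"
            )
        if exon.index == 1:
            raise CoordinateError("'-' offset before exon 1 has no intron")
        intron_len = exon.g_start - model.exons[exon.index - 2].g_end - 1
        if -pos.intron_offset > intron_len:
            raise CoordinateError(
                f"offset {pos.intron_offset} exceeds intron {exon.index - 1} "
                f"length {intron_len}"
            )
        return g + pos.intron_offset


def g_to_c(model: GeneModel, g: int) -> CPosition:
    """Map a genomic position to its c. position on *model*.

    Intronic positions anchor to the nearer exon boundary; an exact midpoint
    tie goes to the preceding exon (the ``+`` form).  Positions upstream of
    exon 1 or downstream of the last exon continue the utr5/utr3 counts
    contiguously.
    """
    tx = model._tx_of_g.get(g)
    if tx is not None:
        return model._exonic_c_of_tx(tx)
    if g < model.g_first:
        return CPosition("utr5", model._tss_tx + (model.g_first - g))
    if g > model.g_last:
        utr3_exonic = len(model._g_of_tx) - 1 - model._stop_tx
        return CPosition("utr3", utr3_exonic + (g - model.g_last))
    # intronic: find flanking exons
    for left, right in zip(model.exons, model.exons[1:]):
        if left.g_end < g < right.g_start:
            d_left = g - left.g_end
            d_right = right.g_start - g
            if d_left <= d_right:
                base = model._exonic_c_of_tx(model._tx_of_g[left.g_end])
                return CPosition(base.anchor, base.base, d_left)
            base = model._exonic_c_of_tx(model._tx_of_g[right.g_start])
            return CPosition(base.anchor, base.base, -d_right)
    raise CoordinateError(f"position {g} not mappable")  # pragma: no cover


def interval_size(
    model: GeneModel, c_start: CPosition | str, c_end: CPosition | str
) -> int:
    """Inclusive base-pair count between two c. positions.

    This is the quantity reported as a deletion/duplication size, e.g. the
    13186 bp of a promoter-through-exon-2 deletion.
    """
    g1 = c_to_g(model, c_start)
    g2 = c_to_g(model, c_end)
    if g1 > g2:
        raise CoordinateError(f"inverted interval: {c_start} maps after {c_end}")
    return g2 - g1 + 1


def name_rearrangement_span(
    model: GeneModel, g_start: int, g_end: int, kind: Literal["del", "dup"]
) -> str:
    """Exon-span event label, e.g. ``exon2_6dup`` or ``promoter_exon2del``.

    The label runs from the first to the last exon fully or partially
    overlapped by [g_start, g_end]; an interval reaching upstream of exon 1
    gets a ``promoter_`` prefix and names only its last contained exon.
    An interval touching no exon and not upstream gets a warning label.
    """
    if kind not in ("del", "dup"):
        raise ValueError(f"kind must be 'del' or 'dup', got {kind!r}")
    if g_start > g_end:
        raise CoordinateError("inverted genomic interval")
    hit = [e.index for e in model.exons if not (g_end < e.g_start or g_start > e.g_end)]
    promoter = g_start < model.g_first
    if promoter:
        last = hit[-1] if hit else 0
        if last == 0:
            return f"promoter_{kind}"
        return f"promoter_exon{last}{kind}"
    if not hit:
        return f"intronic_only_{kind}"
    if hit[0] == hit[-1]:
        return f"exon{hit[0]}{kind}"
    return f"exon{hit[0]}_{hit[-1]}{kind}"


# -- label aliases ---------------------------------------------------------

_ALIASES = {
    "promoter_ex2del": "promoter_exon2del",
    "promoter_2exondel": "promoter_exon2del",
}


def canonical_label(label: str) -> str:
    """Normalize historic event-label spellings to the canonical form."""
    return _ALIASES.get(label.strip(), label.strip())


# -- gene model TSV I/O ----------------------------------------------------
#
# Format: two '#'-prefixed header lines carrying metadata and CDS anchors,
# then 4 tab-separated columns: exon_index, g_start, g_end, flag.

def write_gene_model(model: GeneModel, path: str | Path) -> None:
    lines = [
        f"#gene={model.gene_name}\treference={model.reference_id}",
        f"#translation_start_g={model.translation_start_g}\tstop_end_g={model.stop_end_g}",
    ]
    for e in model.exons:
        lines.append(f"{e.index}\t{e.g_start}\t{e.g_end}\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_model(path: str | Path) -> GeneModel:
    text = Path(path).read_text().splitlines()
    if len(text) < 3 or not text[0].startswith("#") or not text[1].startswith("#"):
        raise GeneModelError(f"{path}: expected 2 header lines then exon rows")

    def _kv(line: str) -> dict[str, str]:
        return dict(f.split("=", 1) for f in line.lstrip("#").split("\t"))

    h1, h2 = _kv(text[0]), _kv(text[1])
    exons = []
    for ln, line in enumerate(text[2:], start=3):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise GeneModelError(f"{path}:{ln}: expected 4 columns, got {len(fields)}")
        exons.append(ExonInterval(int(fields[0]), int(fields[1]), int(fields[2])))
    return GeneModel(
        gene_name=h1.get("gene", "?"),
        reference_id=h1.get("reference", "?"),
        exons=exons,
        translation_start_g=int(h2["translation_start_g"]),
        stop_end_g=int(h2["stop_end_g"]),
    )
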
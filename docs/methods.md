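# Methods

## Coordinate model

All genomic coordinates are 1-based inclusive, in *gene-forward*
orientation (the strand on which the gene is transcribed); BED output
converts to 0-based half-open at the writer boundary.  A gene model is a
list of non-overlapping exon intervals plus two CDS anchors: the genomic
position of the A of the start codon and of the last base of the stop
codon.  HGVS-style c. positions follow the standard convention; two
behaviours are worth calling out:

* `c.-n` counts exonic 5'UTR bases and then continues **contiguously into
  upstream genomic sequence** past the start of exon 1 (promoter positions
  such as `c.-1823` are legal), and `c.*n` continues past the last exon's
  end symmetrically.  This is required to express promoter-involving
  deletions.
* Intronic positions reported by `g_to_c` anchor to the *nearer* exon
  boundary; an exact midpoint tie goes to the preceding exon (the `+`
  form).  This makes output canonical and deterministic; note that a
  position near an intron's 3' end therefore renders as `NEXT-k` even if
  another source printed it as `PREV+m` — both denote the same base.

The gene-model file is a small TSV (two `#` header lines carrying the CDS
anchors, then `exon_index, g_start, g_end, flag` rows).  The format is
defined as already gene-forward; minus-strand genes are normalized before
writing the file rather than at load time.

## Junction localization

A junction amplicon is matched against the reference by exact anchor
seeding (default 20 bp at each read end) plus maximal extension.  If the
maximal reference-matching prefix and suffix of the read overlap by *m*
bases, the junction carries *m* bp of microhomology and *m + 1*
sequence-identical breakpoint placements; the reported call is the
leftmost (minimum-coordinate) representative, with the ambiguity count
carried alongside.  If a gap remains instead, it is reported as a
non-templated insertion (insertion and microhomology are mutually
exclusive by construction).  Both read orientations are tried; `N` never
matches; a seed occurring at several positions of a repeat-dense region is
disambiguated by which placement extends furthest, and only an exact tie
is a multi-mapping error.  An optional mismatch budget (default 0) absorbs
isolated sequencing errors during extension; with a non-zero budget the
terminal seed is tiled three deep so an error inside the first 20 bp does
not lose the anchor.  Every call satisfies the reconstruction identity:
left flank + insert + right flank rebuilds the read byte-for-byte.

## Mechanism classification

A junction is called **NAHR** when (i) both breakpoints fall inside repeat
features, (ii) the two parents have the same orientation and the same
class/family string (subfamilies may differ: AluSx1 × AluSx3 qualifies,
Alu × MER83 does not), and (iii) the two junction flanks are homologous
**in register with the junction**: position `left_break + i` is compared
with `right_break − 1 + i` over a ±100 bp window, and the best 20 bp
stretch must reach ≥ 80% identity (thresholds `I_min`, `L_min`, window all
configurable).  The register comparison is the decisive design choice: a
true crossover fuses homologous offsets and scores ≥ 90%, while an NHEJ
break that merely *lands* inside two Alu copies is out of register and
scores near the 25% background — an aligner-based comparison would call
such junctions homologous and systematically overcall NAHR.  The reported
identity/length describe the best stretch greedily extended, so a 31 bp
monomer-insert or an indel between the copies further out does not drown a
genuine crossover; conversely, an indel *between* the crossover and the
window edge lowers the score, which errs toward the conservative side.
**NHEJ** is the fallback for junctions with ≤ 7 bp of microhomology (with
or without an insertion); anything else is **unresolved**.  Degenerate
evidence never raises.  Raising `I_min` or `L_min` can only move calls
from NAHR toward NHEJ/unresolved, never the reverse (the best-window mean
is non-increasing in window length).

The numeric thresholds (80%, 20 bp, 7 bp) are this package's own encoding
of the qualitative dichotomy — "extensive sequence identity" versus "a few
bp" — used in the clinical literature, chosen a priori as round values
that separate those regimes; the source case series classified junctions
by inspection and states no cutoffs.

## Chimeric-element reconstruction

The recombinant at a NAHR junction is the 5' part of the upstream parent
up to the crossover plus the 3' part of the downstream parent after it
(the shared window counted once).  Status:

* `complete_dimer_recombinant` — both parents dimeric and the recombinant
  length within ±25 bp of the parents' mean length (crossovers at
  homologous offsets reproduce a full element);
* `complete_monomer_recombinant` — exactly one parent monomeric (FLAM-like
  or a truncated element) and the crossover inside one of the dimeric
  parent's monomers, completing the fused monomer unit;
* `partial` otherwise; crossovers in A-rich linker/tail tracts can never
  be complete (their alignment register is undefined).

## MLPA model

Within each sample, every probe signal is divided by the sum of that
sample's control-probe signals; the dosage quotient is that ratio divided
by the median ratio across control samples.  DQ < 0.75 → heterozygous
deletion, DQ > 1.25 → heterozygous duplication, strict inequalities;
DQ < 0.25 or > 1.75 adds a `possible_homozygous` flag but keeps the
heterozygous state (the FH cohort context is heterozygous).  Contiguous
same-state exons collapse to `exonX_Ydel/dup`; a low promoter probe
prepends `promoter_` and the label then names only the last affected exon;
non-contiguous or mixed del+dup patterns raise a review error rather than
guessing.  The normalization and thresholds follow common MLPA practice
and are configurable; vendor kit software is not reproduced.

## Synthetic locus generator

The generator is first-class, tested code and defines the study
conditions.  The default locus is an 18-exon gene: exon lengths fixed at
LDLR-like values (first exon carrying a 60 bp 5'UTR, last exon a 2.4 kb
3'UTR), intron lengths drawn per seed from 1.8–3 kb, 3 kb flanks, total
~50 kb.  One master Alu-like dimeric consensus is built per run: left
monomer 132 bp; right monomer = the left-monomer sequence with a 31 bp
insert (at monomer offset 40) plus 3% substitutions; A-rich linker
(10–15 bp, ≥ 80% A by construction) and 3' A-tail (10–20 bp); total
315–330 bp.  Pseudo-subfamilies are derived from the master by 2% seeded
substitutions ("subfamilies of different ages" without an external repeat
library; a real consensus FASTA can be supplied instead), and a FLAM-like
monomeric consensus is the master's left monomer plus a short tail
(~133 bp).  Introns are filled with copies (per-copy divergence drawn from
2–8%, random orientation) to ~65% intronic coverage — about 85–90 copies,
matching the published density of the real locus.  MLPA probes sit at the
midpoint of each exon's *coding* overlap (a probe in a 2.4 kb 3'UTR would
not represent the exon's dosage), plus one promoter probe and eight
control probes.

**NAHR events** pick the crossover uniformly among maximal shared
perfect-identity windows (≥ 20 bp) between the two parents' gene-forward
sequences, found along their best local alignment; windows touching an
element edge are trimmed and A-rich windows (> 70% one base) are excluded
as register-ambiguous.  By construction the junction microhomology equals
the window length and the truth records the leftmost placement.
**NHEJ events** join two breaks with an exact requested microhomology
(0–7 bp) or insertion (0–20 bp): the reference is locally edited to create
the microhomology run and to pin its ends (and the ends of an insertion)
so that requested and recoverable values coincide exactly; all edits are
recorded in the truth.  Junction amplicons are symmetric slices of the
rearranged allele with optional uniform substitution errors; MLPA signals
are `base · (copies/2) · (1 + ε)`, `ε ~ N(0, σ)`, clipped at zero.  All
output is a pure function of `(spec, seed)` through a single
`numpy.random.default_rng` stream per operation.

What the generator does *not* emulate: indel divergence between repeat
copies (substitution-only, so alignments are register-true), inversions
and complex multi-junction events, capillary-trace artefacts upstream of
MLPA signals, and sequencing chromatogram noise beyond uniform
substitutions.  Passing recovery tests therefore demonstrate correctness
of the arithmetic and the classification logic under these conditions, not
robustness to structurally messy real-world data.

## Surrogate LDLR model

The real locus is described by the RefSeqGene record NG_009060, which this
package deliberately does not bundle.  `alusv.ldlr.surrogate_ldlr_model()`
builds a synthetic stand-in from two sets of published facts about the
eight known Czech-cohort rearrangements: the cDNA exon boundaries implied
by their HGVS c. endpoints (e.g. `c.190+566` pins exon 2's last coding
base at c.190; eleven boundaries are pinned this way, the rest are
plausible placeholders consistent with an 860-codon CDS), and their
published genomic sizes, each of which is linear in exactly one
yet-unsolved intron length once the others are fixed — so eight sizes are
solved sequentially for eight intron lengths (1, 2, 8, 9, 12, 14, 15, 17),
with the remaining nine set to placeholders chosen only to keep every
solved length positive and every printed intronic offset inside its
intron.  The builder verifies all eight sizes after solving and raises on
any inconsistency.  Consequence: size checks against this model are
*consistency* checks of the coordinate engine against the published
architecture, not an independent re-derivation from the accession — the
engine itself is validated separately by exhaustive roundtrip enumeration
on randomized toy models.  The model's intron lengths are not the true
LDLR intron lengths.

The eight-event fixture plants the named junction-flanking repeats
(greedily scheduled inside their compartments so each breakpoint sits
≥ 10 bp inside its element and neighbours never overlap) with the
published orientations, then synchronizes a 30 bp tract between each NAHR
parent pair at homologous element offsets — for the two monomer × dimer
events inside the dimer's right monomer, downstream of the 31 bp insert.
Real NAHR substrates show exactly such long perfect tracts (that is what
makes them substrates); synchronizing one makes the fixture deterministic
at every seed instead of relying on run-length statistics of diverged
copies.

## Problem sizes and numerical choices

The test suite and the reproduction script use: 200 mixed events for the
end-to-end battery, 100 samples × 19 probes for MLPA recovery, 1000
instances (≤ 2 kb) for the split-enumeration oracle, 100 trials for
false-positive and error-tolerance rates, and ~10–12 kb regions with ~20
planted copies for the scanner benchmark — sizes at which every battery
completes in seconds while keeping binomial noise well inside the asserted
margins.  Local alignment uses Biopython's `PairwiseAligner` (scanning
defaults: match +2, mismatch −3, gap open −5, gap extend −2, minimum score
60, overlapping windows of ~4 consensus lengths with mask-and-rescan so
tandem copies are all found; hit extents are extended by the unaligned
consensus stubs, since local alignment clips diverged element ends).
Scanner overlap resolution is greedy by score.  Percentages round half-up
to one decimal via `decimal.Decimal` (the convention of printed cohort
tables, immune to binary-float round-to-even surprises).

## Known limitations

* Inversions, and NAHR between inverted repeats, are out of scope (the
  orientation-incompatible error is raised instead).
* Exact per-base agreement of breakpoint coordinates with externally
  printed endpoints is only defined up to the microhomology ambiguity
  interval, and published coordinates are not guaranteed to be
  leftmost-aligned; recovery is therefore always scored within the
  interval.
* The in-register homology measure assumes substitution-level divergence
  between repeat copies; large indels between copies would depress it and
  could demote borderline NAHR calls to unresolved.
* Multi-transcript projection, genome liftover and full HGVS allele
  grammar are not implemented.
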
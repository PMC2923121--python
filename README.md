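# alusv

Breakpoint characterization of large (multi-exon) deletions and duplications
in repeat-dense disease genes — the analysis chain a molecular-genetics lab
runs after an MLPA screen flags a gross rearrangement, modelled on the LDLR
gene in familial hypercholesterolemia (FH).

## The problem

LDLR (18 exons over ~45 kb) is one of the most Alu-dense genes in the human
genome: ~98 Alu elements cover about 65% of its intronic sequence.  That
density makes the locus a hotspot for gross rearrangements, which arise by
two repair pathways with distinct sequence signatures:

* **NAHR** (non-allelic homologous recombination) — two highly similar but
  non-allelic repeats recombine.  Both breakpoints fall inside repeat
  elements of the same family in direct relative orientation, the junction
  shows a long stretch of sequence identity between its flanks, and a
  *chimeric* repeat (5' part of one parent + 3' part of the other) is left
  at the join.  When the crossover offsets line up, the chimera is itself a
  complete element — a "complete recombinant" Alu, or a complete *monomer*
  recombinant when a monomeric element (FLAM, a free left Alu monomer) pairs
  with a full dimer and the crossover sits in the dimer's homologous
  monomer.
* **NHEJ** (non-homologous end joining) — double-strand-break ends are
  ligated with at most a few bases of *microhomology* (sequence shared by
  both flanks, which makes the exact breakpoint ambiguous over
  `mh_len + 1` equivalent placements), sometimes with a short non-templated
  insertion instead.

The package implements every step of the characterization:

| module | role |
| --- | --- |
| `alusv.mlpa` | MLPA dosage quotients (DQ = normalized probe ratio vs. control samples; ~1.0 two copies, <0.75 het deletion, >1.25 het duplication) and exon-span event labels (`exon2_6dup`, `promoter_exon2del`, ...) |
| `alusv.gene_model` | HGVS-style c.↔g. coordinate arithmetic (intronic offsets, promoter `c.-n`, 3'UTR `c.*n`), rearrangement sizes, exon-span naming |
| `alusv.junction` | breakpoint localization from a junction-spanning amplicon: leftmost-aligned breakpoints, microhomology length/sequence, inserted sequence, ambiguity count |
| `alusv.repeats` | RepeatMasker `.out` parsing, breakpoint annotation, Smith–Waterman consensus scanning, chimeric-element reconstruction |
| `alusv.mechanism` | NAHR/NHEJ/unresolved classification from junction + repeat evidence |
| `alusv.synthetic` | seeded generator of Alu-dense loci, NAHR/NHEJ events, junction amplicons and MLPA tables, with exact truth records |
| `alusv.ldlr` | a surrogate LDLR gene model and the battery of eight published Czech-cohort rearrangements (see `docs/methods.md`) |
| `alusv.report` / `alusv.cli` | per-event reports, cohort arithmetic, `alusv` command-line tool |

## Worked example

The bundled battery re-creates the eight published LDLR rearrangements on a
synthetic surrogate locus, simulates a junction amplicon for each, and runs
the full characterization chain:

```
$ alusv report --seed 0
label              hgvs_c                  size_bp mechanism repeat5          repeat3          mh_len
promoter_exon2del  c.-1947_190+443del      13187   NAHR      AluY/SINE/Alu    AluY/SINE/Alu    36
exon2_6dup         c.67+3741_940+85dup     14244   NAHR      AluSx1/SINE/Alu  AluSx3/SINE/Alu  24
exon3_12del        c.190+912_1846-1240del  17596   NAHR      FLAM_A/SINE/Alu  AluY/SINE/Alu    61
exon4_8dup         c.314-446_1187-386dup   8119    NHEJ      AluSx1/SINE/Alu  MER83/LTR/ERV1   2
exon5_10del        c.695-67_1587-30del     7636    NHEJ      AluJo/SINE/Alu   AluSx1/SINE/Alu  4
exon9_14del        c.1186+472_2140+137del  10292   NAHR      AluYa5/SINE/Alu  AluY/SINE/Alu    25
exon9_15del        c.1187-272_2312-1068del 13935   NAHR      AluJb/SINE/Alu   AluSx1/SINE/Alu  71
exon16_18dup       c.2311+1672_*946dup     7247    NAHR      AluYb8/SINE/Alu  AluSq2/SINE/Alu  23
{"total": {"NAHR": 6, "NHEJ": 2, "unresolved": 0}, ...}
```

Reading the table: each row is one characterized junction.  `hgvs_c` and
`size_bp` describe the rearranged segment implied by the *leftmost-aligned*
recovered breakpoints — within a junction's microhomology tract every
placement is sequence-identical, so coordinates (and hence sizes) are only
defined up to that ambiguity; the NAHR rows sit a few bases off the planted
coordinates for exactly that reason, while the two NHEJ rows (2 and 4 bp of
microhomology) match them exactly.  The tally line is the mechanism summary:
six NAHR events (long flank identity between same-family, same-orientation
repeats) and two NHEJ events — one joining an Alu to a MER83 (LTR/ERV1)
element with 2 bp of microhomology, one joining two oppositely oriented Alus
with 4 bp.

Other subcommands: `alusv simulate` (synthetic locus + truth files),
`alusv mlpa-call` (DQ table + event label from a probe-signal TSV),
`alusv characterize` (junction FASTA → report TSV/JSON/BED),
`alusv coords` (c.↔g. conversion, e.g.
`alusv coords --model ldlr.tsv --range c.-1823_190+566 --size` → `13186`).

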
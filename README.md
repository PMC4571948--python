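# armotif

Sequence-analysis toolkit for the **ankyrin-repeat-binding ΨβXXQP motif**
recognized by the Golgi S-acyltransferases **zDHHC17** (HIP14) and
**zDHHC13** (HIP14L).

These two enzymes recruit substrates such as SNAP25b, CSPα and Huntingtin
through their N-terminal ankyrin-repeat (AR) domain, which recognizes a
short linear motif in intrinsically disordered regions of its partners:

```
Ψ β X X Q P        Ψ ∈ {V, I, A, P}   (aliphatic, Leu excluded)
                   β ∈ {V, I, T}      (C-beta-branched)
                   X   any residue; Gln-Pro invariant
```

with three mutually exclusive submotifs `[VIA][VI]XXQP`, `P[VI][VIL]XQP`
and `Q[VI]TXXQP` (the last requires a Gln immediately upstream). `armotif`
is aimed at researchers triaging candidate zDHHC17/13 interactors: it
implements the motif grammar and scanner, in-silico point-mutation rescans,
ortholog conservation calls via BLOSUM62 global alignment, an
intrinsic-disorder filter with two-predictor rescue logic, the staged
candidate-prioritization cascade, a neighbor-joining phylogeny of
AR-containing zDHHC enzymes, and seeded synthetic-data generators with
ground truth for end-to-end testing.

## Worked example

```python
from armotif import (ProteinRecord, bundled_definitions, scan,
                     parse_mutation, predict_mutation_effect)

peptide = ProteinRecord(id="SNAP25b_111_120", sequence="GVVASQPARV",
                        numbering_offset=111)
hit = scan(peptide, bundled_definitions("all"))[0]
print(hit.matched, hit.start, hit.end, hit.q_position, hit.p_position)
# VVASQP 112 117 116 117

defs = bundled_definitions("general")
for label in ("V112A", "V113A", "Q116A", "P117A"):
    eff = predict_mutation_effect(peptide, parse_mutation(label), defs)
    print(label, eff.classification)
# V112A retained   (Ala is itself an allowed aliphatic residue)
# V113A lost       (Ala is not C-beta-branched)
# Q116A lost       (invariant Gln)
# P117A lost       (invariant Pro)
```

The ten-residue SNAP25b peptide carries exactly one consensus hit at
residues 112–117; the invariant Gln and Pro land on Gln116 and Pro117, the
residues whose truncation or substitution abolishes zDHHC17/13 binding.
In relaxed mode, terminal-Pro substitutions to Val or Ile are graded
`partial` (they only partially preserve the interaction) while Gly/Ser/Thr
are `lost`.

The `examples/` directory holds one short narrative script per capability
(scanning, mutation rescans, conservation, disorder filtering,
prioritization, NJ trees, simulation); each prints the numbers it computes
and states what they mean. A thin CLI mirrors the library:

```sh
armotif scan --fasta peptide.fasta --offset 111 --motifs all
armotif prioritize --candidates candidates.tsv
armotif tree --fasta zdhhc_ar.fasta --out tree.nwk
```

## Candidate prioritization

`run_cascade` reproduces the staged narrowing used to build the published
candidate table: motif presence → physiological-binding evidence
(Golgi/plasma-membrane localization, S-acylation, zDHHC13 interaction, or
homology to a qualified protein) → motif in a predicted-disordered region,
with experimentally studied proteins entering the final set by experiment.
A bundled, clearly labelled *synthetic* reconstruction of the 20-candidate
table (`armotif.load_bundled_candidates()`) reproduces the published
summary counts; see `docs/methods.md` for exactly what is and is not
transcribed from the source.

## Limitations

Motif integrity is the only quantity modelled: binding determinants outside
the six-residue consensus (e.g. HTT Thr496 and Arg500, whose substitution
impairs binding experimentally) are invisible to the scanner, and no
binding-affinity prediction is attempted. See `docs/methods.md`.
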
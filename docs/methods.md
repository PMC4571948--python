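# Methods

## The motif model

The AR domains of zDHHC17 and zDHHC13 recognize a six-residue short linear
motif (SLiM), ΨβXXQP, in intrinsically disordered regions of their binding
partners. `armotif` models it as a strict position-class pattern — an
ordered list of allowed-residue sets — not as a PSSM: the motif was defined
from a handful of experimentally validated sequences, and class membership,
not frequency, is what the mutagenesis data support.

* Ψ = {V, I, A, P}. Leucine is excluded deliberately; it is the one
  aliphatic residue the motif definition rules out.
* β = {V, I, T} (C-beta-branched).
* X positions accept all 20 standard residues.
* Positions 5 and 6 are invariant Gln and Pro.

Three submotifs restrict the consensus: `[VIA][VI]XXQP`; `P[VI][VIL]XQP`
(when Pro occupies Ψ, a third aliphatic position is required); and
`Q[VI]TXXQP` (when Thr occupies β, a Gln is required immediately upstream).
The upstream Gln is a *context* residue: it is required for the submotif to
match but is not part of the reported hit span, so every hit is six
residues long and hits are comparable across submotifs. A hit at the very
first sequence position can never satisfy the context submotif
(`context_ok=False`). The three submotifs are pairwise exclusive on any
window (their Ψ/β class combinations are disjoint), and each implies the
general consensus; both properties are asserted by exhaustive enumeration
in the test suite.

Residues are the 20 standard uppercase letters; lowercase input is
uppercased on ingest, and any other letter (B, Z, X, U, J, O, `*`)
silently fails every class — ambiguity codes are data to skip, not errors.

### Relaxed terminal mode

Substituting the invariant Pro with Val or Ile only partially preserves
binding, while Gly/Ser/Thr abolish it. Relaxed mode therefore admits
{V, I} at the terminal position as a `partial` qualifier rather than a
match; it is **off by default** because partial restoration is a grading of
an impaired interaction, not an alternative motif. Mutation rescans
classify a substitution as `retained` (a full hit still covers the original
span), `partial` (only a relaxed hit does) or `lost`.

### Known limitation

The scanner models motif integrity only. HTT T496A and R500A impair binding
experimentally yet are classified `retained` here: Thr496 sits on an
unconstrained X position and Arg500 lies outside the hexamer. Binding
evidently also depends on residues outside the class-constrained consensus
(possibly via phosphorylation of Ser/Thr in the variable positions); no
attempt is made to model that, and the concordance tests assert the
`retained` calls as documented scanner behaviour.

## Coordinates

All coordinates are 1-based, inclusive, in protein numbering: a record's
`numbering_offset` gives the residue number of its first position, so the
peptide spanning residues 111–120 of SNAP25b reports its hit at 112–117
with the invariant Gln at 116. Overlapping hits are all reported (the
analysis never deduplicates); ties are ordered by start.

## Alignment and conservation

Ortholog comparison uses optimal global (Needleman–Wunsch) alignment under
BLOSUM62 with affine gaps, open 10 and extend 0.5 (a gap of length L costs
`10 + 0.5·(L−1)`); these are CLUSTALW-like defaults, fixed in the pipeline
config since nothing stronger is specified by the source analysis. The
implementation is Bio.Align.PairwiseAligner; co-optimal alignments are
resolved deterministically by taking the aligner's first enumerated
traceback. Scores are validated in the tests against an exhaustive
enumeration of all alignments of short pairs.

Pairwise reference-versus-ortholog alignments substitute for a progressive
multiple alignment: only the correspondence of the six motif columns is
needed, and pairwise NW is exactly specifiable and testable. A motif is
called **conserved** across an ortholog set when every ortholog's mapped
six-residue segment is gap-free and itself matches the general consensus —
conservation is class-level, not identity-level, since orthologous motifs
visibly exchange residues within a class. A gap inside the mapped segment
is a negative call, not an error. Per-position categories follow the
bold-type convention of the published table: `absolute` (identical in all
sequences), `equivalent` (differences confined to Val/Ile or Ser/Thr),
`other`.

Column shading of aligned sets uses the fraction of sequence pairs with a
strictly positive BLOSUM62 score (gap pairs count as dissimilar): `black`
at fraction 1.0, `gray` in [0.6, 0.8], `none` otherwise. The legend this
implements names the matrix but not the statistic; the thresholds live in
the config so the statistic can be swapped.

## Disorder filter

External disorder predictors are web tools and are deliberately not
re-implemented. The built-in stand-in is a FoldIndex-style windowed score:
over a window of width `w` (default 21, odd, clamped at the termini) let
H be the mean Kyte–Doolittle hydropathy rescaled to [0, 1] via
`(kd + 4.5)/9` and R the absolute mean net charge (K, R = +1; D, E = −1);
the score is `I = 2.785·H − R − 1.151`, disordered iff `I < 0`. The
built-in track has no secondary-structure model, so its coil calls equal
its disorder calls; external tracks (TSV: position, residue, score, call,
optional coil) may carry real coil calls and are cross-checked residue by
residue against the record.

The motif-level filter requires **all six** hit residues disordered in the
primary track — the strictest reading of "lies within a disordered region";
a `majority` rule (≥ 4 of 6) is available in config since the source
procedure does not state whether partial overlap sufficed. The
two-predictor rescue is preserved exactly: a hit that is all-coil but not
disordered in the primary track passes if a secondary track calls all six
residues disordered. The filter is monotone in the primary calls.

## Prioritization cascade

Stage 1 keeps candidates with at least one submotif hit; stage 2 keeps
those with any of the four physiology flags (Golgi/PM localization,
S-acylation, zDHHC13 interaction, homology to a qualified protein — an OR,
following the procedure's own parenthetical list); stage 3 applies the
disorder filter. Stages are nested, so the per-stage counts are
non-increasing. The final set is the union of stage-3 survivors and
candidates flagged `tested_in_this_study`: the experimentally studied
proteins enter the table by experiment, not by the cascade. Footnote-style
flag counts (S-acylated, zDHHC17 substrate, zDHHC13 interactor, motif
conserved) are computed over the final set only, because the published
counts refer to the final 20 proteins. Candidates may be full sequences or
printed motif-region segments; a provenance column records which. Rows are
sorted by protein id and reports are byte-deterministic.

Disorder input for the cascade resolves in order: an explicit per-candidate
track, a `disordered` passthrough call from the candidate table, then the
built-in predictor on the candidate's own sequence. The passthrough exists
because region-only candidates are six-to-ten residue segments on which a
21-residue windowed score is meaningless, and the curated table is by
construction restricted to motifs already predicted disordered.

### The bundled candidate table

`data/table1_candidates_synthetic.tsv` is a **synthetic reconstruction**,
labelled as such: the published per-protein table is available only as an
image. The six studied proteins carry their printed signatures (VVASQP in
SNAP25b 111–120, IITEQP at HTT 494–499, VTMTQP with its upstream Gln in
CLIP3, VSKQP in SNAP23, AIETQP in MAP6, IVIQP in CSPα); residues the source
does not print (the Ψ residue of the CSPα and SNAP23 signatures, HTT
501–502, all flanks) are neutral filler, and the 14 remaining candidates
carry engineered submotif segments under their real gene symbols. Evidence
flags are assigned to reproduce the published marginal counts exactly
(final set 20; 15 S-acylated; 10 zDHHC17 substrates; 8 zDHHC13 interactors;
12 conserved; 14 beyond the six tested) while honouring the prose
constraints (JNK2 not S-acylated; MAP6 S-acylated by other enzymes but not
a zDHHC17 substrate; NMNAT2 a substrate; MMP14 a zDHHC13-only interactor).
Passing the count checks therefore shows the cascade arithmetic and the
fixture's consistency with the published totals — not a re-derivation of
the table from primary interaction screens, which are out of scope. The
17 → 15 → 14 narrowing of the wider search is likewise exercised on
generator-engineered tables, since the identity of those candidates is not
published.

## Neighbor-joining phylogeny

Distances are `1 − fractional identity` over the pairwise global alignment
(columns with a gap in either row count against identity); this matches
common sequence-identity tree builders, and nothing more specific is
stated by the source. Tree construction is Saitou–Nei NJ: minimize
`Q(i,j) = (N−2)·d(i,j) − r_i − r_j`, join, assign branch lengths, reduce,
and finish with an unrooted trifurcation. Ties in Q are broken by the
lowest index pair; negative branch lengths are reported as computed with a
logged warning. NJ is consistent on additive matrices, which the tests
exploit: trees regenerated from 50 random additive matrices are recovered
exactly (Robinson–Foulds distance 0), and the implementation is
cross-checked against an independent NJ implementation. Reproducing the
published zDHHC tree requires the UniProt sequences named in its figure;
`examples/06_nj_tree.py` shows the recipe on synthetic families instead.

## Synthetic-data generators

All generators draw from per-generator streams derived from one master
seed and are byte-deterministic. Background residues are uniform over the
20 letters by default — uniformity makes the consensus false-positive rate
analytically checkable at `(4/20)(3/20)(1/20)(1/20) = 1.5×10⁻⁴` per window
— which also means the background lacks the compositional bias of real
disordered regions; passing the round-trip tests demonstrates scanner and
pipeline correctness, not performance on natural proteomes.

* **Proteomes**: per-protein implant counts are Poisson at the requested
  density (capped by placement capacity); implants are sampled uniformly
  from each submotif's classes, placed without overlap, with the context
  Gln written for the Thr-form submotif. Truth tables list exact
  coordinates; scanner recall on truth is total by construction.
* **Decoys**: valid consensus windows with exactly one class-constrained
  position (1, 2, 5 or 6 — the X positions cannot be violated) replaced by
  an out-of-class residue, embedded in glycine flanks chosen so no shifted
  window can match.
* **Ortholog triples**: frog-like and zebrafish-like derivatives substitute
  non-motif positions at the requested rate (default 0.1, roughly the
  divergence where class-level conservation is informative) and either
  preserve the motif span (plus its upstream context residue) or ablate one
  constrained position.
* **Candidate tables**: flags and engineered disorder tracks are set so the
  cascade yields exact target stage counts; infeasible (increasing) targets
  are rejected.

## Problem sizes and numerical choices

Test and acceptance workloads are desk-scale by design: 200 random
500-mers for the scanner oracle, alignment enumeration on pairs up to
8-mers, 50 additive matrices of 5–10 taxa, 100 ortholog replicates of
~170-residue proteins, 20-to-40-protein synthetic proteomes. Floating-point
comparisons in shading use a 1e-9 tolerance on pair fractions; distance
matrices are validated symmetric within 1e-9 with exact-zero diagonals.
The disorder formula's constants are part of its definition and are not
fitted.
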
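"""Motif scanning of protein records and in-silico point-mutation rescans.

Coordinates are 1-based and inclusive, expressed in *protein numbering*: a
record carries a ``numbering_offset`` giving the residue number of its first
sequence position, so a peptide excised from residues 111–120 of a protein
reports hits at their native positions (e.g. Val112–Pro117).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

from .motifs import (
    MotifDefinition,
    RELAXED_TERMINAL,
    build_general_consensus,
    evaluate_window,
)

_GENERAL = build_general_consensus()


@dataclass(frozen=True)
class ProteinRecord:
    """A protein (or peptide) sequence with its numbering convention."""

    id: str
    sequence: str
    description: str = ""
    numbering_offset: int = 1

    def __post_init__(self):
        seq = str(self.sequence).upper()
        if not seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, position: int) -> str:
        """Residue at a protein-numbering position."""
        idx = position - self.numbering_offset
        if not 0 <= idx < len(self.sequence):
            raise IndexError(
                f"position {position} outside {self.id} "
                f"({self.numbering_offset}–{self.numbering_offset + len(self) - 1})"
            )
        return self.sequence[idx]


@dataclass(frozen=True)
class MotifHit:
    """One matched window, in protein numbering (end − start = 5)."""

    protein_id: str
    start: int
    end: int
    matched: str
    general: bool
    submotif_labels: tuple = ()
    context_ok: bool = True
    qualifier: str = "full"  # "full" | "partial"

    @property
    def q_position(self) -> int:
        """Protein-numbering coordinate of the invariant Gln (core position 5)."""
        return self.start + 4

    @property
    def p_position(self) -> int:
        """Protein-numbering coordinate of the invariant Pro (core position 6)."""
        return self.start + 5

    def span(self):
        return (self.start, self.end)


def scan(
    record: ProteinRecord,
    definitions: Sequence[MotifDefinition],
    relaxed: bool = False,
) -> List[MotifHit]:
    """Scan every window of *record* against *definitions*.

    All overlapping hits are reported, sorted by start. One hit is emitted
    per matching window, labelled with every supplied submotif-style
    definition that matches it; the ``general`` flag records whether the
    window satisfies the general ΨβXXQP consensus regardless of which
    definitions were supplied. In relaxed mode a window whose only defect is
    Val/Ile at the terminal-Pro position is reported with
    ``qualifier="partial"``.

    ``context_ok`` is False when a context-requiring definition matched on
    core classes but the required upstream residue was absent or wrong (a
    hit at the first sequence position can never satisfy it); such a
    definition does not contribute a label.
    """
    if not definitions:
        raise ValueError("at least one motif definition is required")
    seq = record.sequence
    defs = [d.relaxed() if relaxed else d for d in definitions]
    general_def = _GENERAL.relaxed() if relaxed else _GENERAL
    hits: List[MotifHit] = []
    width = len(defs[0])
    if any(len(d) != width for d in defs):
        raise ValueError("all definitions must have the same core length")
    for i in range(len(seq) - width + 1):
        window = seq[i : i + width]
        upstream = seq[i - 1] if i > 0 else None
        labels = []
        qualifiers = []
        context_ok = True
        for d in defs:
            m = evaluate_window(d, window, upstream)
            if d.upstream_context is not None and m.core_ok and not m.context_ok:
                context_ok = False
            if m.matched:
                labels.append(d.name)
                qualifiers.append(m.qualifier)
        if not labels:
            continue
        gm = evaluate_window(general_def, window, upstream)
        hits.append(
            MotifHit(
                protein_id=record.id,
                start=record.numbering_offset + i,
                end=record.numbering_offset + i + width - 1,
                matched=window,
                general=gm.matched and gm.qualifier == "full",
                submotif_labels=tuple(
                    l for l in labels if l != general_def.name
                ),
                context_ok=context_ok,
                qualifier="full" if "full" in qualifiers else "partial",
            )
        )
    return hits


# --- mutations --------------------------------------------------------------

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class Mutation:
    """A single point substitution in protein numbering, e.g. P117A."""

    position: int
    wild_type: str
    substituted: str

    @property
    def label(self) -> str:
        return f"{self.wild_type}{self.position}{self.substituted}"


def parse_mutation(label: str) -> Mutation:
    """Parse a ``<WT><position><substituted>`` label such as ``V112A``."""
    m = _MUTATION_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed mutation label {label!r}")
    wt, pos, sub = m.groups()
    return Mutation(position=int(pos), wild_type=wt.upper(), substituted=sub.upper())


def apply_mutation(record: ProteinRecord, mutation: Mutation) -> ProteinRecord:
    """Apply a substitution, checking the stated wild-type residue."""
    actual = record.residue_at(mutation.position)
    if actual != mutation.wild_type:
        raise ValueError(
            f"wild-type mismatch at {mutation.position} of {record.id}: "
            f"label says {mutation.wild_type}, sequence has {actual}"
        )
    idx = mutation.position - record.numbering_offset
    seq = record.sequence[:idx] + mutation.substituted + record.sequence[idx + 1 :]
    return replace(record, sequence=seq)


@dataclass(frozen=True)
class MutationEffect:
    """Rescan outcome for one mutation."""

    classification: str  # "retained" | "partial" | "lost"
    before: tuple
    after: tuple
    per_hit: dict = field(default_factory=dict)  # (start, end) -> status


def predict_mutation_effect(
    record: ProteinRecord,
    mutation: Mutation,
    definitions: Sequence[MotifDefinition],
    relaxed: bool = False,
) -> MutationEffect:
    """Classify a substitution by rescanning the mutated sequence.

    For each wild-type hit span: ``retained`` if a full-qualifier hit still
    covers exactly that span after mutation, ``partial`` if only a
    relaxed-qualifier hit does, ``lost`` otherwise. The overall
    classification is the best outcome over the wild-type hits
    (retained > partial > lost). Binding determinants outside the motif are
    deliberately not modelled.
    """
    before = scan(record, definitions, relaxed=relaxed)
    if not before:
        raise ValueError(
            f"no motif hit in {record.id}; nothing to assess for {mutation.label}"
        )
    mutated = apply_mutation(record, mutation)
    after = scan(mutated, definitions, relaxed=relaxed)
    after_spans = {h.span(): h.qualifier for h in after}
    # full beats partial if both present at a span
    for h in after:
        if h.qualifier == "full":
            after_spans[h.span()] = "full"
    per_hit = {}
    for h in before:
        q = after_spans.get(h.span())
        if q == "full":
            per_hit[h.span()] = "retained"
        elif q == "partial":
            per_hit[h.span()] = "partial"
        else:
            per_hit[h.span()] = "lost"
    order = {"retained": 0, "partial": 1, "lost": 2}
    classification = min(per_hit.values(), key=order.__getitem__)
    return MutationEffect(
        classification=classification,
        before=tuple(before),
        after=tuple(after),
        per_hit=per_hit,
    )
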
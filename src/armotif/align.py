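"""Pairwise global alignment, motif-position mapping and conservation calls.

Orthologs are compared by optimal global (Needleman–Wunsch) alignment under
BLOSUM62 with affine gap penalties (default open 10, extend 0.5, a gap of
length L costing ``open + (L-1)*extend``). Motif conservation across a
reference-plus-orthologs set follows the class-level reading of the
consensus: a motif counts as conserved when every ortholog's aligned,
gap-free six-residue segment itself satisfies the general ΨβXXQP pattern —
individual residues may differ as long as they stay within their position
class. Per-position categories mirror the bold-type rule used for the
human/frog/zebrafish comparison (absolute identity, or the conservative
Val/Ile and Ser/Thr exchanges), and column shading follows the
BLOSUM62-positive pairwise-similarity fractions (black = all pairs similar,
gray = 60–80% of pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .motifs import build_general_consensus
from .scan import MotifHit, ProteinRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")

_GENERAL = build_general_consensus()


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment of sequences *a* and *b*."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    @property
    def column_map(self) -> Dict[int, int]:
        """Map from 0-based ungapped positions of *a* to alignment columns."""
        mapping = {}
        pos = 0
        for col, res in enumerate(self.aligned_a):
            if res != "-":
                mapping[pos] = col
                pos += 1
        return mapping

    def map_to_b(self, a_position: int) -> Optional[str]:
        """Residue of *b* aligned to 0-based position *a_position* of *a*.

        Returns ``None`` when that column holds a gap in *b*.
        """
        col = self.column_map[a_position]
        res = self.aligned_b[col]
        return None if res == "-" else res


def nw_align(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> AlignmentResult:
    """Optimal global alignment of two residue strings under BLOSUM62.

    Ties among co-optimal alignments are resolved deterministically by
    taking the aligner's first enumerated traceback.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a.upper(), b.upper())[0]
    return AlignmentResult(
        aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=float(aln.score)
    )


# --- ortholog conservation --------------------------------------------------

@dataclass(frozen=True)
class OrthologSet:
    """A reference record (human) plus at least one ortholog record."""

    reference: ProteinRecord
    orthologs: dict  # species -> ProteinRecord

    def __post_init__(self):
        if not self.orthologs:
            raise ValueError("an OrthologSet needs at least one ortholog")


@dataclass(frozen=True)
class ConservationCall:
    """Per-position conservation categories and the overall call.

    Categories: ``absolute`` (identical in all sequences), ``equivalent``
    (differences confined to Val/Ile or Ser/Thr), ``other``.
    """

    per_position: tuple  # length 6
    motif_conserved: bool
    ortholog_segments: dict  # species -> segment or None (gap)

    def __post_init__(self):
        if len(self.per_position) != 6:
            raise ValueError("per_position must have length 6")


_EQUIVALENT_GROUPS = (frozenset("VI"), frozenset("ST"))


def _position_category(residues: Sequence[Optional[str]]) -> str:
    if any(r is None for r in residues):
        return "other"
    rs = {r.upper() for r in residues}
    if len(rs) == 1:
        return "absolute"
    if any(rs <= g for g in _EQUIVALENT_GROUPS):
        return "equivalent"
    return "other"


def motif_conserved(
    ortholog_set: OrthologSet,
    hit: MotifHit,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ConservationCall:
    """Class-level conservation of a reference motif hit across orthologs.

    Each ortholog is globally aligned to the reference; the six hit columns
    are mapped through the alignment. The motif is conserved iff every
    ortholog's mapped segment is gap-free and itself matches the general
    consensus. A gap inside a mapped segment yields ``motif_conserved=False``
    (it is a negative call, not an error).
    """
    ref = ortholog_set.reference
    start_idx = hit.start - ref.numbering_offset
    if not (0 <= start_idx and start_idx + 6 <= len(ref.sequence)):
        raise ValueError(f"hit {hit.start}-{hit.end} outside reference {ref.id}")
    per_residue: List[List[Optional[str]]] = [
        [ref.sequence[start_idx + k]] for k in range(6)
    ]
    segments: Dict[str, Optional[str]] = {}
    conserved = True
    for species, rec in ortholog_set.orthologs.items():
        res = nw_align(ref.sequence, rec.sequence, gap_open, gap_extend)
        mapped = [res.map_to_b(start_idx + k) for k in range(6)]
        for k in range(6):
            per_residue[k].append(mapped[k])
        if any(r is None for r in mapped):
            segments[species] = None
            conserved = False
            continue
        segment = "".join(mapped)
        segments[species] = segment
        if not all(
            cls.accepts(res) for cls, res in zip(_GENERAL.core, segment)
        ):
            conserved = False
    categories = tuple(_position_category(rs) for rs in per_residue)
    return ConservationCall(
        per_position=categories,
        motif_conserved=conserved,
        ortholog_segments=segments,
    )


# --- similarity shading -----------------------------------------------------

def pair_similar(a: str, b: str) -> bool:
    """True iff both residues are non-gap and their BLOSUM62 score is positive."""
    if a == "-" or b == "-":
        return False
    try:
        return float(BLOSUM62[a.upper(), b.upper()]) > 0
    except (KeyError, IndexError):
        return False


def shading_categories(
    aligned: Sequence[str], gray_low: float = 0.6, gray_high: float = 0.8
) -> List[str]:
    """Per-column shading of an aligned set: ``black`` / ``gray`` / ``none``.

    A column is black when every sequence pair scores positive under
    BLOSUM62 (gap pairs count as non-similar), gray when the similar-pair
    fraction falls within [gray_low, gray_high], and unshaded otherwise.
    """
    if len(aligned) < 2:
        raise ValueError("shading requires at least 2 aligned sequences")
    ncol = len(aligned[0])
    if any(len(s) != ncol for s in aligned):
        raise ValueError("aligned sequences must have equal length")
    eps = 1e-9
    out = []
    for col in range(ncol):
        column = [s[col] for s in aligned]
        pairs = list(combinations(column, 2))
        frac = sum(pair_similar(x, y) for x, y in pairs) / len(pairs)
        if frac >= 1.0 - eps:
            out.append("black")
        elif gray_low - eps <= frac <= gray_high + eps:
            out.append("gray")
        else:
            out.append("none")
    return out
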
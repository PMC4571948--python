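"""Seeded synthetic-data generators with attached ground truth.

Every input class the pipeline consumes can be generated here so that each
stage is testable without external downloads: proteomes with submotif
instances implanted at a controlled density, decoys violating exactly one
motif position, ortholog triples (reference / frog-like / zebrafish-like)
with a controlled non-motif substitution rate, and candidate tables
engineered to yield chosen per-stage cascade counts.

All generators are fully deterministic under their seed; per-generator
streams are derived from one master seed so outputs are byte-identical
across runs. Background residues are drawn uniformly from the 20 standard
letters by default (uniformity makes the false-positive rate of the general
consensus analytically checkable: (4/20)(3/20)(1/20)(1/20) = 1.5e-4 per
window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import OrthologSet
from .disorder import DisorderTrack
from .motifs import STANDARD_AA, build_general_consensus, build_submotifs
from .prioritize import Candidate, CandidateAnnotation
from .scan import MotifHit, ProteinRecord, scan

AA = "".join(sorted(STANDARD_AA))

_GENERAL = build_general_consensus()
_SUBMOTIFS = build_submotifs()

# positions of the general consensus that are class-constrained (0-based);
# the two X positions admit every residue and cannot be violated
_CONSTRAINED = (0, 1, 4, 5)

# stream ids for per-generator derived RNG streams
_STREAMS = {"proteome": 1, "decoys": 2, "orthologs": 3, "candidates": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class SyntheticSpec:
    """Study conditions for the generators."""

    seed: int = 0
    n_proteins: int = 50
    length_range: Tuple[int, int] = (300, 600)
    motif_density: float = 1.0  # expected implanted motifs per protein
    submotif_mix: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ortholog_subst_rate: float = 0.1
    preserve_motif: bool = True
    cascade_targets: Optional[Tuple[int, int, int]] = None

    def __post_init__(self):
        if abs(sum(self.submotif_mix) - 1.0) > 1e-9:
            raise ValueError("submotif_mix proportions must sum to 1")
        if not 0.0 <= self.ortholog_subst_rate <= 1.0:
            raise ValueError("ortholog_subst_rate must be in [0, 1]")
        if self.motif_density < 0:
            raise ValueError("motif_density must be non-negative")
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid length_range")


def _sample_window(rng: np.random.Generator, submotif_index: int) -> Tuple[str, bool]:
    """Sample a hexamer uniformly from a submotif's classes.

    Returns ``(window, needs_context_q)``.
    """
    d = _SUBMOTIFS[submotif_index]
    window = "".join(
        rng.choice(sorted(cls.allowed)) for cls in d.core
    )
    return window, d.upstream_context is not None


def gen_proteome(spec: SyntheticSpec):
    """Proteome with implanted submotif instances and a coordinate truth table.

    Returns ``(records, truth)`` where truth is a DataFrame with columns
    protein_id, start, end, submotif, window (coordinates 1-based, inclusive,
    context Gln not part of the span). The number of implants per protein is
    Poisson with mean ``motif_density``, capped by what fits.
    """
    rng = _rng(spec.seed, "proteome")
    lo, hi = spec.length_range
    if spec.motif_density > 0 and hi < 7:
        raise ValueError("length_range too short to place a motif with context")
    records: List[ProteinRecord] = []
    truth_rows = []
    aa = np.array(list(AA))
    for p in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(aa, size=length))
        n_implants = int(rng.poisson(spec.motif_density))
        # slot model: segments of 7 (context slot + hexamer) placed without overlap
        max_slots = length // 8
        n_implants = min(n_implants, max_slots)
        placed = []  # (segment_start, segment_end) 0-based inclusive, incl. context slot
        for _ in range(n_implants):
            sub = int(rng.choice(3, p=list(spec.submotif_mix)))
            window, needs_q = _sample_window(rng, sub)
            ok = None
            for _attempt in range(200):
                s = int(rng.integers(1, length - 6))  # leave room for upstream residue
                if all(not (s - 1 <= e and b <= s + 6) for b, e in placed):
                    ok = s
                    break
            if ok is None:
                continue
            seq[ok : ok + 6] = list(window)
            if needs_q:
                seq[ok - 1] = "Q"
            placed.append((ok - 1, ok + 5))
            truth_rows.append(
                {
                    "protein_id": f"synth_{p:04d}",
                    "start": ok + 1,
                    "end": ok + 6,
                    "submotif": _SUBMOTIFS[sub].name,
                    "window": window,
                }
            )
        records.append(
            ProteinRecord(
                id=f"synth_{p:04d}",
                sequence="".join(seq),
                description=f"synthetic proteome seed={spec.seed}",
            )
        )
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "start", "end", "submotif", "window"]
    )
    return records, truth


def gen_decoys(n: int, seed: int = 0, violate_position: Optional[int] = None):
    """Decoy records: valid consensus windows broken at exactly one position.

    Each decoy is a general-consensus hexamer with one class-constrained
    position (1, 2, 5 or 6, 1-based) replaced by a residue outside its
    class, embedded in glycine flanks so no shifted window can match.
    Returns ``(records, truth)``; truth records the violated position and
    the out-of-class residue.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, "decoys")
    records = []
    rows = []
    for k in range(n):
        window = list(
            "".join(rng.choice(sorted(cls.allowed)) for cls in _GENERAL.core)
        )
        pos = (
            int(rng.choice(_CONSTRAINED))
            if violate_position is None
            else violate_position - 1
        )
        if pos not in _CONSTRAINED:
            raise ValueError("violate_position must be one of 1, 2, 5, 6")
        outside = sorted(STANDARD_AA - _GENERAL.core[pos].allowed)
        replacement = str(rng.choice(outside))
        original = window[pos]
        window[pos] = replacement
        records.append(
            ProteinRecord(
                id=f"decoy_{k:04d}",
                sequence="GGG" + "".join(window) + "GGG",
                description="single-violation decoy",
            )
        )
        rows.append(
            {
                "protein_id": f"decoy_{k:04d}",
                "violated_position": pos + 1,
                "original": original,
                "replacement": replacement,
                "window": "".join(window),
            }
        )
    return records, pd.DataFrame(rows)


def gen_ortholog_triple(record: ProteinRecord, spec: SyntheticSpec):
    """Derive frog-like and zebrafish-like orthologs from a reference.

    Non-motif positions are substituted independently at
    ``ortholog_subst_rate``; the motif span (plus the residue immediately
    upstream, protecting any context Gln) is preserved when
    ``preserve_motif`` is true, otherwise ablated by one class-violating
    substitution per ortholog. Returns ``(OrthologSet, truth_dict)``.
    """
    hits = scan(record, [_GENERAL])
    if not hits:
        raise ValueError(f"record {record.id} contains no motif hit")
    hit = hits[0]
    rng = _rng(spec.seed, "orthologs")
    start = hit.start - record.numbering_offset
    protected = set(range(max(start - 1, 0), start + 6))
    orthologs = {}
    truth: Dict[str, object] = {"preserve_motif": spec.preserve_motif, "hit": hit}
    for species in ("frog_like", "zebrafish_like"):
        seq = list(record.sequence)
        n_subst = 0
        for i in range(len(seq)):
            if i in protected:
                continue
            if rng.random() < spec.ortholog_subst_rate:
                choices = [a for a in AA if a != seq[i]]
                seq[i] = str(rng.choice(choices))
                n_subst += 1
        if not spec.preserve_motif:
            pos = int(rng.choice(_CONSTRAINED))
            outside = sorted(STANDARD_AA - _GENERAL.core[pos].allowed)
            seq[start + pos] = str(rng.choice(outside))
        orthologs[species] = ProteinRecord(
            id=f"{record.id}_{species}",
            sequence="".join(seq),
            numbering_offset=record.numbering_offset,
        )
        truth[f"n_substitutions_{species}"] = n_subst
    return OrthologSet(reference=record, orthologs=orthologs), truth


# background alphabet for candidate sequences: no Gln, no Pro, so the only
# window satisfying the invariant Gln-Pro pair is the implanted one
_CAND_BG = "".join(sorted(STANDARD_AA - set("QP")))


def gen_candidate_table(
    targets: Tuple[int, int, int],
    seed: int = 0,
    n_nonmotif: int = 0,
    seq_length: int = 40,
):
    """Engineer candidates so the cascade hits exact per-stage counts.

    ``targets = (motif_positive, physiology_pass, disorder_pass)`` must be
    non-increasing. Of the ``motif_positive`` candidates with an implanted
    submotif, the first ``physiology_pass`` receive a physiology flag, and
    of those the first ``disorder_pass`` receive an all-disordered track
    (the rest get ordered, non-coil tracks). ``n_nonmotif`` background-only
    candidates can be added to exercise the motif stage.

    Returns ``(candidates, tracks, expected)`` where expected carries the
    stage counts the cascade must reproduce.
    """
    s1, s2, s3 = targets
    if not (s1 >= s2 >= s3 >= 0):
        raise ValueError("cascade targets must be non-increasing and non-negative")
    rng = _rng(seed, "candidates")
    bg = np.array(list(_CAND_BG))
    candidates: List[Candidate] = []
    tracks: Dict[str, DisorderTrack] = {}

    def background(n):
        return "".join(rng.choice(bg, size=n))

    for k in range(s1 + n_nonmotif):
        pid = f"cand_{k:03d}"
        seq = list(background(seq_length))
        if k < s1:
            sub = int(rng.integers(0, 3))
            d = _SUBMOTIFS[sub]
            window = "".join(
                rng.choice(sorted(cls.allowed - set("QP")) or sorted(cls.allowed))
                if cls.label == "X"
                else rng.choice(sorted(cls.allowed))
                for cls in d.core
            )
            pos = int(rng.integers(1, seq_length - 6))
            seq[pos : pos + 6] = list(window)
            if d.upstream_context is not None:
                seq[pos - 1] = "Q"
        sequence = "".join(seq)
        ann = CandidateAnnotation(
            protein_id=pid,
            golgi_or_pm_localized=k < s2,
        )
        candidates.append(
            Candidate(
                record=ProteinRecord(id=pid, sequence=sequence),
                annotation=ann,
                provenance="sequence",
            )
        )
        disordered = k < s3
        n = len(sequence)
        tracks[pid] = DisorderTrack(
            protein_id=pid,
            source="external:engineered",
            scores=np.full(n, -1.0 if disordered else 1.0),
            calls=np.full(n, disordered),
            coil_calls=np.full(n, disordered),
        )
    expected = {
        "motif_positive": s1,
        "physiology_pass": s2,
        "disorder_pass": s3,
        "final_set_size": s3,
    }
    return candidates, tracks, expected
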
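"""Staged prioritization of candidate AR-binding proteins.

The cascade mirrors the published candidate-identification procedure:

1. **Motif stage** — keep candidates whose sequence (or printed motif-region
   segment) contains at least one submotif hit.
2. **Physiology stage** — keep those with evidence of binding under
   physiological conditions: Golgi/plasma-membrane localization, S-acylation,
   interaction with zDHHC13, or homology to a protein with these features
   (an OR over the four flags).
3. **Disorder stage** — keep those whose motif passes the intrinsic-disorder
   filter (:func:`armotif.disorder.motif_disordered`).

The final set is the union of stage-3 survivors and candidates flagged as
experimentally tested in the originating study (those enter by experiment,
not by the cascade). Footnote-style flag counts are reported over the final
set only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .disorder import DisorderTrack, builtin_disorder, motif_disordered
from .motifs import MotifDefinition, build_submotifs
from .scan import ProteinRecord, scan

logger = logging.getLogger(__name__)

FLAG_COLUMNS = (
    "s_acylated",
    "dhhc17_substrate",
    "dhhc13_interactor",
    "golgi_or_pm_localized",
    "homolog_of_qualified",
    "motif_conserved_hfz",
    "tested_in_this_study",
)

#: Flags any one of which satisfies the physiology stage.
PHYSIOLOGY_FLAGS = (
    "golgi_or_pm_localized",
    "s_acylated",
    "dhhc13_interactor",
    "homolog_of_qualified",
)


@dataclass
class CandidateAnnotation:
    """Per-protein evidence flags (Table-1 footnote style)."""

    protein_id: str
    s_acylated: bool = False
    dhhc17_substrate: bool = False
    dhhc13_interactor: bool = False
    golgi_or_pm_localized: bool = False
    homolog_of_qualified: bool = False
    motif_conserved_hfz: bool = False
    tested_in_this_study: bool = False
    motif_region: Optional[str] = None
    disordered_given: Optional[bool] = None  # passthrough disorder call


@dataclass
class Candidate:
    """A candidate protein: a record (full sequence or printed segment) + flags."""

    record: ProteinRecord
    annotation: CandidateAnnotation
    provenance: str = "sequence"  # "sequence" | "region"

    def __post_init__(self):
        if self.provenance not in ("sequence", "region"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class PrioritizationReport:
    rows: pd.DataFrame
    stage_counts: Dict[str, int]
    flag_counts: Dict[str, int]
    final_ids: Tuple[str, ...]
    excluded: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def final_set_size(self) -> int:
        return len(self.final_ids)

    def summary(self) -> str:
        lines = [
            "prioritization cascade summary",
            f"  candidates            : {len(self.rows)}",
            f"  motif-positive        : {self.stage_counts['motif_positive']}",
            f"  physiology pass       : {self.stage_counts['physiology_pass']}",
            f"  disorder pass         : {self.stage_counts['disorder_pass']}",
            f"  final set (with tested): {self.final_set_size}",
            "  flag counts over the final set:",
        ]
        for key, value in self.flag_counts.items():
            lines.append(f"    {key:<22}: {value}")
        if self.excluded:
            lines.append("  excluded:")
            for pid, reason in self.excluded:
                lines.append(f"    {pid}: {reason}")
        return "\n".join(lines)


def _disorder_for(
    candidate: Candidate,
    hits,
    tracks: Optional[dict],
    rule: str,
    window: int,
) -> bool:
    """Disorder verdict for a candidate: any hit passing the motif filter."""
    ann = candidate.annotation
    pid = candidate.record.id
    entry = (tracks or {}).get(pid)
    if entry is not None:
        if isinstance(entry, DisorderTrack):
            primary, secondary = entry, None
        else:
            primary, secondary = entry
        return any(motif_disordered(h, primary, secondary, rule=rule) for h in hits)
    if ann.disordered_given is not None:
        return ann.disordered_given
    track = builtin_disorder(candidate.record, window=window)
    return any(motif_disordered(h, track, rule=rule) for h in hits)


def run_cascade(
    candidates: Sequence[Candidate],
    definitions: Optional[Sequence[MotifDefinition]] = None,
    tracks: Optional[dict] = None,
    disorder_rule: str = "all",
    disorder_window: int = 21,
) -> PrioritizationReport:
    """Run the three-stage cascade and build a Table-1-style report.

    *definitions* defaults to the three submotifs. *tracks* maps protein id
    to a DisorderTrack or a (primary, secondary) pair; candidates without a
    track fall back to their annotation's given disorder call, then to the
    built-in predictor on their own sequence/segment. Rows are sorted by
    protein id; identical inputs produce byte-identical reports.
    """
    if definitions is None:
        definitions = build_submotifs()
    for cand in candidates:
        if cand.record.sequence == "":
            raise ValueError(f"candidate {cand.record.id} has no sequence or region")
    ordered = sorted(candidates, key=lambda c: c.record.id)
    rows = []
    excluded: List[Tuple[str, str]] = []
    final_ids: List[str] = []
    n_stage1 = n_stage2 = n_stage3 = 0
    for cand in ordered:
        ann = cand.annotation
        pid = cand.record.id
        hits = scan(cand.record, definitions)
        sub_hits = [h for h in hits if h.submotif_labels]
        stage1 = bool(sub_hits)
        stage2 = stage1 and any(getattr(ann, f) for f in PHYSIOLOGY_FLAGS)
        stage3 = stage2 and _disorder_for(
            cand, sub_hits, tracks, disorder_rule, disorder_window
        )
        n_stage1 += stage1
        n_stage2 += stage2
        n_stage3 += stage3
        in_final = stage3 or ann.tested_in_this_study
        if in_final:
            final_ids.append(pid)
        else:
            if not stage1:
                reason = "no submotif hit"
            elif not stage2:
                reason = "no physiological-binding evidence"
            else:
                reason = "motif not in a disordered region"
            excluded.append((pid, reason))
        labels = sorted({l for h in sub_hits for l in h.submotif_labels})
        row = {
            "protein_id": pid,
            "provenance": cand.provenance,
            "n_hits": len(sub_hits),
            "submotifs": ";".join(labels),
            "motif_positive": stage1,
            "physiology_pass": stage2,
            "disorder_pass": stage3,
            "in_final_set": in_final,
        }
        for f in FLAG_COLUMNS:
            row[f] = getattr(ann, f)
        rows.append(row)
    frame = pd.DataFrame(rows)
    final = frozenset(final_ids)
    if len(frame):
        final_rows = frame[frame["protein_id"].isin(final)]
    else:
        final_rows = frame
    flag_counts = {
        "s_acylated": 0,
        "dhhc17_substrate": 0,
        "dhhc13_interactor": 0,
        "motif_conserved_hfz": 0,
        "tested_in_this_study": 0,
        "not_tested_in_this_study": 0,
    }
    if len(final_rows):
        for key in (
            "s_acylated",
            "dhhc17_substrate",
            "dhhc13_interactor",
            "motif_conserved_hfz",
            "tested_in_this_study",
        ):
            flag_counts[key] = int(final_rows[key].sum())
        flag_counts["not_tested_in_this_study"] = int(
            (~final_rows["tested_in_this_study"]).sum()
        )
    return PrioritizationReport(
        rows=frame,
        stage_counts={
            "motif_positive": n_stage1,
            "physiology_pass": n_stage2,
            "disorder_pass": n_stage3,
        },
        flag_counts=flag_counts,
        final_ids=tuple(sorted(final_ids)),
        excluded=excluded,
    )


# --- candidate-table IO -----------------------------------------------------

def read_candidate_table(path) -> List[Candidate]:
    """Read a candidate TSV: id, sequence_or_region columns plus flags.

    Recognized columns: ``protein_id``, ``sequence_or_region``, optional
    ``provenance`` (sequence|region), optional ``numbering_offset``, the
    seven flag columns, and an optional ``disordered`` passthrough call.
    Absent flag columns default to False with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("protein_id", "sequence_or_region"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in FLAG_COLUMNS:
        if col not in df.columns:
            logger.warning("%s: flag column %r absent; defaulting to False", path, col)
            df[col] = "0"
        df[col] = df[col].fillna("0")
    candidates = []
    for _, row in df.iterrows():
        seq = str(row["sequence_or_region"]).strip()
        if not seq or seq.lower() == "nan":
            raise ValueError(
                f"{path}: candidate {row['protein_id']!r} has neither a "
                "sequence nor a motif region"
            )
        provenance = str(row.get("provenance", "sequence") or "sequence")
        offset = int(row.get("numbering_offset") or 1)
        flags = {f: _as_bool(row[f]) for f in FLAG_COLUMNS}
        given = None
        if "disordered" in df.columns and str(row["disordered"]).lower() != "nan":
            given = _as_bool(row["disordered"])
        ann = CandidateAnnotation(
            protein_id=str(row["protein_id"]),
            motif_region=seq if provenance == "region" else None,
            disordered_given=given,
            **flags,
        )
        candidates.append(
            Candidate(
                record=ProteinRecord(
                    id=str(row["protein_id"]), sequence=seq, numbering_offset=offset
                ),
                annotation=ann,
                provenance=provenance,
            )
        )
    return candidates


def _as_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no", ""}:
        return False
    raise ValueError(f"unparseable flag value {value!r}")


def write_report(report: PrioritizationReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("# armotif prioritization report v1\n")
        fh.write(
            "# columns: protein_id provenance n_hits submotifs "
            "motif_positive physiology_pass disorder_pass in_final_set + flags\n"
        )
        report.rows.to_csv(fh, sep="\t", index=False)


def load_bundled_candidates() -> List[Candidate]:
    """Load the bundled synthetic reconstruction of the published Table-1 set.

    The published table is available only as an image; this fixture carries
    the six studied proteins with their printed motif signatures and 14
    further candidates with engineered submotif segments, with evidence
    flags assigned to reproduce the published summary counts. It is a
    synthetic stand-in for the curated table, suitable for exercising the
    cascade, not a primary data source.
    """
    ref = resources.files("armotif.data").joinpath("table1_candidates_synthetic.tsv")
    with resources.as_file(ref) as path:
        return read_candidate_table(path)
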
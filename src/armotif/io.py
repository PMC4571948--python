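"""FASTA and TSV input/output plus the flat-text pipeline configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import List, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import STANDARD_AA
from .scan import MotifHit, ProteinRecord

logger = logging.getLogger(__name__)

HIT_COLUMNS = (
    "protein_id",
    "start",
    "end",
    "matched",
    "general",
    "submotifs",
    "context_ok",
    "qualifier",
)


def read_fasta(path, numbering_offset: int = 1) -> List[ProteinRecord]:
    """Read a (possibly wrapped, CRLF-tolerant) multi-record FASTA file.

    Record ids are the first whitespace-delimited token of the header;
    sequences are uppercased. Non-standard residue letters are kept but
    logged. An empty file or a record with an empty sequence is an error.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        nonstandard = sorted(set(seq) - STANDARD_AA)
        if nonstandard:
            logger.warning(
                "%s: record %s contains non-standard letters %s "
                "(they will not match any motif class)",
                path,
                rec.id,
                "".join(nonstandard),
            )
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                description=rec.description,
                numbering_offset=numbering_offset,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def write_hits_tsv(hits: Sequence[MotifHit], path) -> None:
    """Write motif hits as TSV (protein coordinates, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("# armotif hits v1\n")
        fh.write(
            "# columns: protein_id start end matched general "
            "submotifs context_ok qualifier\n"
        )
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.protein_id,
                        str(h.start),
                        str(h.end),
                        h.matched,
                        str(int(h.general)),
                        ";".join(h.submotif_labels),
                        str(int(h.context_ok)),
                        h.qualifier,
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """Effective run configuration (precedence: CLI flags > file > defaults)."""

    motifs: str = "all"            # general | submotifs | all
    relaxed: bool = False
    gap_open: float = 10.0
    gap_extend: float = 0.5
    disorder_window: int = 21
    disorder_rule: str = "all"     # all | majority
    shading_gray_low: float = 0.6
    shading_gray_high: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.motifs not in ("general", "submotifs", "all"):
            raise ValueError(f"invalid motif set {self.motifs!r}")
        if self.disorder_rule not in ("all", "majority"):
            raise ValueError(f"invalid disorder rule {self.disorder_rule!r}")
        if self.disorder_window < 3 or self.disorder_window % 2 == 0:
            raise ValueError("disorder_window must be odd and >= 3")

    def describe(self) -> str:
        pairs = [(f.name, getattr(self, f.name)) for f in fields(self)]
        return " ".join(f"{k}={v}" for k, v in pairs)


def load_config(path) -> PipelineConfig:
    """Load a flat ``key = value`` config file (``#`` comments allowed)."""
    text = Path(path).read_text()
    values = {}
    casts = {f.name: f.type for f in fields(PipelineConfig)}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in casts:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = value
    cfg = PipelineConfig()
    typed = {}
    for key, value in values.items():
        current = getattr(cfg, key)
        if isinstance(current, bool):
            typed[key] = value.strip().lower() in {"1", "true", "yes"}
        elif isinstance(current, int):
            typed[key] = int(value)
        elif isinstance(current, float):
            typed[key] = float(value)
        else:
            typed[key] = value
    return replace(cfg, **typed)
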
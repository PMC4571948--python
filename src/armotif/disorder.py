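"""Per-residue intrinsic-disorder calls and the motif-level disorder filter.

The AR-binding motif is required to lie in an intrinsically disordered
region. Two sources of per-residue calls are supported:

* a built-in windowed hydropathy/charge score of the FoldIndex family
  (a desk-scale stand-in, not a re-implementation of any external
  predictor): over a clamped window of width ``w`` centred on each residue,
  with H the mean Kyte–Doolittle hydropathy rescaled to [0,1] via
  ``(kd + 4.5)/9`` and R the absolute mean net charge (K,R = +1, D,E = −1),
  the score is ``I = 2.785*H − R − 1.151`` and a residue is called
  disordered iff ``I < 0``;
* external predictor tracks read from TSV (position, residue, score, call,
  optional coil column), cross-checked residue-by-residue against the
  record.

The motif-level filter applies a two-predictor rescue: a hit passes if all
six residues are disordered in the primary track, OR all six are coil
(secondary-structure-free) in the primary track and all six are disordered
in the secondary track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .scan import MotifHit, ProteinRecord

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


@dataclass
class DisorderTrack:
    """Per-residue disorder scores/calls aligned to one protein record."""

    protein_id: str
    source: str  # "builtin" or "external:<name>"
    scores: np.ndarray
    calls: np.ndarray
    coil_calls: Optional[np.ndarray] = None
    numbering_offset: int = 1

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.scores.shape != self.calls.shape:
            raise ValueError("scores and calls must have equal length")
        if self.coil_calls is not None:
            self.coil_calls = np.asarray(self.coil_calls, dtype=bool)
            if self.coil_calls.shape != self.calls.shape:
                raise ValueError("coil_calls must match calls in length")

    def __len__(self) -> int:
        return len(self.calls)

    def slice_for(self, hit: MotifHit) -> slice:
        start = hit.start - self.numbering_offset
        stop = start + 6
        if start < 0 or stop > len(self):
            raise ValueError(
                f"track for {self.protein_id} does not cover hit "
                f"{hit.start}-{hit.end}"
            )
        return slice(start, stop)


def builtin_disorder(record: ProteinRecord, window: int = 21) -> DisorderTrack:
    """Windowed hydropathy/charge disorder stand-in (see module docstring).

    ``window`` must be odd and at least 3; it is clamped at the termini, so
    terminal residues average over fewer neighbours. Non-standard residue
    letters contribute zero charge and the hydropathy-scale midpoint.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    seq = record.sequence
    n = len(seq)
    kd = np.array([KYTE_DOOLITTLE.get(r, 0.0) for r in seq])
    ch = np.array([_CHARGE.get(r, 0.0) for r in seq])
    half = window // 2
    # clamped-window means via cumulative sums
    ckd = np.concatenate([[0.0], np.cumsum(kd)])
    cch = np.concatenate([[0.0], np.cumsum(ch)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    width = (hi - lo).astype(float)
    mean_kd = (ckd[hi] - ckd[lo]) / width
    mean_ch = (cch[hi] - cch[lo]) / width
    hydropathy = (mean_kd + 4.5) / 9.0
    scores = 2.785 * hydropathy - np.abs(mean_ch) - 1.151
    calls = scores < 0
    return DisorderTrack(
        protein_id=record.id,
        source="builtin",
        scores=scores,
        calls=calls,
        coil_calls=calls.copy(),  # no secondary-structure model: coil == disordered
        numbering_offset=record.numbering_offset,
    )


_TRUTHY = {"1", "true", "t", "yes", "d"}
_FALSY = {"0", "false", "f", "no", "o"}


def _parse_call(value, path, position) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"{path}: unparseable call {value!r} at position {position}")


def read_track(path, record: ProteinRecord, name: str = "external") -> DisorderTrack:
    """Read an external disorder track TSV and validate it against *record*.

    Expected columns: ``position``, ``residue``, ``score``, ``call`` and an
    optional ``coil``. The track must cover the record exactly; any residue
    mismatch is reported with its position.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"position", "residue", "score", "call"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) != len(record.sequence):
        raise ValueError(
            f"{path}: {len(df)} rows but {record.id} has "
            f"{len(record.sequence)} residues"
        )
    positions = df["position"].astype(int).to_numpy()
    expected = np.arange(
        record.numbering_offset, record.numbering_offset + len(record.sequence)
    )
    if not np.array_equal(positions, expected):
        raise ValueError(f"{path}: positions must run {expected[0]}..{expected[-1]}")
    for pos, res, actual in zip(positions, df["residue"], record.sequence):
        if str(res).upper() != actual:
            raise ValueError(
                f"{path}: residue mismatch at position {pos}: "
                f"track has {res!r}, sequence has {actual!r}"
            )
    calls = np.array(
        [_parse_call(v, path, p) for v, p in zip(df["call"], positions)]
    )
    coil = None
    if "coil" in df.columns:
        coil = np.array(
            [_parse_call(v, path, p) for v, p in zip(df["coil"], positions)]
        )
    return DisorderTrack(
        protein_id=record.id,
        source=f"external:{name}",
        scores=df["score"].astype(float).to_numpy(),
        calls=calls,
        coil_calls=coil,
        numbering_offset=record.numbering_offset,
    )


def track_to_frame(track: DisorderTrack, record: ProteinRecord) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "position": np.arange(
                track.numbering_offset, track.numbering_offset + len(track)
            ),
            "residue": list(record.sequence),
            "score": np.round(track.scores, 6),
            "call": track.calls.astype(int),
        }
    )
    if track.coil_calls is not None:
        frame["coil"] = track.coil_calls.astype(int)
    return frame


def motif_disordered(
    hit: MotifHit,
    primary: DisorderTrack,
    secondary: Optional[DisorderTrack] = None,
    rule: str = "all",
) -> bool:
    """Motif-level disorder filter with two-predictor rescue.

    True iff the hit residues are called disordered in the primary track,
    or they are all coil in the primary track and called disordered in the
    secondary track. ``rule`` selects how many of the six residues must be
    disordered: ``"all"`` (default, strictest reading) or ``"majority"``
    (at least 4 of 6); the coil condition for rescue always requires all six.
    """
    if rule == "all":
        need = 6
    elif rule == "majority":
        need = 4
    else:
        raise ValueError(f"unknown disorder rule {rule!r}")
    sl = primary.slice_for(hit)
    if int(primary.calls[sl].sum()) >= need:
        return True
    coil = primary.coil_calls
    if coil is not None and bool(coil[sl].all()) and secondary is not None:
        sl2 = secondary.slice_for(hit)
        if int(secondary.calls[sl2].sum()) >= need:
            return True
    return False


def write_track(track: DisorderTrack, record: ProteinRecord, path) -> None:
    """Write a track in the TSV schema accepted by :func:`read_track`."""
    frame = track_to_frame(track, record)
    with open(path, "w") as fh:
        fh.write(f"# armotif disorder track v1\tsource={track.source}\n")
        fh.write("# columns: position residue score call[ coil]\n")
        frame.to_csv(fh, sep="\t", index=False)
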
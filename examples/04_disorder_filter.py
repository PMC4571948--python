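"""Apply the intrinsic-disorder filter to motif hits.

The AR-binding motif must lie in a disordered region. The built-in windowed
hydropathy/charge score provides desk-scale per-residue calls; the filter
also supports the two-predictor rescue: a motif that is merely coil (no
secondary structure) in the primary track passes if a secondary track calls
it disordered.
"""

from armotif import (
    ProteinRecord,
    builtin_disorder,
    bundled_definitions,
    motif_disordered,
    scan,
)

# a charged, low-hydropathy context keeps the motif region disordered
record = ProteinRecord(
    id="disordered_ctx",
    sequence="KEKEDKSEEKKSEE" + "VVASQP" + "KEDKSEEKKSEEDK",
)
track = builtin_disorder(record, window=21)
for hit in scan(record, bundled_definitions("general")):
    verdict = motif_disordered(hit, track)
    print(
        f"{record.id}: {hit.matched} at {hit.start}-{hit.end} "
        f"disordered={verdict} "
        f"(residue scores {track.scores[hit.start - 1 : hit.end].round(2)})"
    )

# Negative scores mean disordered; embedded in a charged disordered context
# the motif passes the filter.
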
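"""Scan the SNAP25b decapeptide for the AR-binding consensus.

The ten-residue peptide GVVASQPARV spans residues 111-120 of SNAP25b and is
sufficient for recognition by the ankyrin-repeat domains of zDHHC17/13.
Scanning it with the general [VIAP][VIT]XXQP consensus locates the motif at
its native coordinates.
"""

from armotif import ProteinRecord, bundled_definitions, scan

peptide = ProteinRecord(
    id="SNAP25b_111_120", sequence="GVVASQPARV", numbering_offset=111
)
for hit in scan(peptide, bundled_definitions("all")):
    print(
        f"{hit.protein_id}: {hit.matched} at {hit.start}-{hit.end} "
        f"(invariant Gln at {hit.q_position}, Pro at {hit.p_position}); "
        f"submotifs: {', '.join(hit.submotif_labels) or 'none'}"
    )

# Expected output: one hit, VVASQP at 112-117, Gln116 / Pro117 — the
# residues whose truncation or substitution abolishes zDHHC17/13 binding.
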
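"""In-silico alanine scan of the SNAP25b and HTT motif regions.

A point substitution is applied and the sequence rescanned: the motif is
"retained" when a full hit still covers the original span, "partial" when
only a relaxed terminal Val/Ile hit remains, "lost" otherwise. Positions
outside the class-constrained consensus (the two X positions and flanking
residues) leave the motif intact by construction.
"""

from armotif import (
    ProteinRecord,
    bundled_definitions,
    parse_mutation,
    predict_mutation_effect,
)

defs = bundled_definitions("general")

snap25 = ProteinRecord(id="SNAP25b", sequence="GVVASQPARV", numbering_offset=111)
print("SNAP25b alanine panel:")
for label in ("V112A", "V113A", "Q116A", "P117A"):
    effect = predict_mutation_effect(snap25, parse_mutation(label), defs)
    print(f"  {label}: {effect.classification}")

htt = ProteinRecord(id="HTT", sequence="IITEQPRAS", numbering_offset=494)
print("HTT 494-502 alanine panel:")
for label in ("I495A", "T496A", "Q498A", "P499A", "R500A"):
    effect = predict_mutation_effect(htt, parse_mutation(label), defs)
    print(f"  {label}: {effect.classification}")

print("Terminal-Pro substitutions (relaxed mode):")
for label in ("P117V", "P117I", "P117G", "P117S", "P117T"):
    effect = predict_mutation_effect(snap25, parse_mutation(label), defs, relaxed=True)
    print(f"  {label}: {effect.classification}")

# V112A is retained because Ala is itself an allowed aliphatic residue;
# V113A/Q116A/P117A and I495A/Q498A/P499A break their position class.
# Val/Ile at the terminal Pro are graded "partial" — they only partially
# preserve binding — while Gly/Ser/Thr are "lost".
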
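"""Build a neighbor-joining tree of two diverged protein families.

Distances are 1 - fractional identity from pairwise global alignments;
the Saitou-Nei algorithm then agglomerates. Two families derived from
different ancestors separate into disjoint subtrees — the desk-scale
analogue of the split between the vertebrate zDHHC17 and zDHHC13 groups.
Reproducing the published tree itself requires downloading the UniProt
sequences named in its figure; point `nj_from_records` at that FASTA to
do so.
"""

import numpy as np

from armotif import ProteinRecord, nj_from_records

rng = np.random.default_rng(11)
aa = list("ACDEFGHIKLMNPQRSTVWY")
base17 = "".join(rng.choice(aa, size=120))
base13 = "".join(rng.choice(aa, size=120))


def diverge(seq, n):
    s = list(seq)
    for i in rng.choice(len(s), size=n, replace=False):
        s[i] = str(rng.choice([a for a in aa if a != s[i]]))
    return "".join(s)


records = [
    ProteinRecord(id=f"zdhhc17_{sp}", sequence=diverge(base17, 8))
    for sp in ("human", "mouse", "frog", "fish")
] + [
    ProteinRecord(id=f"zdhhc13_{sp}", sequence=diverge(base13, 8))
    for sp in ("human", "mouse", "frog", "fish")
]

tree = nj_from_records(records)
print(tree.newick())
print(f"total tree length: {tree.total_length():.3f}")

# In the Newick string the four zdhhc17_* leaves group together, as do the
# four zdhhc13_* leaves: within-family identity distances are far smaller
# than between-family ones.
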
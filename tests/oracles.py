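"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the scanner oracle
uses hardcoded regular expressions, the alignment oracle enumerates every
gapped alignment, and the disorder oracle recomputes windowed means
directly from the formula.
"""

import re

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

# Overlap-tolerant regexes for the published consensus and submotifs,
# written directly from their bracket spellings.
RX_GENERAL = re.compile(r"(?=([VIAP][VIT][A-Z]{2}QP))")
RX_SUB1 = re.compile(r"(?=([VIA][VI][A-Z]{2}QP))")
RX_SUB2 = re.compile(r"(?=(P[VI][VIL][A-Z]QP))")
RX_SUB3 = re.compile(r"(?<=Q)(?=([VI]T[A-Z]{2}QP))")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _starts(rx, seq):
    # restrict [A-Z] wildcards to the 20 standard letters
    return {
        m.start()
        for m in rx.finditer(seq)
        if all(c in AA20 for c in m.group(1))
    }


def regex_scan(seq):
    """0-based start sets for (general, sub1, sub2, sub3)."""
    seq = seq.upper()
    return {
        "general": _starts(RX_GENERAL, seq),
        "sub1": _starts(RX_SUB1, seq),
        "sub2": _starts(RX_SUB2, seq),
        "sub3": _starts(RX_SUB3, seq),
    }


def brute_force_global_score(a, b, gap_open=10.0, gap_extend=0.5):
    """Best global alignment score by exhaustive path enumeration.

    Gap convention: a maximal gap of length L costs open + (L-1)*extend;
    terminal gaps are penalized like internal ones.
    """
    best = [-np.inf]
    la, lb = len(a), len(b)

    def rec(i, j, last, score):
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, "M", score + float(_B62[a[i], b[j]]))
        if i < la:
            rec(i + 1, j, "A", score - (gap_extend if last == "A" else gap_open))
        if j < lb:
            rec(i, j + 1, "B", score - (gap_extend if last == "B" else gap_open))

    rec(0, 0, None, 0.0)
    return best[0]


KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


def direct_disorder_scores(seq, window):
    """Naive per-residue recomputation of the windowed disorder score."""
    half = window // 2
    out = []
    for i in range(len(seq)):
        chunk = seq[max(i - half, 0) : min(i + half + 1, len(seq))]
        h = np.mean([(KD.get(c, 0.0) + 4.5) / 9.0 for c in chunk])
        r = abs(np.mean([CHARGE.get(c, 0.0) for c in chunk]))
        out.append(2.785 * h - r - 1.151)
    return np.array(out)


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths.

    Returns (newick, taxa, distance_matrix) where the matrix holds exact
    leaf-to-leaf path lengths (an additive matrix).
    """
    taxa = [f"t{i}" for i in range(n_taxa)]
    # each active node: (newick fragment, {leaf: distance to this node})
    active = [(t, {t: 0.0}) for t in taxa]
    dist = {}
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (nwk_i, di) = active[i]
        (nwk_j, dj) = active[j]
        li = float(rng.uniform(0.1, 1.0))
        lj = float(rng.uniform(0.1, 1.0))
        for a, da in di.items():
            for b, db in dj.items():
                dist[frozenset((a, b))] = da + li + db + lj
        merged = {a: da + li for a, da in di.items()}
        merged.update({b: db + lj for b, db in dj.items()})
        node = (f"({nwk_i}:{li:.6f},{nwk_j}:{lj:.6f})", merged)
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [node]
    (nwk_i, di), (nwk_j, dj) = active
    lj = float(rng.uniform(0.1, 1.0))
    for a, da in di.items():
        for b, db in dj.items():
            dist[frozenset((a, b))] = da + db + lj
    newick = f"({nwk_i}:0.0,{nwk_j}:{lj:.6f});"
    d = np.zeros((n_taxa, n_taxa))
    for ii in range(n_taxa):
        for jj in range(ii + 1, n_taxa):
            d[ii, jj] = d[jj, ii] = dist[frozenset((taxa[ii], taxa[jj]))]
    return newick, taxa, d
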
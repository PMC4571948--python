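"""Global alignment, motif-position mapping and conservation calls."""

import numpy as np
import pytest

from armotif import (
    OrthologSet,
    ProteinRecord,
    motif_conserved,
    nw_align,
    scan,
    shading_categories,
)
from armotif.align import BLOSUM62, pair_similar
from armotif.motifs import build_general_consensus
from oracles import brute_force_global_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestNwAlign:
    def test_identity_alignment(self):
        s = "GVVASQPARV"
        res = nw_align(s, s)
        assert res.aligned_a == s and res.aligned_b == s
        assert res.score == sum(float(BLOSUM62[c, c]) for c in s)

    def test_qp_pair_score(self):
        assert nw_align("QP", "QP").score == 12.0  # Q/Q=5, P/P=7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nw_align("", "QP")

    def test_score_is_symmetric(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(3, 30))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(3, 30))))
            assert nw_align(a, b).score == pytest.approx(nw_align(b, a).score)

    def test_degapped_rows_equal_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(3, 25))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(3, 25))))
            res = nw_align(a, b)
            assert res.aligned_a.replace("-", "") == a
            assert res.aligned_b.replace("-", "") == b

    def test_score_equals_exhaustive_enumeration(self):
        """DP score equals the best score over all explicit alignments."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(1, 7))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(1, 7))))
            assert nw_align(a, b).score == pytest.approx(
                brute_force_global_score(a, b)
            )

    def test_mapping_identity_for_gapfree_alignments(self):
        a = "VVASQPARV"
        res = nw_align(a, a)
        for i in range(len(a)):
            assert res.column_map[i] == i
            assert res.map_to_b(i) == a[i]


def _triple(ref_seq, frog_seq, fish_seq, offset=1):
    ref = ProteinRecord(id="ref", sequence=ref_seq, numbering_offset=offset)
    return OrthologSet(
        reference=ref,
        orthologs={
            "frog": ProteinRecord(id="frog", sequence=frog_seq),
            "zebrafish": ProteinRecord(id="fish", sequence=fish_seq),
        },
    )


class TestConservation:
    BASE = "MSTDDAKAGVVASQPARVLDTKEEIRGNASWQERLMTS"

    def _hit(self, oset):
        return scan(oset.reference, [build_general_consensus()])[0]

    def test_identical_sequences_absolutely_conserved(self):
        oset = _triple(self.BASE, self.BASE, self.BASE)
        call = motif_conserved(oset, self._hit(oset))
        assert call.motif_conserved
        assert set(call.per_position) == {"absolute"}

    def test_ablated_ortholog_not_conserved(self):
        broken = self.BASE.replace("VVASQP", "LLLLLL")
        oset = _triple(self.BASE, self.BASE, broken)
        call = motif_conserved(oset, self._hit(oset))
        assert not call.motif_conserved

    def test_class_level_exchange_still_conserved(self):
        # V->I at the beta position stays inside its class: conserved,
        # with an "equivalent" per-position category
        swapped = self.BASE.replace("VVASQP", "VIASQP")
        oset = _triple(self.BASE, swapped, self.BASE)
        call = motif_conserved(oset, self._hit(oset))
        assert call.motif_conserved
        assert call.per_position[1] == "equivalent"
        assert call.per_position[0] == "absolute"

    def test_gap_in_mapped_segment_is_negative_call(self):
        # ortholog lacking the motif region entirely -> gapped mapping
        deleted = self.BASE.replace("VVASQP", "")
        oset = _triple(self.BASE, self.BASE, deleted)
        call = motif_conserved(oset, self._hit(oset))
        assert not call.motif_conserved

    def test_adding_an_ortholog_never_rescues(self):
        """Monotonicity: a failing set cannot become conserved by adding taxa."""
        broken = self.BASE.replace("VVASQP", "LLLLLL")
        small = OrthologSet(
            reference=ProteinRecord(id="ref", sequence=self.BASE),
            orthologs={"frog": ProteinRecord(id="frog", sequence=broken)},
        )
        hit = self._hit(small)
        assert not motif_conserved(small, hit).motif_conserved
        bigger = OrthologSet(
            reference=small.reference,
            orthologs={**small.orthologs,
                       "fish": ProteinRecord(id="fish", sequence=self.BASE)},
        )
        assert not motif_conserved(bigger, hit).motif_conserved

    def test_requires_at_least_one_ortholog(self):
        with pytest.raises(ValueError):
            OrthologSet(reference=ProteinRecord(id="r", sequence=self.BASE),
                        orthologs={})


class TestShading:
    def test_all_identical_column_is_black(self):
        assert shading_categories(["Q", "Q", "Q"]) == ["black"]

    def test_one_gap_two_identical_is_none(self):
        # 1 similar pair of 3 -> fraction 1/3
        assert shading_categories(["Q", "Q", "-"]) == ["none"]

    def test_two_of_three_pairs_is_gray(self):
        # S/T and S/A score positive, T/A does not: fraction 2/3
        assert shading_categories(["S", "T", "A"]) == ["gray"]

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            shading_categories(["QP"])

    def test_matches_direct_pair_recount(self):
        rng = np.random.default_rng(11)
        letters = list(AA) + ["-"]
        seqs = ["".join(rng.choice(letters, size=40)) for _ in range(3)]
        cats = shading_categories(seqs)
        for col, cat in enumerate(cats):
            column = [s[col] for s in seqs]
            pairs = [
                (column[i], column[j])
                for i in range(3)
                for j in range(i + 1, 3)
            ]
            frac = sum(pair_similar(x, y) for x, y in pairs) / len(pairs)
            if frac == 1.0:
                assert cat == "black"
            elif 0.6 <= frac <= 0.8:
                assert cat == "gray"
            else:
                assert cat == "none"
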
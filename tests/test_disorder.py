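"""Built-in disorder stand-in, external tracks, and the motif-level filter."""

import numpy as np
import pytest

from armotif import (
    DisorderTrack,
    ProteinRecord,
    builtin_disorder,
    motif_disordered,
    read_track,
    scan,
    write_track,
)
from armotif.motifs import build_general_consensus
from oracles import direct_disorder_scores

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestBuiltin:
    def test_poly_lysine_is_disordered(self):
        track = builtin_disorder(ProteinRecord(id="k", sequence="K" * 60))
        assert track.calls.all()
        # the plateau value follows from the formula: 2.785*(0.6/9) - 1 - 1.151
        assert track.scores[30] == pytest.approx(2.785 * ((-3.9 + 4.5) / 9) - 1 - 1.151)

    def test_poly_isoleucine_is_ordered(self):
        track = builtin_disorder(ProteinRecord(id="i", sequence="I" * 60))
        assert not track.calls.any()
        assert track.scores[30] == pytest.approx(2.785 * 1.0 - 1.151)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            builtin_disorder(ProteinRecord(id="x", sequence="A" * 10), window=10)

    def test_scores_equal_direct_recomputation(self):
        rng = np.random.default_rng(5)
        for window in (5, 21):
            seq = "".join(rng.choice(list(AA), size=120))
            track = builtin_disorder(ProteinRecord(id="r", sequence=seq), window)
            np.testing.assert_allclose(
                track.scores, direct_disorder_scores(seq, window), atol=1e-12
            )

    def test_translation_invariance_outside_first_window(self):
        """Prepending k residues shifts calls by k beyond the window edge."""
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list(AA), size=100))
        prefix = "".join(rng.choice(list(AA), size=15))
        w = 21
        base = builtin_disorder(ProteinRecord(id="a", sequence=seq), w)
        shifted = builtin_disorder(ProteinRecord(id="b", sequence=prefix + seq), w)
        # positions whose window no longer touches either modified terminus
        np.testing.assert_array_equal(
            base.calls[w : len(seq) - w], shifted.calls[15 + w : 15 + len(seq) - w]
        )


class TestExternalTracks:
    def _record(self):
        return ProteinRecord(id="p1", sequence="GVVASQPARV", numbering_offset=111)

    def _write(self, tmp_path, rows, header="position\tresidue\tscore\tcall"):
        path = tmp_path / "track.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_well_formed_round_trip(self, tmp_path):
        record = self._record()
        track = builtin_disorder(record, window=5)
        path = tmp_path / "t.tsv"
        write_track(track, record, path)
        back = read_track(path, record, name="t")
        np.testing.assert_array_equal(back.calls, track.calls)
        np.testing.assert_allclose(back.scores, track.scores, atol=1e-6)
        np.testing.assert_array_equal(back.coil_calls, track.coil_calls)

    def test_short_file_rejected(self, tmp_path):
        record = self._record()
        rows = [f"{111 + i}\t{r}\t0.0\t1" for i, r in enumerate(record.sequence[:-1])]
        with pytest.raises(ValueError, match="rows"):
            read_track(self._write(tmp_path, rows), record)

    def test_residue_mismatch_names_the_position(self, tmp_path):
        record = self._record()
        residues = list(record.sequence)
        residues[3] = "W"  # sequence has A at 114
        rows = [f"{111 + i}\t{r}\t0.0\t1" for i, r in enumerate(residues)]
        with pytest.raises(ValueError, match="position 114"):
            read_track(self._write(tmp_path, rows), record)


def _hit(sequence="GVVASQPARV", offset=111):
    record = ProteinRecord(id="p", sequence=sequence, numbering_offset=offset)
    return scan(record, [build_general_consensus()])[0]


def _track(calls, coil=None, offset=111):
    calls = np.array(calls, dtype=bool)
    return DisorderTrack(
        protein_id="p",
        source="external:test",
        scores=np.where(calls, -1.0, 1.0),
        calls=calls,
        coil_calls=None if coil is None else np.array(coil, dtype=bool),
        numbering_offset=offset,
    )


class TestMotifFilter:
    def test_fully_disordered_primary_passes(self):
        assert motif_disordered(_hit(), _track([True] * 10))

    def test_coil_but_ordered_rescued_by_secondary(self):
        primary = _track([False] * 10, coil=[True] * 10)
        secondary = _track([True] * 10)
        assert motif_disordered(_hit(), primary, secondary)

    def test_ordered_non_coil_fails_regardless_of_secondary(self):
        primary = _track([False] * 10, coil=[False] * 10)
        secondary = _track([True] * 10)
        assert not motif_disordered(_hit(), primary, secondary)

    def test_coil_but_no_secondary_fails(self):
        primary = _track([False] * 10, coil=[True] * 10)
        assert not motif_disordered(_hit(), primary)

    def test_one_ordered_motif_residue_fails_strict_rule(self):
        calls = [True] * 10
        calls[4] = False  # inside the 112-117 hit
        assert not motif_disordered(_hit(), _track(calls))
        assert motif_disordered(_hit(), _track(calls), rule="majority")

    def test_monotone_in_primary_calls(self):
        """Flipping any residue ordered->disordered never flips true->false."""
        rng = np.random.default_rng(3)
        hit = _hit()
        for _ in range(50):
            calls = rng.random(10) < 0.5
            base = motif_disordered(hit, _track(calls.tolist()))
            for i in range(10):
                if not calls[i]:
                    flipped = calls.copy()
                    flipped[i] = True
                    after = motif_disordered(hit, _track(flipped.tolist()))
                    assert after or not base

    def test_uncovered_span_is_an_error(self):
        short = DisorderTrack(
            protein_id="p",
            source="external:test",
            scores=np.zeros(3),
            calls=np.ones(3, dtype=bool),
            numbering_offset=111,
        )
        with pytest.raises(ValueError, match="cover"):
            motif_disordered(_hit(), short)
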
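import random

import pytest
from Bio import Align

from ribovar.genemodel import Sequence
from ribovar.pseudogene import (
    alignment_stats,
    blosum62,
    needleman_wunsch_align,
    pseudogene_rescue_report,
    six_frame_translate,
)
from ribovar.synthetic_data import degrade_protein
from oracles import brute_force_alignment_score


class TestSixFrameTranslate:
    def test_forward_frames(self):
        frames = six_frame_translate(Sequence("x", "ATGGCC"))
        assert frames[1] == "MA"
        assert frames[2] == "W"  # TGG
        assert frames[3] == "G"  # GGC

    def test_reverse_complement_frame(self):
        # revcomp of ATGGCC is GGCCAT -> frame -1 reads GGC CAT -> "GH"
        frames = six_frame_translate(Sequence("x", "ATGGCC"))
        assert frames[-1] == "GH"

    def test_length_seven_frame_lengths(self):
        frames = six_frame_translate(Sequence("x", "ATGGCCA"))
        assert [len(frames[f]) for f in (1, 2, 3)] == [2, 2, 1]

    def test_internal_stops_rendered_not_truncated(self):
        frames = six_frame_translate(Sequence("x", "ATGTAAGCC"))
        assert frames[1] == "M*A"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate(Sequence("x", "AT"))


class TestNeedlemanWunsch:
    def test_identical_sequences(self):
        aln = needleman_wunsch_align("MKWVT", "MKWVT")
        assert (aln.identity_pct, aln.similarity_pct, aln.gaps_pct) == (100.0, 100.0, 0.0)

    def test_terminal_gap_free_geometry(self):
        aln = needleman_wunsch_align("AAAA", "AAA")
        assert aln.length == 4 and aln.gaps_pct == 25.0
        assert aln.identity_pct == 75.0

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            needleman_wunsch_align("AB1", "AA")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            needleman_wunsch_align("", "AA")

    def test_gap_removal_recovers_inputs(self):
        rng = random.Random(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(aas) for _ in range(rng.randint(5, 30)))
            b = "".join(rng.choice(aas) for _ in range(rng.randint(5, 30)))
            aln = needleman_wunsch_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b
            assert aln.length >= max(len(a), len(b))

    @pytest.mark.parametrize("end_gaps_free", [True, False])
    def test_score_matches_exhaustive_enumeration(self, end_gaps_free):
        mat = blosum62()
        rng = random.Random(17)
        alphabet = "ACDE"
        for _ in range(60):
            a = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 6)))
            dp = needleman_wunsch_align(a, b, mat, 10.0, 0.5, end_gaps_free).score
            bf = brute_force_alignment_score(a, b, mat.score, 10.0, 0.5, end_gaps_free)
            assert dp == pytest.approx(bf, abs=1e-9)

    def test_score_matches_biopython_aligner(self):
        """Independent cross-check against Bio.Align.PairwiseAligner with the
        same matrix, affine gap costs and free end gaps."""
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
        rng = random.Random(23)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            a = "".join(rng.choice(aas) for _ in range(rng.randint(10, 60)))
            b = "".join(rng.choice(aas) for _ in range(rng.randint(10, 60)))
            ours = needleman_wunsch_align(a, b).score
            assert ours == pytest.approx(aligner.score(a, b), abs=1e-6)

    def test_score_symmetric_in_arguments(self):
        rng = random.Random(31)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(rng.choice(aas) for _ in range(rng.randint(5, 25)))
            b = "".join(rng.choice(aas) for _ in range(rng.randint(5, 25)))
            assert needleman_wunsch_align(a, b).score == pytest.approx(
                needleman_wunsch_align(b, a).score
            )


class TestAlignmentStats:
    @pytest.mark.parametrize(
        "a,b,ident,simil,gaps",
        [
            ("AC", "AC", 100.0, 100.0, 0.0),
            ("A-", "AG", 50.0, 50.0, 50.0),
            ("AILV", "AILI", 75.0, 100.0, 0.0),  # V/I scores +3: similar
        ],
    )
    def test_examples(self, a, b, ident, simil, gaps):
        assert alignment_stats(a, b) == (ident, simil, gaps)

    def test_matches_independent_column_recount(self):
        mat = blosum62()
        rng = random.Random(41)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(aas) for _ in range(rng.randint(10, 40)))
            b = "".join(rng.choice(aas) for _ in range(rng.randint(10, 40)))
            aln = needleman_wunsch_align(a, b)
            ident = simil = gaps = 0
            for ca, cb in zip(aln.aligned_a, aln.aligned_b):
                if "-" in (ca, cb):
                    gaps += 1
                else:
                    ident += ca == cb
                    simil += mat.score(ca, cb) > 0
            L = aln.length
            assert aln.identity_pct == pytest.approx(100 * ident / L)
            assert aln.similarity_pct == pytest.approx(100 * simil / L)
            assert aln.gaps_pct == pytest.approx(100 * gaps / L)

    def test_identity_never_exceeds_similarity(self):
        rng = random.Random(43)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(aas) for _ in range(15))
            b = "".join(rng.choice(aas) for _ in range(15))
            aln = needleman_wunsch_align(a, b)
            assert aln.identity_pct <= aln.similarity_pct

    def test_self_alignment_full_identity_no_gaps(self):
        rng = random.Random(47)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        s = "".join(rng.choice(aas) for _ in range(30))
        aln = needleman_wunsch_align(s, s)
        assert aln.identity_pct == 100.0 and aln.gaps_pct == 0.0


class TestRescueReport:
    REF = "MPGVTVKDVNQQEFVRALAAFLKKSGKLKVPEWVDTVKLAKHKELAPYDENWFYTRAAST"

    def test_back_translated_reference_is_perfect_frame_one(self):
        _, dna, _ = degrade_protein(self.REF, 1.0, seed=5, name="pg")
        rep = pseudogene_rescue_report(dna, self.REF)
        assert rep.frame == 1
        assert rep.alignment.identity_pct == 100.0
        assert rep.diff_positions == []

    def test_one_nt_prefix_selects_frame_two(self):
        _, dna, _ = degrade_protein(self.REF, 1.0, seed=5, frame_shift=1, name="pg")
        rep = pseudogene_rescue_report(dna, self.REF)
        assert rep.frame == 2

    def test_reverse_complement_selects_negative_frame(self):
        _, dna, _ = degrade_protein(self.REF, 1.0, seed=5, reverse=True, name="pg")
        rep = pseudogene_rescue_report(dna, self.REF)
        assert rep.frame == -1
        assert rep.alignment.identity_pct == 100.0

    def test_planted_identity_recovered_within_one_column(self):
        for target in (0.9, 0.8):
            _, dna, truth = degrade_protein(self.REF, target, seed=9, name="pg")
            rep = pseudogene_rescue_report(dna, self.REF)
            planted = 100.0 * (len(self.REF) - truth["n_substitutions"]) / len(self.REF)
            assert abs(rep.alignment.identity_pct - planted) <= 100.0 / len(self.REF)

    def test_indels_produce_gap_columns(self):
        _, dna, _ = degrade_protein(self.REF, 0.5, allow_indels=True, seed=13, name="pg")
        rep = pseudogene_rescue_report(dna, self.REF)
        assert rep.alignment.gaps_pct > 0.0

    def test_diff_positions_are_reference_indices(self):
        _, dna, truth = degrade_protein(self.REF, 0.9, seed=15, name="pg")
        rep = pseudogene_rescue_report(dna, self.REF)
        assert all(1 <= p <= len(self.REF) for p in rep.diff_positions)
        assert len(rep.diff_positions) == truth["n_substitutions"]
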
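"""Global alignment optimality, similarity percentages, paralog pairing."""

import numpy as np
import pytest

from mipkit.pairwise import (
    PairingConfig, PairwiseAlignment, all_pairs_table, find_paralog_pairs,
    global_align, load_matrix, percent_similarity,
)
from mipkit.seqio import ProteinRecord


def rec(seq, rid="x"):
    return ProteinRecord(id=rid, sequence=seq)


def brute_force_score(a, b, score, gap_open, gap_extend):
    """Exhaustive enumeration over every global alignment.

    Scores a full column list with affine gaps (a length-L run costs
    open + (L-1)*extend, terminal runs included), independently of any DP.
    """
    best = [-np.inf]

    def col_score(cols):
        total = 0.0
        for row in (0, 1):
            run = 0
            for col in cols:
                if col[row] is None:
                    run += 1
                else:
                    if run:
                        total -= gap_open + (run - 1) * gap_extend
                    run = 0
            if run:
                total -= gap_open + (run - 1) * gap_extend
        total += sum(score(x, y) for x, y in cols if x is not None and y is not None)
        return total

    def walk(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], col_score(cols))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            walk(i + 1, j, cols + [(a[i], None)])
        if j < len(b):
            walk(i, j + 1, cols + [(None, b[j])])

    walk(0, 0, [])
    return best[0]


def blosum_fn():
    alphabet, mat = load_matrix("BLOSUM62")
    idx = {c: i for i, c in enumerate(alphabet)}
    return lambda x, y: mat[idx[x], idx[y]]


class TestGlobalAlign:
    def test_identical_sequences_align_gap_free(self):
        aln = global_align(rec("MKVLINAPW", "a"), rec("MKVLINAPW", "b"))
        assert aln.pid == 100.0 and "-" not in aln.row_a + aln.row_b

    def test_single_mismatch_column(self):
        aln = global_align(rec("A", "a"), rec("C", "b"))
        assert (aln.row_a, aln.row_b) == ("A", "C")

    def test_empty_sequence_rejected(self):
        b = rec("A", "b")
        b.sequence = ""  # bypass construction-time validation
        with pytest.raises(ValueError):
            global_align(rec("A", "a"), b)

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            global_align(rec("AC", "a"), rec("AC", "b"),
                         PairingConfig(matrix="NOSUCH"))

    @pytest.mark.parametrize("seed", range(4))
    def test_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        score = blosum_fn()
        cfg = PairingConfig()
        for _ in range(8):
            a = "".join(rng.choice(list("ACDE"), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACDE"), size=rng.integers(1, 7)))
            expect = brute_force_score(a, b, score, cfg.gap_open, cfg.gap_extend)
            got = global_align(rec(a, "a"), rec(b, "b"), cfg).score
            assert got == pytest.approx(expect, abs=1e-9), (a, b)

    def test_score_matches_biopython_aligner(self, rng):
        from Bio.Align import PairwiseAligner, substitution_matrices

        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        for _ in range(15):
            a = "".join(rng.choice(list("ACDEFGHIKL"), size=rng.integers(10, 40)))
            b = "".join(rng.choice(list("ACDEFGHIKL"), size=rng.integers(10, 40)))
            assert global_align(rec(a, "a"), rec(b, "b")).score == pytest.approx(
                aligner.score(a, b), abs=1e-9
            )

    def test_score_symmetric(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACDEFGHIKL"), size=20))
            b = "".join(rng.choice(list("ACDEFGHIKL"), size=25))
            s1 = global_align(rec(a, "a"), rec(b, "b")).score
            s2 = global_align(rec(b, "b"), rec(a, "a")).score
            assert s1 == pytest.approx(s2)

    def test_ungapping_recovers_inputs(self, rng):
        a = "".join(rng.choice(list("ACDEFGHIKL"), size=30))
        b = "".join(rng.choice(list("ACDEFGHIKL"), size=22))
        aln = global_align(rec(a, "a"), rec(b, "b"))
        assert aln.row_a.replace("-", "") == a
        assert aln.row_b.replace("-", "") == b


class TestPercentSimilarity:
    def test_identical_rows_both_modes(self):
        aln = PairwiseAlignment("a", "b", "MKVLINAPWE", "MKVLINAPWE", 0, 0, 0)
        assert percent_similarity(aln, "identity") == 100.0
        assert percent_similarity(aln, "positives") == 100.0

    def test_hand_built_alignment(self):
        # 10 columns: 7 identities, 1 positive pair (I/L scores +2 in
        # BLOSUM62), 2 gap columns -> 70% identity, 80% positives
        aln = PairwiseAlignment("a", "b", "MKVAINAPWE", "MKVAL--PWE", 0, 0, 0)
        assert percent_similarity(aln, "identity") == pytest.approx(70.0)
        assert percent_similarity(aln, "positives") == pytest.approx(80.0)

    def test_zero_length_rejected(self):
        aln = PairwiseAlignment("a", "b", "", "", 0, 0, 0)
        with pytest.raises(ValueError, match="zero-length"):
            percent_similarity(aln, "identity")

    def test_positives_never_below_identity(self, rng):
        for _ in range(100):
            a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                   size=rng.integers(5, 40)))
            b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                   size=rng.integers(5, 40)))
            aln = global_align(rec(a, "a"), rec(b, "b"))
            assert aln.psim >= aln.pid


class TestFindParalogPairs:
    def test_identical_pair_detected(self, rng):
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        other = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        hits = find_paralog_pairs(
            [rec(a, "p1"), rec(a, "p2"), rec(other, "q")]
        )
        assert [(h[0], h[1]) for h in hits] == [("p1", "p2")]

    def test_threshold_100_returns_nothing_for_distinct(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
                for _ in range(4)]
        recs = [rec(s, f"s{i}") for i, s in enumerate(seqs)]
        assert find_paralog_pairs(recs, PairingConfig(threshold=100.0)) == []

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            find_paralog_pairs([rec("ACDE", "a")])

    def test_planted_near_duplicates_recovered_exactly(self, small_family):
        hits = find_paralog_pairs(small_family.records)
        got = sorted((h[0], h[1]) for h in hits)
        assert got == small_family.truth.pairs

    def test_all_pairs_table_shape(self):
        recs = [rec("ACDEFGHIKL", "a"), rec("ACDEFGHIKV", "b"),
                rec("MNPQRSTVWY", "c")]
        df = all_pairs_table(recs)
        assert len(df) == 3 and (df.psim >= df.pid).all()
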
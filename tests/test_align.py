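import random

import numpy as np
import pytest

from amplikit._kernels import MOVE_DIAG, MOVE_E, MOVE_F
from amplikit.align import (
    AlignmentResult,
    ScoringParams,
    compute_identity,
    global_align,
    global_align_linear,
    score_moves,
)


def enumerate_optimum(a, b, params):
    """Exhaustive alignment enumeration (tiny inputs only).

    Scores every path with the position-dependent gap model via
    score_moves, which walks the moves independently of any DP kernel.
    """
    best = [None]

    def rec(i, j, moves):
        if i == len(a) and j == len(b):
            s = score_moves(moves, a, b, params)
            if best[0] is None or s > best[0]:
                best[0] = s
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, moves + [MOVE_DIAG])
        if j < len(b):
            rec(i, j + 1, moves + [MOVE_E])
        if i < len(a):
            rec(i + 1, j, moves + [MOVE_F])

    rec(0, 0, [])
    return best[0]


def biopython_aligner(p: ScoringParams):
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = p.match_reward
    a.mismatch_score = p.mismatch_penalty
    # our gap run of length L costs open + L*extend; biopython charges the
    # "open" score at the first gap position and "extend" at the rest
    a.open_internal_deletion_score = -(p.gap_open_interior_query + p.gap_extend_interior_query)
    a.extend_internal_deletion_score = -p.gap_extend_interior_query
    a.open_left_deletion_score = -(p.gap_open_terminal_query + p.gap_extend_terminal_query)
    a.extend_left_deletion_score = -p.gap_extend_terminal_query
    a.open_right_deletion_score = -(p.gap_open_terminal_query + p.gap_extend_terminal_query)
    a.extend_right_deletion_score = -p.gap_extend_terminal_query
    a.open_internal_insertion_score = -(p.gap_open_interior_target + p.gap_extend_interior_target)
    a.extend_internal_insertion_score = -p.gap_extend_interior_target
    a.open_left_insertion_score = -(p.gap_open_terminal_target + p.gap_extend_terminal_target)
    a.extend_left_insertion_score = -p.gap_extend_terminal_target
    a.open_right_insertion_score = -(p.gap_open_terminal_target + p.gap_extend_terminal_target)
    a.extend_right_insertion_score = -p.gap_extend_terminal_target
    return a


class TestGlobalAlign:
    def test_identity_alignment(self):
        r = global_align("ACGT", "ACGT")
        assert (r.matches, r.mismatches, r.columns) == (4, 0, 4)
        assert r.score == 4 * ScoringParams().match_reward
        assert r.cigar == "4M"

    def test_single_substitution(self):
        r = global_align("ACGT", "AGGT")
        assert (r.matches, r.mismatches) == (3, 1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_column_accounting_invariant(self, dna_factory):
        for _ in range(25):
            r = global_align(dna_factory(40), dna_factory(55))
            assert (
                r.matches + r.mismatches + r.internal_gap_columns
                + r.terminal_gap_columns == r.columns
            )
            # CIGAR lengths reconcile with the two sequence lengths
            n_m = sum(1 for mv in r.moves if mv == MOVE_DIAG)
            n_d = sum(1 for mv in r.moves if mv == MOVE_E)
            n_i = sum(1 for mv in r.moves if mv == MOVE_F)
            assert n_m + n_i == 40
            assert n_m + n_d == 55

    def test_exhaustive_enumeration_oracle(self):
        rand = random.Random(101)
        params = ScoringParams()
        for _ in range(60):
            a = "".join(rand.choice("ACGT") for _ in range(rand.randint(1, 5)))
            b = "".join(rand.choice("ACGT") for _ in range(rand.randint(1, 5)))
            expected = enumerate_optimum(a, b, params)
            assert global_align(a, b, params, method="full").score == expected
            assert global_align_linear(a, b, params).score == expected

    def test_brute_force_dp_oracle_random_pairs(self, pyrng):
        params = ScoringParams()
        oracle = biopython_aligner(params)
        for _ in range(200):
            la, lb = pyrng.randint(10, 60), pyrng.randint(10, 60)
            a = "".join(pyrng.choice("ACGT") for _ in range(la))
            b = "".join(pyrng.choice("ACGT") for _ in range(lb))
            assert global_align(a, b, params).score == oracle.score(b, a)

    def test_score_symmetry_with_equal_penalties(self, dna_factory):
        for _ in range(20):
            a, b = dna_factory(30), dna_factory(45)
            assert global_align(a, b).score == global_align(b, a).score

    def test_identical_suffix_never_decreases_score(self, dna_factory):
        # holds under uniform gap pricing; with discounted terminal gaps a
        # trailing gap can lose its discount when a suffix lands behind it
        params = ScoringParams(
            gap_open_terminal_query=20, gap_open_terminal_target=20,
            gap_extend_terminal_query=2, gap_extend_terminal_target=2,
        )
        for _ in range(20):
            a, b = dna_factory(25), dna_factory(30)
            base = global_align(a, b, params).score
            suffix = dna_factory(10)
            assert global_align(a + suffix, b + suffix, params).score >= base


class TestLinearMemoryVariant:
    def test_equal_scores_with_full_dp(self, pyrng):
        params = ScoringParams()
        for _ in range(50):
            la, lb = pyrng.randint(100, 300), pyrng.randint(100, 300)
            a = "".join(pyrng.choice("ACGT") for _ in range(la))
            b = "".join(pyrng.choice("ACGT") for _ in range(lb))
            full = global_align(a, b, params, method="full")
            lin = global_align_linear(a, b, params)
            assert full.score == lin.score
            # the linear traceback must itself price to the optimal score
            assert score_moves(lin.moves, a, b, params) == full.score

    def test_identity_agrees_on_similar_pairs(self, pyrng):
        # unrelated pairs admit many co-optimal tracebacks with different
        # column counts; for homologous pairs (where identity is used)
        # both paths must report the same identity
        params = ScoringParams()
        for _ in range(30):
            a = "".join(pyrng.choice("ACGT") for _ in range(pyrng.randint(120, 250)))
            chars = list(a)
            for _ in range(pyrng.randint(1, 10)):
                pos = pyrng.randrange(len(chars))
                chars[pos] = pyrng.choice("ACGT")
            if pyrng.random() < 0.5:  # one small indel
                pos = pyrng.randrange(1, len(chars) - 1)
                chars[pos:pos] = [pyrng.choice("ACGT")]
            b = "".join(chars)
            full = global_align(a, b, params, method="full")
            lin = global_align_linear(a, b, params)
            assert full.score == lin.score
            assert compute_identity(full, len(a), len(b)) == pytest.approx(
                compute_identity(lin, len(a), len(b)), abs=1e-9
            )

    def test_product_switch_uses_linear_path(self, dna_factory):
        # 6000 x 6000 = 3.6e7 > 25,000,000: the divide-and-conquer path
        # is mandatory and must handle an all-match alignment
        seq = dna_factory(6000)
        r = global_align(seq, seq)
        assert r.matches == 6000
        assert r.columns == 6000
        assert r.mismatches == 0

    def test_forced_paths_agree_on_asymmetric_penalties(self, pyrng):
        params = ScoringParams(
            gap_open_interior_query=11, gap_open_interior_target=25,
            gap_extend_terminal_query=2, gap_extend_terminal_target=1,
        )
        for _ in range(30):
            a = "".join(pyrng.choice("ACGT") for _ in range(pyrng.randint(5, 90)))
            b = "".join(pyrng.choice("ACGT") for _ in range(pyrng.randint(5, 90)))
            assert (
                global_align(a, b, params, method="full").score
                == global_align(a, b, params, method="linear").score
            )


class TestIdentity:
    def test_identical_sequences_all_definitions(self):
        r = global_align("ACGTACGT", "ACGTACGT")
        for iddef in range(5):
            assert compute_identity(r, 8, 8, iddef) == 1.0

    def test_gapless_alignment_arithmetic(self):
        a = "A" * 9 + "C"
        b = "A" * 9 + "G"
        r = global_align(a, b)
        for iddef in (1, 2, 3, 4):
            assert compute_identity(r, 10, 10, iddef) == pytest.approx(0.9)

    def test_terminal_gap_changes_iddef1_vs_iddef2(self):
        # constructed alignment: 90 matches plus a 10-column terminal gap
        moves = np.array([MOVE_DIAG] * 90 + [MOVE_E] * 10, dtype=np.uint8)
        result = AlignmentResult(
            score=0, moves=moves, columns=100, matches=90, mismatches=0,
            internal_gap_columns=0, terminal_gap_columns=10, internal_gap_runs=0,
        )
        assert compute_identity(result, 90, 100, 1) == pytest.approx(0.90)
        assert compute_identity(result, 90, 100, 2) == pytest.approx(1.00)
        assert compute_identity(result, 90, 100, 0) == pytest.approx(1.00)

    def test_internal_gap_run_counts_once_under_iddef3(self):
        flank_l = "ACGTTGCAGCTTAGGCATCAGGCAT"
        flank_r = "TTGACCGGTAACGGTTACATGGCAA"
        a = flank_l + flank_r
        b = flank_l + "GGG" + flank_r  # one 3-base insertion relative to a
        r = global_align(a, b)
        assert r.internal_gap_columns == 3
        assert r.internal_gap_runs == 1
        assert compute_identity(r, len(a), len(b), 3) == pytest.approx(50 / 51)

    def test_zero_denominator_yields_zero(self):
        result = AlignmentResult(
            score=0, moves=np.array([MOVE_E], dtype=np.uint8), columns=1,
            matches=0, mismatches=0, internal_gap_columns=0,
            terminal_gap_columns=1, internal_gap_runs=0,
        )
        assert compute_identity(result, 0, 1, 2) == 0.0
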
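"""Optimal global pairwise alignment with affine gaps.

The cost model follows the usual amplicon-search convention: match +2,
mismatch -4, and affine gap penalties that distinguish *interior* gaps
(open 20, extend 2) from *terminal* gaps touching either end of the
alignment (open 2, extend 1), so end overhangs are cheap.  A gap run in
the query is terminal exactly when it lies before the first or after the
last query symbol, and symmetrically for the target.

Two aligners produce identical scores: a full-matrix Gotoh with traceback
(quadratic memory, used while ``len(a) * len(b) <= 25,000,000``) and a
divide-and-conquer variant (Myers–Miller style) that only ever holds a few
score vectors, used automatically above that product, which corresponds to
two 5,000 bp sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from ._kernels import MOVE_DIAG, MOVE_E, MOVE_F
from .seqio import normalize_sequence

__all__ = [
    "ScoringParams",
    "AlignmentResult",
    "global_align",
    "global_align_linear",
    "compute_identity",
    "LINEAR_MEMORY_PRODUCT",
]

LINEAR_MEMORY_PRODUCT = 25_000_000

# 4-bit IUPAC masks (A=1, C=2, G=4, T=8)
_CHAR_CODE = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "M": 3, "R": 5, "S": 6, "W": 9, "Y": 10, "K": 12,
    "V": 7, "H": 11, "D": 13, "B": 14, "N": 15,
}


def sequence_codes(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as 4-bit IUPAC masks (case-insensitive)."""
    codes = np.empty(len(sequence), dtype=np.uint8)
    for idx, ch in enumerate(sequence.upper()):
        code = _CHAR_CODE.get(ch)
        if code is None:
            raise ValueError(f"non-IUPAC symbol {ch!r} at position {idx}")
        codes[idx] = code
    return codes


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scores and penalties (penalties are non-negative)."""

    match_reward: int = 2
    mismatch_penalty: int = -4
    gap_open_interior_query: int = 20
    gap_open_interior_target: int = 20
    gap_open_terminal_query: int = 2
    gap_open_terminal_target: int = 2
    gap_extend_interior_query: int = 2
    gap_extend_interior_target: int = 2
    gap_extend_terminal_query: int = 1
    gap_extend_terminal_target: int = 1

    def __post_init__(self):
        if self.match_reward <= self.mismatch_penalty:
            raise ValueError("match_reward must exceed mismatch_penalty")
        for name in (
            "gap_open_interior_query", "gap_open_interior_target",
            "gap_open_terminal_query", "gap_open_terminal_target",
            "gap_extend_interior_query", "gap_extend_interior_target",
            "gap_extend_terminal_query", "gap_extend_terminal_target",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def substitution_matrix(self) -> np.ndarray:
        """16x16 int64 matrix over IUPAC mask codes.

        Equal symbols score the match reward; N against anything scores 0;
        other overlapping ambiguity sets score the match reward; disjoint
        sets score the mismatch penalty.
        """
        S = np.empty((16, 16), dtype=np.int64)
        for x in range(16):
            for y in range(16):
                if x == y:
                    S[x, y] = self.match_reward
                elif x == 15 or y == 15:
                    S[x, y] = 0
                elif x & y:
                    S[x, y] = self.match_reward
                else:
                    S[x, y] = self.mismatch_penalty
        return S

    def penalty_vector(self) -> np.ndarray:
        return np.array(
            [
                self.gap_open_interior_query, self.gap_extend_interior_query,
                self.gap_open_terminal_query, self.gap_extend_terminal_query,
                self.gap_open_interior_target, self.gap_extend_interior_target,
                self.gap_open_terminal_target, self.gap_extend_terminal_target,
            ],
            dtype=np.int64,
        )


@dataclass
class AlignmentResult:
    """One optimal global alignment and its column bookkeeping.

    ``moves`` is the alignment path: 0 = aligned column, 1 = gap in the
    query (target symbol consumed), 2 = gap in the target.  The CIGAR is
    query-centric: M aligned, D gap in query, I gap in target.
    """

    score: int
    moves: np.ndarray
    columns: int
    matches: int
    mismatches: int
    internal_gap_columns: int
    terminal_gap_columns: int
    internal_gap_runs: int

    @property
    def cigar(self) -> str:
        parts = []
        symbols = {MOVE_DIAG: "M", MOVE_E: "D", MOVE_F: "I"}
        prev = None
        run = 0
        for mv in self.moves:
            if prev is not None and mv != prev:
                parts.append(f"{run}{symbols[prev]}")
                run = 0
            prev = mv
            run += 1
        if prev is not None:
            parts.append(f"{run}{symbols[prev]}")
        return "".join(parts)

    def aligned_strings(self, a: str, b: str) -> tuple[str, str]:
        """Render the two gapped rows of the alignment."""
        ra, rb = [], []
        i = j = 0
        for mv in self.moves:
            if mv == MOVE_DIAG:
                ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
            elif mv == MOVE_E:
                ra.append("-"); rb.append(b[j]); j += 1
            else:
                ra.append(a[i]); rb.append("-"); i += 1
        return "".join(ra), "".join(rb)


def _summarize(score: int, moves: np.ndarray, a_norm: str, b_norm: str) -> AlignmentResult:
    columns = len(moves)
    # leading/trailing runs of gap columns are terminal
    lead = 0
    while lead < columns and moves[lead] != MOVE_DIAG:
        lead += 1
    trail = 0
    while trail < columns - lead and moves[columns - 1 - trail] != MOVE_DIAG:
        trail += 1
    matches = mismatches = 0
    internal_gap_columns = 0
    internal_gap_runs = 0
    i = j = 0
    prev_mv = None
    for idx, mv in enumerate(moves):
        interior = lead <= idx < columns - trail
        if mv == MOVE_DIAG:
            if a_norm[i] == b_norm[j]:
                matches += 1
            else:
                mismatches += 1
            i += 1
            j += 1
        else:
            if mv == MOVE_E:
                j += 1
            else:
                i += 1
            if interior:
                internal_gap_columns += 1
                if mv != prev_mv:
                    internal_gap_runs += 1
        prev_mv = mv
    return AlignmentResult(
        score=int(score),
        moves=moves,
        columns=columns,
        matches=matches,
        mismatches=mismatches,
        internal_gap_columns=internal_gap_columns,
        terminal_gap_columns=lead + trail,
        internal_gap_runs=internal_gap_runs,
    )


def score_moves(
    moves: np.ndarray, a: str, b: str, params: Optional[ScoringParams] = None
) -> int:
    """Score an alignment path under the position-dependent gap model.

    Independent of the DP kernels; used to price divide-and-conquer
    alignments and as an internal consistency check.
    """
    params = params or ScoringParams()
    S = params.substitution_matrix()
    ac = sequence_codes(a)
    bc = sequence_codes(b)
    m, n = len(ac), len(bc)
    total = 0
    i = j = 0
    prev = None
    for mv in moves:
        if mv == MOVE_DIAG:
            total += int(S[ac[i], bc[j]])
            i += 1
            j += 1
        elif mv == MOVE_E:
            terminal = i == 0 or i == m
            if terminal:
                open_, ext = params.gap_open_terminal_query, params.gap_extend_terminal_query
            else:
                open_, ext = params.gap_open_interior_query, params.gap_extend_interior_query
            if prev != MOVE_E:
                total -= open_
            total -= ext
            j += 1
        else:
            terminal = j == 0 or j == n
            if terminal:
                open_, ext = params.gap_open_terminal_target, params.gap_extend_terminal_target
            else:
                open_, ext = params.gap_open_interior_target, params.gap_extend_interior_target
            if prev != MOVE_F:
                total -= open_
            total -= ext
            i += 1
        prev = mv
    return total


def _validate(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("cannot align an empty sequence")


def global_align(
    a: str,
    b: str,
    params: Optional[ScoringParams] = None,
    *,
    method: str = "auto",
) -> AlignmentResult:
    """Optimal global alignment of query ``a`` against target ``b``.

    ``method`` is ``auto`` (full dynamic programming up to a length
    product of 25,000,000, divide-and-conquer above), ``full`` or
    ``linear`` to force either path.
    """
    _validate(a, b)
    params = params or ScoringParams()
    if method == "auto":
        method = "full" if len(a) * len(b) <= LINEAR_MEMORY_PRODUCT else "linear"
    if method == "linear":
        return global_align_linear(a, b, params)
    if method != "full":
        raise ValueError(f"unknown method {method!r}")
    ac = sequence_codes(a)
    bc = sequence_codes(b)
    score, moves = _kernels.gotoh_full(
        ac, bc, params.substitution_matrix(), params.penalty_vector()
    )
    return _summarize(score, moves, normalize_sequence(a), normalize_sequence(b))


def global_align_linear(
    a: str, b: str, params: Optional[ScoringParams] = None
) -> AlignmentResult:
    """Divide-and-conquer global alignment in linear memory.

    Splits the query at its midpoint, locates the optimal crossing column
    of the split row from forward and backward score vectors (including
    crossings inside a vertical gap run, whose open penalty must not be
    charged twice), and recurses.  The score always equals
    :func:`global_align`; the traceback is one optimal alignment, not
    necessarily the same one.
    """
    _validate(a, b)
    params = params or ScoringParams()
    ac = sequence_codes(a)
    bc = sequence_codes(b)
    ar = ac[::-1].copy()
    br = bc[::-1].copy()
    m, n = len(ac), len(bc)
    S = params.substitution_matrix()
    pens = params.penalty_vector()
    moves: list[int] = []
    _mm_recurse(ac, bc, ar, br, 0, m, 0, n, m, n, False, False, S, pens, moves)
    moves_arr = np.asarray(moves, dtype=np.uint8)
    score = score_moves(moves_arr, a, b, params)
    return _summarize(score, moves_arr, normalize_sequence(a), normalize_sequence(b))


def _gap_cost(pens: np.ndarray, base: int, edge: bool, length: int) -> int:
    if length == 0:
        return 0
    off = base + (2 if edge else 0)
    return -(int(pens[off]) + length * int(pens[off + 1]))


def _mm_recurse(
    ac, bc, ar, br, i1, i2, j1, j2, m, n, top_free, bot_free, S, pens, out
) -> None:
    R = i2 - i1
    W = j2 - j1
    if R == 0:
        out.extend([MOVE_E] * W)
        return
    if R == 1:
        out.extend(_base_row(ac, bc, i1, j1, j2, m, n, top_free, bot_free, S, pens))
        return
    mid = (i1 + i2) // 2
    CCf, DDf = _kernels.gotoh_forward(ac, bc, i1, mid, j1, j2, m, n, top_free, S, pens)
    CCb, DDb = _kernels.gotoh_forward(
        ar, br, m - i2, m - mid, n - j2, n - j1, m, n, bot_free, S, pens
    )
    best = None
    for jj in range(W + 1):
        j = j1 + jj
        t1 = int(CCf[jj]) + int(CCb[W - jj])
        if best is None or t1 > best[0]:
            best = (t1, jj, 1)
        edge = j == 0 or j == n
        open_f = int(pens[6] if edge else pens[4])
        t2 = int(DDf[jj]) + int(DDb[W - jj]) + open_f
        if t2 > best[0]:
            best = (t2, jj, 2)
    _, jj, kind = best
    js = j1 + jj
    if kind == 1:
        _mm_recurse(ac, bc, ar, br, i1, mid, j1, js, m, n, top_free, False, S, pens, out)
        _mm_recurse(ac, bc, ar, br, mid, i2, js, j2, m, n, False, bot_free, S, pens, out)
    else:
        # the optimal path crosses the split row inside a vertical gap run:
        # the two symbols around the split are emitted here and the halves
        # are told not to re-charge the run's open penalty at their corner
        _mm_recurse(ac, bc, ar, br, i1, mid - 1, j1, js, m, n, top_free, True, S, pens, out)
        out.extend([MOVE_F, MOVE_F])
        _mm_recurse(ac, bc, ar, br, mid + 1, i2, js, j2, m, n, True, bot_free, S, pens, out)


def _base_row(ac, bc, i1, j1, j2, m, n, top_free, bot_free, S, pens) -> list[int]:
    """Optimal alignment of a single query symbol against b[j1:j2]."""
    W = j2 - j1
    i2 = i1 + 1
    e_top = i1 == 0 or i1 == m
    e_bot = i2 == 0 or i2 == m
    best_score = None
    best_moves = None
    for p in range(W):
        score = (
            _gap_cost(pens, 0, e_top, p)
            + int(S[ac[i1], bc[j1 + p]])
            + _gap_cost(pens, 0, e_bot, W - 1 - p)
        )
        if best_score is None or score > best_score:
            best_score = score
            best_moves = [MOVE_E] * p + [MOVE_DIAG] + [MOVE_E] * (W - 1 - p)
    for p in range(W + 1):
        jp = j1 + p
        edge = jp == 0 or jp == n
        open_f = 0 if (p == 0 and top_free) or (p == W and bot_free) else int(
            pens[6] if edge else pens[4]
        )
        fcost = open_f + int(pens[7] if edge else pens[5])
        score = (
            _gap_cost(pens, 0, e_top, p) - fcost + _gap_cost(pens, 0, e_bot, W - p)
        )
        if best_score is None or score > best_score:
            best_score = score
            best_moves = [MOVE_E] * p + [MOVE_F] + [MOVE_E] * (W - p)
    return best_moves


def compute_identity(
    result: AlignmentResult, len_a: int, len_b: int, iddef: int = 2
) -> float:
    """Fraction identity of an alignment under one of five definitions.

    0: matches / length of the shorter sequence;
    1: matches / alignment columns;
    2 (default): matches / columns excluding terminal gap columns;
    3: matches / (matches + mismatches + internal gap runs), counting each
       internal indel run as a single difference;
    4: matches / alignment columns with all gap columns counted
       (BLAST-style).
    A zero denominator yields identity 0.
    """
    r = result
    if iddef == 0:
        denom = min(len_a, len_b)
    elif iddef in (1, 4):
        denom = r.columns
    elif iddef == 2:
        denom = r.columns - r.terminal_gap_columns
    elif iddef == 3:
        denom = r.matches + r.mismatches + r.internal_gap_runs
    else:
        raise ValueError(f"iddef must be 0..4, got {iddef}")
    if denom <= 0:
        return 0.0
    return r.matches / denom
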
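"""Paired-end read merging by optimal ungapped overlap.

The reverse read is reverse-complemented and slid along the forward read;
every overlap is scored column by column with quality-weighted match and
mismatch contributions (alpha = +4, beta = -5 at perfect quality, shrunk
towards each other as the error probabilities p1, p2 of the two observed
bases grow, assuming uniform 0.25 base frequencies):

    observed equal:     alpha * P + beta * (1 - P),
        P = (1-p1)(1-p2) + p1 p2 / 3           (both right, or both wrong
                                                the same way)
    observed different: beta * P' + alpha * (1 - P'),
        P' = 1 - [(1-p1) p2/3 + (1-p2) p1/3 + 2 p1 p2 / 9]
                                               (complement of the chance
                                                the true bases coincide)

The best-scoring overlap is kept if it is long enough, has few enough
observed mismatches and yields a merged length in bounds.  Overlapping
columns receive posterior qualities: agreement multiplies the evidence
(quality goes up), disagreement keeps the better base with reduced
confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .seqio import SequenceRecord, normalize_sequence, reverse_complement

__all__ = [
    "MergeOptions",
    "MergeResult",
    "overlap_score",
    "merge_pair",
    "merge_pairs",
    "posterior_quality",
]

_MAX_Q = 93  # highest representable Phred score (ASCII '~' at +33)


@dataclass(frozen=True)
class MergeOptions:
    min_overlap: int = 10
    max_diffs: int = 5
    min_merged_len: int = 1
    max_merged_len: Optional[int] = None
    allow_stagger: bool = False
    alpha: float = 4.0
    beta: float = -5.0
    qmax_out: int = 41

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (self.alpha > 0 > self.beta):
            raise ValueError("alpha must be positive and beta negative")


@dataclass
class MergeResult:
    merged: Optional[SequenceRecord]
    reason: Optional[str]  # rejection reason, None when merged
    offset: int = 0  # reverse-complement start minus forward start
    overlap: int = 0
    diffs: int = 0
    score: float = 0.0

    @property
    def ok(self) -> bool:
        return self.merged is not None


def _error_prob(q: int) -> float:
    return 10.0 ** (-q / 10.0)


_table_cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}


def _score_tables(alpha: float, beta: float) -> tuple[np.ndarray, np.ndarray]:
    key = (alpha, beta)
    if key not in _table_cache:
        q = np.arange(_MAX_Q + 1)
        p = 10.0 ** (-q / 10.0)
        p1 = p[:, None]
        p2 = p[None, :]
        p_same = (1 - p1) * (1 - p2) + p1 * p2 / 3.0
        eq = alpha * p_same + beta * (1 - p_same)
        p_diff = 1.0 - ((1 - p1) * p2 / 3.0 + (1 - p2) * p1 / 3.0 + 2 * p1 * p2 / 9.0)
        ne = beta * p_diff + alpha * (1 - p_diff)
        _table_cache[key] = (eq, ne)
    return _table_cache[key]


def posterior_quality(q1: int, q2: int, agree: bool, qmax_out: int = 41) -> int:
    """Posterior Phred score of an overlap column.

    On agreement the posterior error probability is
    ``p1 p2/3 / (1 - p1 - p2 + 4 p1 p2/3)``; on disagreement the base with
    the smaller error probability is kept (p1 <= p2 after swapping) with
    ``p1 (1 - p2/3) / (p1 + p2 - 4 p1 p2/3)``.  The result is rounded and
    capped at ``qmax_out``.
    """
    if q1 < 0 or q2 < 0:
        raise ValueError("qualities must be >= 0")
    p1, p2 = _error_prob(q1), _error_prob(q2)
    if agree:
        num = p1 * p2 / 3.0
        den = 1.0 - p1 - p2 + 4.0 * p1 * p2 / 3.0
    else:
        if p1 > p2:
            p1, p2 = p2, p1
        num = p1 * (1.0 - p2 / 3.0)
        den = p1 + p2 - 4.0 * p1 * p2 / 3.0
    if den <= 0.0 or num <= 0.0:
        return qmax_out if agree else 0
    p_post = num / den
    if p_post >= 1.0:
        return 0
    q_post = round(-10.0 * math.log10(p_post))
    return min(q_post, qmax_out)


def overlap_score(
    forward: SequenceRecord,
    reverse_rc: SequenceRecord,
    offset: int,
    options: Optional[MergeOptions] = None,
) -> float:
    """Quality-weighted score of one overlap placement.

    ``offset`` positions the reverse-complement start relative to the
    forward start; the overlapping columns are scored and summed.
    """
    options = options or MergeOptions()
    eq, ne = _score_tables(options.alpha, options.beta)
    f = normalize_sequence(forward.sequence)
    r = normalize_sequence(reverse_rc.sequence)
    lo = max(0, offset)
    hi = min(len(f), offset + len(r))
    if hi - lo < 1:
        raise ValueError("overlap must contain at least one column")
    total = 0.0
    for p in range(lo, hi):
        q1 = min(forward.qualities[p], _MAX_Q)
        q2 = min(reverse_rc.qualities[p - offset], _MAX_Q)
        if f[p] == r[p - offset]:
            total += eq[q1, q2]
        else:
            total += ne[q1, q2]
    return total


def merge_pair(
    forward: SequenceRecord,
    reverse: SequenceRecord,
    options: Optional[MergeOptions] = None,
) -> MergeResult:
    """Merge one read pair or report why it cannot be merged.

    All overlap placements are scored (ties prefer the smaller overlap)
    and the winner is checked against the minimum overlap, the stagger
    rule, the mismatch budget and the merged-length bounds, in that
    order.  In a staggered placement the 3' overhangs are trimmed and
    only the overlapping consensus is kept.
    """
    options = options or MergeOptions()
    if forward.qualities is None or reverse.qualities is None:
        raise ValueError("paired-end merging requires FASTQ qualities")
    rc = reverse_complement(reverse)
    eq, ne = _score_tables(options.alpha, options.beta)
    fcodes = np.frombuffer(normalize_sequence(forward.sequence).encode(), dtype=np.uint8)
    rcodes = np.frombuffer(normalize_sequence(rc.sequence).encode(), dtype=np.uint8)
    fquals = np.clip(np.asarray(forward.qualities, dtype=np.int64), 0, _MAX_Q)
    rquals = np.clip(np.asarray(rc.qualities, dtype=np.int64), 0, _MAX_Q)
    d, score, diffs, olen = _kernels.merge_offset_scan(
        fcodes, fquals, rcodes, rquals, eq, ne
    )
    base = MergeResult(None, None, offset=int(d), overlap=int(olen),
                       diffs=int(diffs), score=float(score))
    if olen < options.min_overlap:
        base.reason = "overlap too short"
        return base
    if d < 0 and not options.allow_stagger:
        base.reason = "staggered"
        return base
    if diffs > options.max_diffs:
        base.reason = "too many differences"
        return base

    lf, lr = len(fcodes), len(rcodes)
    lo, hi = max(0, d), min(lf, d + lr)
    seq: list[str] = []
    quals: list[int] = []
    if d >= 0:
        seq.extend(forward.sequence[:lo])
        quals.extend(forward.qualities[:lo])
    for p in range(lo, hi):
        fb, rb = forward.sequence[p], rc.sequence[p - d]
        q1, q2 = forward.qualities[p], rc.qualities[p - d]
        if fcodes[p] == rcodes[p - d]:
            seq.append(fb)
            quals.append(posterior_quality(q1, q2, True, options.qmax_out))
        else:
            # keep the higher-quality base; ties keep the forward base
            seq.append(fb if q1 >= q2 else rb)
            quals.append(posterior_quality(q1, q2, False, options.qmax_out))
    if d >= 0:
        if d + lr > lf:
            seq.extend(rc.sequence[hi - d:])
            quals.extend(rc.qualities[hi - d:])
        else:
            seq.extend(forward.sequence[hi:])
            quals.extend(forward.qualities[hi:])
    merged_seq = "".join(seq)
    if len(merged_seq) < options.min_merged_len:
        base.reason = "merged sequence too short"
        return base
    if options.max_merged_len is not None and len(merged_seq) > options.max_merged_len:
        base.reason = "merged sequence too long"
        return base
    base.merged = SequenceRecord(
        label=forward.label,
        description=forward.description,
        sequence=merged_seq,
        qualities=quals,
        abundance=forward.abundance,
        ordinal=forward.ordinal,
    )
    return base


def merge_pairs(
    forwards: Sequence[SequenceRecord],
    reverses: Sequence[SequenceRecord],
    options: Optional[MergeOptions] = None,
) -> list[MergeResult]:
    if len(forwards) != len(reverses):
        raise ValueError("forward and reverse files have different read counts")
    options = options or MergeOptions()
    return [merge_pair(f, r, options) for f, r in zip(forwards, reverses)]
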
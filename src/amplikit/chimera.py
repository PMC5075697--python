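"""Chimera detection by two-parent vote scoring (UCHIME approach).

A PCR chimera is a read whose left part comes from one template and whose
right part from another.  For each query, candidate parents are collected
by splitting the query into four segments and searching each against the
parent set (identity 0.55, maxaccepts 4, maxrejects 16).  For every
candidate pair the query and both parents are merged into a three-way
alignment on query coordinates; at columns where the parents disagree the
query votes for the parent it matches.  A crossover position splits the
columns into a left and a right side; with Y yes votes (query matches the
side's model parent) and N no votes,

    h = Y / (xn * (N + dn)),         xn = 8.0, dn = 1.4 by default,

maximized over crossover positions and parent orderings, and requiring at
least one yes vote on each side (otherwise a single parent explains the
query).  A query is called chimeric when h >= minh (0.28) and the chimeric
model improves on the best single parent by at least mindiv percentage
points (0.8); with a high score but smaller improvement it is borderline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .align import global_align
from .kmer import WordIndex
from .search import SearchOptions, apply_query_mask, usearch_global
from .seqio import SequenceRecord

__all__ = ["ChimeraOptions", "ChimeraEvaluation", "find_parent_candidates",
           "score_chimera", "uchime_denovo", "uchime_ref"]


@dataclass(frozen=True)
class ChimeraOptions:
    segments: int = 4
    parent_maxaccepts: int = 4
    parent_maxrejects: int = 16
    parent_id: float = 0.55
    minh: float = 0.28
    mindiv: float = 0.8
    xn: float = 8.0
    dn: float = 1.4
    abskew: float = 2.0
    wordlength: int = 8
    qmask: str = "dust"

    def search_options(self) -> SearchOptions:
        return SearchOptions(
            id_threshold=self.parent_id,
            maxaccepts=self.parent_maxaccepts,
            maxrejects=self.parent_maxrejects,
            wordlength=self.wordlength,
            qmask=self.qmask,
            dbmask=self.qmask,
        )


@dataclass
class ChimeraEvaluation:
    query: SequenceRecord
    parent_a: Optional[SequenceRecord]
    parent_b: Optional[SequenceRecord]
    score: float  # best h
    divergence: float  # percent improvement over best single parent
    crossover: int  # column index of the best split (left side is < this)
    yes_votes: int
    no_votes: int
    abstain_votes: int
    classification: str  # chimeric | non-chimeric | borderline

    @property
    def is_chimeric(self) -> bool:
        return self.classification == "chimeric"


def _segments(sequence: str, n: int) -> list[str]:
    length = len(sequence)
    bounds = [round(i * length / n) for i in range(n + 1)]
    return [sequence[bounds[i]:bounds[i + 1]] for i in range(n)]


def find_parent_candidates(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    index: Optional[WordIndex] = None,
    options: Optional[ChimeraOptions] = None,
    *,
    denovo: bool = False,
) -> list[int]:
    """Ordinals of plausible parents for ``query`` within ``db``.

    The query is cut into near-equal segments, each searched separately so
    that a parent matching only one flank can still surface.  The query
    itself (by label) is excluded; in de novo mode parents must be at
    least ``abskew`` times as abundant as the query.
    """
    options = options or ChimeraOptions()
    sopts = options.search_options()
    if len(query.sequence) < options.segments * options.wordlength:
        return []
    if index is None:
        index = WordIndex.build(
            [apply_query_mask(r.sequence, options.qmask) for r in db],
            k=options.wordlength,
            soft_mask=True,
        )
    found: set[int] = set()
    for seg_no, segment in enumerate(_segments(query.sequence, options.segments)):
        seg_record = SequenceRecord(
            label=f"{query.label}/seg{seg_no}",
            sequence=segment,
            abundance=query.abundance,
            ordinal=query.ordinal,
        )
        for hit in usearch_global(seg_record, db, index, sopts):
            found.add(hit.target_ordinal)
    eligible = []
    for t in sorted(found):
        target = db[t]
        if target.label == query.label:
            continue
        if denovo and target.abundance < options.abskew * query.abundance:
            continue
        eligible.append(t)
    return eligible


def _three_way(query: str, pa: str, pb: str, rows_a=None, rows_b=None):
    """Merge query<->A and query<->B alignments on query coordinates.

    Gaps opened in the query by either parent alignment are propagated to
    all three rows ("once a gap, always a gap" on the query).  Returns the
    three equal-length rows (query, A, B).  ``rows_a``/``rows_b`` are
    optional precomputed (query_row, parent_row) pairs so callers scoring
    many parent pairs align each parent only once.
    """
    rows = {}
    for name, parent, pre in (("a", pa, rows_a), ("b", pb, rows_b)):
        if pre is None:
            aln = global_align(query, parent)
            pre = aln.aligned_strings(query, parent)
        rows[name] = pre
    qlen = len(query)
    ins = [0] * (qlen + 1)
    per_parent = {}
    for name in ("a", "b"):
        qrow, prow = rows[name]
        cols = []  # (query_char or '', parent_char) keyed to query position
        k = 0
        pending = []
        parent_cols = [""] * (qlen + 1)  # insertions before query position k
        aligned = [""] * qlen
        for qc, pc in zip(qrow, prow):
            if qc == "-":
                pending.append(pc)
            else:
                parent_cols[k] = "".join(pending)
                pending = []
                aligned[k] = pc
                k += 1
        parent_cols[qlen] = "".join(pending)
        per_parent[name] = (parent_cols, aligned)
        for k in range(qlen + 1):
            ins[k] = max(ins[k], len(parent_cols[k]))

    out_q, out_a, out_b = [], [], []
    (a_ins, a_al) = per_parent["a"]
    (b_ins, b_al) = per_parent["b"]
    for k in range(qlen + 1):
        width = ins[k]
        out_q.append("-" * width)
        out_a.append(a_ins[k].ljust(width, "-"))
        out_b.append(b_ins[k].ljust(width, "-"))
        if k < qlen:
            out_q.append(query[k])
            out_a.append(a_al[k])
            out_b.append(b_al[k])
    return "".join(out_q), "".join(out_a), "".join(out_b)


def _norm(ch: str) -> str:
    return ch.upper().replace("U", "T")


def _pair_identity(x: str, y: str) -> float:
    num = den = 0
    for cx, cy in zip(x, y):
        if cx == "-" and cy == "-":
            continue
        den += 1
        if _norm(cx) == _norm(cy):
            num += 1
    return num / den if den else 0.0


def score_chimera(
    query: SequenceRecord,
    parent_a: SequenceRecord,
    parent_b: SequenceRecord,
    options: Optional[ChimeraOptions] = None,
    *,
    rows_a=None,
    rows_b=None,
) -> ChimeraEvaluation:
    """Vote-score one candidate parent pair for one query."""
    options = options or ChimeraOptions()
    qr, ar, br = _three_way(
        query.sequence, parent_a.sequence, parent_b.sequence, rows_a, rows_b
    )
    ncols = len(qr)
    # per-column votes at parent-discriminating columns
    sup_a = [0] * ncols  # query sides with A where parents differ
    sup_b = [0] * ncols
    diff = [0] * ncols
    for c in range(ncols):
        a, b, q = _norm(ar[c]), _norm(br[c]), _norm(qr[c])
        if a == b:
            continue
        diff[c] = 1
        if q == a:
            sup_a[c] = 1
        elif q == b:
            sup_b[c] = 1
    cum_a = _cumsum(sup_a)
    cum_b = _cumsum(sup_b)
    cum_d = _cumsum(diff)
    tot_a, tot_b, tot_d = cum_a[-1], cum_b[-1], cum_d[-1]

    best = (0.0, 0, None, 0, 0)  # h, crossover, orientation, Y, N
    for x in range(1, ncols):
        for left_is_a in (True, False):
            if left_is_a:
                y_left, y_right = cum_a[x], tot_b - cum_b[x]
            else:
                y_left, y_right = cum_b[x], tot_a - cum_a[x]
            if y_left < 1 or y_right < 1:
                continue
            Y = y_left + y_right
            N = tot_d - Y
            h = Y / (options.xn * (N + options.dn))
            if h > best[0]:
                best = (h, x, left_is_a, Y, N)
    h, x, left_is_a, Y, N = best
    if left_is_a is None:
        divergence = 0.0
    else:
        left_parent, right_parent = (ar, br) if left_is_a else (br, ar)
        model = left_parent[:x] + right_parent[x:]
        id_model = _pair_identity(qr, model)
        id_best_single = max(_pair_identity(qr, ar), _pair_identity(qr, br))
        divergence = 100.0 * (id_model - id_best_single)
    if h >= options.minh and left_is_a is not None:
        classification = "chimeric" if divergence >= options.mindiv else "borderline"
    else:
        classification = "non-chimeric"
    return ChimeraEvaluation(
        query=query,
        parent_a=parent_a if left_is_a in (True, None) else parent_b,
        parent_b=parent_b if left_is_a in (True, None) else parent_a,
        score=h,
        divergence=divergence,
        crossover=x,
        yes_votes=Y,
        no_votes=N,
        abstain_votes=len(qr) - tot_d,
        classification=classification,
    )


def _cumsum(values: list[int]) -> list[int]:
    out = [0]
    total = 0
    for v in values:
        total += v
        out.append(total)
    return out


def _best_evaluation(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    candidates: list[int],
    options: ChimeraOptions,
) -> ChimeraEvaluation:
    best: Optional[ChimeraEvaluation] = None
    rows = {
        t: global_align(query.sequence, db[t].sequence).aligned_strings(
            query.sequence, db[t].sequence
        )
        for t in candidates
    }
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            ti, tj = candidates[i], candidates[j]
            ev = score_chimera(
                query, db[ti], db[tj], options, rows_a=rows[ti], rows_b=rows[tj]
            )
            if best is None or ev.score > best.score:
                best = ev
    if best is None:
        best = ChimeraEvaluation(
            query=query, parent_a=None, parent_b=None, score=0.0,
            divergence=0.0, crossover=0, yes_votes=0, no_votes=0,
            abstain_votes=0, classification="non-chimeric",
        )
    return best


def uchime_ref(
    records: Sequence[SequenceRecord],
    db: Sequence[SequenceRecord],
    options: Optional[ChimeraOptions] = None,
) -> list[ChimeraEvaluation]:
    """Classify each record against a reference parent database."""
    options = options or ChimeraOptions()
    index = WordIndex.build(
        [apply_query_mask(r.sequence, options.qmask) for r in db],
        k=options.wordlength,
        soft_mask=True,
    )
    out = []
    for record in records:
        candidates = find_parent_candidates(record, db, index, options)
        out.append(_best_evaluation(record, db, candidates, options))
    return out


def uchime_denovo(
    records: Sequence[SequenceRecord],
    options: Optional[ChimeraOptions] = None,
) -> list[ChimeraEvaluation]:
    """De novo classification using more abundant reads as parents.

    Records are processed in abundance-descending order; each is tested
    against the previously seen non-chimeric records, restricted to
    parents at least ``abskew`` times as abundant (chimeras are expected
    to be rarer than the templates that formed them).  Abundances must
    have been parsed (``sizein``).  Results are returned in input order.
    """
    options = options or ChimeraOptions()
    order = sorted(records, key=lambda r: (-r.abundance, r.ordinal))
    pool: list[SequenceRecord] = []
    index = WordIndex(k=options.wordlength, soft_mask=True)
    results: dict[int, ChimeraEvaluation] = {}
    for record in order:
        candidates = find_parent_candidates(
            record, pool, index, options, denovo=True
        )
        ev = _best_evaluation(record, pool, candidates, options)
        results[record.ordinal] = ev
        if not ev.is_chimeric:
            pool.append(record)
            index.add(apply_query_mask(record.sequence, options.qmask))
    return [results[r.ordinal] for r in records]
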
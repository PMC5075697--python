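"""Heuristic global-alignment search against a sequence database.

``usearch_global`` shortlists database sequences by shared-word counts,
aligns the query against candidates in shortlist order, and accepts a
candidate when its identity reaches the ``id`` threshold.  The scan stops
after ``maxaccepts`` acceptances (1 by default) or ``maxrejects``
rejections (32 by default; 0 means unlimited for either), which is what
makes the search a heuristic: a low-identity, high-word-count candidate can
exhaust the rejection budget before the best target is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import AlignmentResult, ScoringParams, compute_identity, global_align
from .kmer import WordIndex, effective_min_word_matches, rank_candidates, unique_words
from .mask import dust_mask_sequence
from .seqio import SequenceRecord, reverse_complement

__all__ = ["SearchOptions", "Hit", "usearch_global", "search_exact", "allpairs_global"]


@dataclass(frozen=True)
class SearchOptions:
    """Accept/reject policy for database search."""

    id_threshold: float = 0.0
    maxaccepts: int = 1
    maxrejects: int = 32  # 0 = unlimited
    strand: str = "plus"  # plus | both
    self_exclude: bool = False
    minqsize: int = 0
    maxgaps: Optional[int] = None
    maxsubs: Optional[int] = None
    top_hits_only: bool = False
    maxhits: Optional[int] = None
    iddef: int = 2
    wordlength: int = 8
    minwordmatches: int = 10
    qmask: str = "dust"  # none | dust | soft
    dbmask: str = "dust"
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self):
        if not 0.0 <= self.id_threshold <= 1.0:
            raise ValueError("id threshold must be within [0, 1]")
        if not 3 <= self.wordlength <= 15:
            raise ValueError("wordlength must be in 3..15")
        if self.strand not in ("plus", "both"):
            raise ValueError("strand must be 'plus' or 'both'")


@dataclass
class Hit:
    query_ordinal: int
    target_ordinal: int
    identity: float
    alignment: AlignmentResult
    strand: str = "+"


def apply_query_mask(sequence: str, mode: str) -> str:
    """Sequence used for word extraction under a masking mode.

    ``dust`` soft-masks low-complexity stretches (lowercased, excluded
    from words), ``soft`` respects existing lowercase, ``none`` uses the
    sequence verbatim (uppercased for word purposes).
    """
    if mode == "dust":
        return dust_mask_sequence(sequence, hard=False)
    if mode == "soft":
        return sequence
    if mode == "none":
        return sequence.upper()
    raise ValueError(f"unknown mask mode {mode!r}")


def build_index(db: Sequence[SequenceRecord], options: SearchOptions) -> WordIndex:
    """Word index over the database under the configured database mask."""
    masked = [apply_query_mask(r.sequence, options.dbmask) for r in db]
    return WordIndex.build(masked, k=options.wordlength, soft_mask=True)


def _scan_strand(
    query: SequenceRecord,
    sequence: str,
    strand: str,
    db: Sequence[SequenceRecord],
    index: WordIndex,
    options: SearchOptions,
) -> list[Hit]:
    masked = apply_query_mask(sequence, options.qmask)
    qwords = unique_words(masked, options.wordlength, soft_mask=True)
    min_shared = effective_min_word_matches(qwords, options.minwordmatches)
    counts = index.count_shared(qwords)
    order = rank_candidates(counts, index.target_lengths, min_shared)
    accepted: list[Hit] = []
    rejected = 0
    for t in order:
        target = db[t]
        # pre-alignment exclusions consume no rejection
        if options.self_exclude and target.label == query.label:
            continue
        if options.minqsize and query.abundance < options.minqsize:
            continue
        result = global_align(sequence, target.sequence, options.scoring)
        identity = compute_identity(result, len(sequence), len(target), options.iddef)
        ok = identity >= options.id_threshold
        if ok and options.maxgaps is not None:
            ok = result.internal_gap_columns <= options.maxgaps
        if ok and options.maxsubs is not None:
            ok = result.mismatches <= options.maxsubs
        if ok:
            accepted.append(Hit(query.ordinal, t, identity, result, strand))
            if options.maxaccepts and len(accepted) >= options.maxaccepts:
                break
        else:
            rejected += 1
            if options.maxrejects and rejected >= options.maxrejects:
                break
    return accepted


def usearch_global(
    query: SequenceRecord,
    db: Sequence[SequenceRecord],
    index: Optional[WordIndex] = None,
    options: Optional[SearchOptions] = None,
) -> list[Hit]:
    """Search one query against the database; hits sorted by identity.

    Candidates are visited in shared-word order; each is aligned and then
    accepted or rejected against the identity threshold and the post-
    alignment filters.  With ``strand both`` the reverse complement is
    searched as well and the better orientation is kept per target (ties
    favour plus).  Equal identities tie-break on target ordinal.
    """
    options = options or SearchOptions()
    if index is None:
        index = build_index(db, options)
    hits = _scan_strand(query, query.sequence, "+", db, index, options)
    if options.strand == "both":
        rc = reverse_complement(query.sequence)
        minus = _scan_strand(query, rc, "-", db, index, options)
        by_target = {h.target_ordinal: h for h in hits}
        for h in minus:
            old = by_target.get(h.target_ordinal)
            if old is None or h.identity > old.identity:
                by_target[h.target_ordinal] = h
        hits = list(by_target.values())
    hits.sort(key=lambda h: (-h.identity, h.target_ordinal))
    if options.maxaccepts:
        hits = hits[: options.maxaccepts]
    if options.top_hits_only and hits:
        best = hits[0].identity
        hits = [h for h in hits if h.identity == best]
    if options.maxhits is not None:
        hits = hits[: options.maxhits]
    return hits


def search_exact(
    query: SequenceRecord, db: Sequence[SequenceRecord], _table_cache: Optional[dict] = None
) -> list[Hit]:
    """Targets whose normalized full-length sequence equals the query's.

    A hash-table lookup, not an alignment; matches report identity 1.0.
    """
    if _table_cache is not None and "table" in _table_cache:
        table = _table_cache["table"]
    else:
        table = {}
        for t, record in enumerate(db):
            table.setdefault(record.normalized, []).append(t)
        if _table_cache is not None:
            _table_cache["table"] = table
    hits = []
    for t in table.get(query.normalized, ()):
        target = db[t]
        result = global_align(query.sequence, target.sequence)
        hits.append(Hit(query.ordinal, t, 1.0, result))
    return hits


def allpairs_global(
    records: Sequence[SequenceRecord], options: Optional[SearchOptions] = None
) -> list[Hit]:
    """All-vs-all optimal alignment (no word-count shortlist, no budgets).

    Every unordered pair is aligned; hits are pairs whose identity reaches
    the threshold, sorted by identity descending.
    """
    if len(records) < 2:
        raise ValueError("allpairs_global needs at least 2 records")
    options = options or SearchOptions()
    hits = []
    for qi in range(len(records)):
        for ti in range(qi + 1, len(records)):
            a, b = records[qi], records[ti]
            result = global_align(a.sequence, b.sequence, options.scoring)
            identity = compute_identity(result, len(a), len(b), options.iddef)
            if identity >= options.id_threshold:
                hits.append(Hit(a.ordinal, b.ordinal, identity, result))
    hits.sort(key=lambda h: (-h.identity, h.query_ordinal, h.target_ordinal))
    return hits
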
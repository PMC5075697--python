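"""Word (k-mer) counting heuristics used to shortlist alignment targets.

A query shares a *word* with a database sequence when both contain the same
k-nucleotide substring (k = 8 by default); multiple occurrences count once.
Shared-word counts order candidates before any alignment is attempted:
more shared words first, shorter sequence first on ties, input order last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "WordIndex",
    "unique_words",
    "count_shared_words",
    "rank_candidates",
    "effective_min_word_matches",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# Posting lists flip to dense bitmaps once a word occurs in more than this
# fraction of targets; purely an internal representation choice.
_BITMAP_FRACTION = 1 / 8


def unique_words(sequence: str, k: int = 8, *, soft_mask: bool = False) -> set[int]:
    """Distinct base-4 codes of all ACGT-only k-mers of ``sequence``.

    Words containing any non-ACGT symbol are skipped.  With ``soft_mask``,
    lowercase (soft-masked) positions are excluded as well, so masked
    low-complexity regions contribute no words.  U counts as T.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sequence)
    if n < k:
        return set()
    mask = (1 << (2 * k)) - 1
    words: set[int] = set()
    code = 0
    run = 0  # valid consecutive symbols ending here
    for ch in sequence:
        if soft_mask and ch.islower():
            run = 0
            continue
        base = _CODE.get(ch.upper())
        if base is None:
            run = 0
            continue
        code = ((code << 2) | base) & mask
        run += 1
        if run >= k:
            words.add(code)
    return words


def effective_min_word_matches(query_words: set[int] | int, configured: int = 10) -> int:
    """Shared-word threshold actually applied to one query.

    Short or simple queries have fewer than ``configured`` unique words, so
    the threshold drops to their unique-word count (floor 1 — with zero
    words no candidate can qualify and the search yields no hits).
    """
    if configured < 1:
        raise ValueError("configured minimum must be >= 1")
    n = query_words if isinstance(query_words, int) else len(query_words)
    return max(1, min(configured, n))


@dataclass
class WordIndex:
    """Inverted index from word code to the targets containing it.

    Postings for very frequent words are stored as dense boolean bitmaps,
    everything else as sorted ordinal lists; the representation never
    affects results.  Targets can be appended incrementally (clustering
    grows its centroid database one sequence at a time).
    """

    k: int = 8
    soft_mask: bool = False
    target_lengths: list[int] = field(default_factory=list)
    _postings: dict[int, list[int]] = field(default_factory=dict)
    _bitmaps: dict[int, np.ndarray] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        targets: Sequence[SequenceRecord | str],
        k: int = 8,
        *,
        soft_mask: bool = False,
    ) -> "WordIndex":
        index = cls(k=k, soft_mask=soft_mask)
        for target in targets:
            index.add(target)
        return index

    @property
    def n_targets(self) -> int:
        return len(self.target_lengths)

    def add(self, target: SequenceRecord | str) -> int:
        """Index one target; returns its ordinal."""
        sequence = target if isinstance(target, str) else target.sequence
        ordinal = len(self.target_lengths)
        self.target_lengths.append(len(sequence))
        for word in unique_words(sequence, self.k, soft_mask=self.soft_mask):
            bitmap = self._bitmaps.get(word)
            if bitmap is not None:
                if ordinal >= bitmap.shape[0]:
                    grown = np.zeros(max(ordinal + 1, 2 * bitmap.shape[0]), dtype=bool)
                    grown[: bitmap.shape[0]] = bitmap
                    bitmap = grown
                    self._bitmaps[word] = bitmap
                bitmap[ordinal] = True
            else:
                posting = self._postings.setdefault(word, [])
                posting.append(ordinal)
                if len(posting) > max(8, int(_BITMAP_FRACTION * (ordinal + 1))):
                    bitmap = np.zeros(ordinal + 1, dtype=bool)
                    bitmap[posting] = True
                    self._bitmaps[word] = bitmap
                    del self._postings[word]
        return ordinal

    def postings(self, word: int) -> list[int]:
        """Sorted target ordinals containing ``word`` (representation-free view)."""
        bitmap = self._bitmaps.get(word)
        if bitmap is not None:
            return [int(t) for t in np.flatnonzero(bitmap) if t < self.n_targets]
        return list(self._postings.get(word, ()))

    def count_shared(self, query_words: Iterable[int]) -> np.ndarray:
        """Per-target count of distinct words shared with the query."""
        counts = np.zeros(self.n_targets, dtype=np.int64)
        for word in query_words:
            bitmap = self._bitmaps.get(word)
            if bitmap is not None:
                view = bitmap[: self.n_targets]
                counts[: view.shape[0]] += view
            else:
                posting = self._postings.get(word)
                if posting:
                    counts[posting] += 1
        return counts


def count_shared_words(query_words: set[int], index: WordIndex) -> np.ndarray:
    return index.count_shared(query_words)


def rank_candidates(
    counts: np.ndarray,
    target_lengths: Sequence[int],
    min_shared: int = 1,
) -> list[int]:
    """Target ordinals with ``count >= min_shared``, most promising first.

    Order: shared-word count descending, then target length ascending, then
    ordinal ascending — a total order independent of index construction.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    counts = np.asarray(counts)
    eligible = np.flatnonzero(counts >= min_shared)
    lengths = np.asarray(target_lengths)
    order = sorted(eligible.tolist(), key=lambda t: (-int(counts[t]), int(lengths[t]), t))
    return order
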
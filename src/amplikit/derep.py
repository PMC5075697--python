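"""Full-length and prefix dereplication, and rereplication.

Dereplication collapses records with identical normalized sequences
(upper case, U as T) into one representative with summed abundance.
Prefix dereplication additionally absorbs any record that is a strict
prefix of another.  Lookups go through a table keyed by an incremental
64-bit FNV-1a hash so all prefixes of a sequence are hashed in linear
total time; hash-equal entries are always verified by full sequence
comparison, so collisions can never merge distinct sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqio import SequenceRecord

__all__ = [
    "FNV1A64_OFFSET_BASIS",
    "FNV1A64_PRIME",
    "fnv1a64",
    "fnv1a64_extend",
    "prefix_hashes",
    "derep_fulllength",
    "derep_prefix",
    "rereplicate",
]

FNV1A64_OFFSET_BASIS = 14695981039346656037
FNV1A64_PRIME = 1099511628211
_MASK64 = (1 << 64) - 1


def fnv1a64_extend(state: int, symbol: str) -> int:
    """Fold one more symbol into a running 64-bit FNV-1a state."""
    return ((state ^ ord(symbol)) * FNV1A64_PRIME) & _MASK64


def fnv1a64(data: str, state: int = FNV1A64_OFFSET_BASIS) -> int:
    for ch in data:
        state = fnv1a64_extend(state, ch)
    return state


def prefix_hashes(sequence: str) -> list[int]:
    """Hashes of all prefixes; entry L is the hash of sequence[:L]."""
    hashes = [FNV1A64_OFFSET_BASIS]
    state = FNV1A64_OFFSET_BASIS
    for ch in sequence:
        state = fnv1a64_extend(state, ch)
        hashes.append(state)
    return hashes


class _HashTable:
    """hash -> bucket of (sequence, payload); equality always verified."""

    def __init__(self):
        self._buckets: dict[int, list] = {}

    def get(self, h: int, sequence: str):
        for entry in self._buckets.get(h, ()):
            if entry[0] == sequence:
                return entry[1]
        return None

    def put(self, h: int, sequence: str, payload) -> None:
        bucket = self._buckets.setdefault(h, [])
        for entry in bucket:
            if entry[0] == sequence:
                entry[1] = payload
                return
        bucket.append([sequence, payload])

    def delete(self, h: int, sequence: str) -> None:
        bucket = self._buckets.get(h, [])
        for idx, entry in enumerate(bucket):
            if entry[0] == sequence:
                del bucket[idx]
                return
        raise KeyError(sequence)

    def values(self):
        for bucket in self._buckets.values():
            for entry in bucket:
                yield entry[1]


@dataclass
class _Rep:
    record: SequenceRecord
    abundance: int
    first_ordinal: int
    alive: bool = True


def _sorted_output(reps: Iterable[_Rep], minuniquesize: int, topn: Optional[int]):
    out = sorted(
        (r for r in reps if r.alive), key=lambda r: (-r.abundance, r.first_ordinal)
    )
    records = [
        rep.record.copy(abundance=rep.abundance)
        for rep in out
        if rep.abundance >= minuniquesize
    ]
    if topn is not None:
        records = records[:topn]
    return records


def derep_fulllength(
    records: Sequence[SequenceRecord],
    *,
    minuniquesize: int = 1,
    topn: Optional[int] = None,
) -> list[SequenceRecord]:
    """One record per distinct normalized sequence, abundance accumulated.

    The representative keeps the first-seen label and original case;
    output is sorted by abundance descending, ties by first occurrence.
    """
    table = _HashTable()
    reps: list[_Rep] = []
    for record in records:
        norm = record.normalized
        h = fnv1a64(norm)
        rep = table.get(h, norm)
        if rep is None:
            rep = _Rep(record, record.abundance, record.ordinal)
            table.put(h, norm, rep)
            reps.append(rep)
        else:
            rep.abundance += record.abundance
    return _sorted_output(reps, minuniquesize, topn)


def derep_prefix(
    records: Sequence[SequenceRecord],
    *,
    minuniquesize: int = 1,
    topn: Optional[int] = None,
) -> list[SequenceRecord]:
    """Collapse identical sequences and strict-prefix containments.

    Records are processed shortest first.  Each record first looks up its
    full sequence (joining an identical entry), then successively shorter
    prefixes down to the length of the shortest input; a prefix match
    absorbs the matched entry, which is replaced in the table by the
    longer sequence with the summed abundance.  A short sequence that is
    a prefix of several longer ones therefore ends up with the shortest
    of them, then the most abundant, the lexicographically smaller label,
    and the earliest input position — enforced here by the processing
    order within each length class.
    """
    if not records:
        return []
    order = sorted(
        records,
        key=lambda r: (len(r.sequence), -r.abundance, r.label, r.ordinal),
    )
    shortest = len(order[0].sequence)
    table = _HashTable()
    reps: list[_Rep] = []
    for record in order:
        norm = record.normalized
        hashes = prefix_hashes(norm)
        full = table.get(hashes[len(norm)], norm)
        if full is not None:
            full.abundance += record.abundance
            continue
        absorbed = None
        for plen in range(len(norm) - 1, shortest - 1, -1):
            prefix = norm[:plen]
            entry = table.get(hashes[plen], prefix)
            if entry is not None:
                absorbed = (hashes[plen], prefix, entry)
                break
        rep = _Rep(record, record.abundance, record.ordinal)
        if absorbed is not None:
            h, prefix, entry = absorbed
            rep.abundance += entry.abundance
            rep.first_ordinal = min(rep.first_ordinal, entry.first_ordinal)
            table.delete(h, prefix)
            entry.alive = False
        table.put(hashes[len(norm)], norm, rep)
        reps.append(rep)
    return _sorted_output(reps, minuniquesize, topn)


def rereplicate(records: Sequence[SequenceRecord], label_prefix: str = "seq") -> list[SequenceRecord]:
    """Expand each record of abundance n into n records of abundance 1.

    Original read labels cannot be reconstructed; output labels are
    ``<prefix><running number>`` starting at 1.
    """
    out: list[SequenceRecord] = []
    counter = 0
    for record in records:
        for _ in range(record.abundance):
            counter += 1
            out.append(
                record.copy(
                    label=f"{label_prefix}{counter}",
                    description="",
                    abundance=1,
                    ordinal=counter - 1,
                )
            )
    return out
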
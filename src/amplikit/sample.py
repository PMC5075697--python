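"""Sorting, seeded shuffling and abundance-aware subsampling.

Randomness comes from numpy's PCG64 generator, a named, platform-stable
algorithm, so a ``randseed`` reproduces results everywhere.  Abundance-
aware subsampling draws reads without replacement: conceptually the input
is rereplicated into individual reads, a uniform subsample is taken and
the result dereplicated again.  That is simulated amplicon by amplicon
with sequential hypergeometric draws, so each amplicon's output abundance
follows the exact multivariate hypergeometric marginal without ever
materialising the expanded read multiset.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = ["random_state", "sort_records", "shuffle", "subsample"]


def random_state(seed: Optional[int] = None) -> np.random.Generator:
    """A PCG64 generator; ``seed`` None or 0 draws entropy from the OS."""
    if not seed:
        return np.random.default_rng()
    return np.random.default_rng(seed)


def sort_records(
    records: Sequence[SequenceRecord],
    key: str = "length",
    *,
    minsize: int = 1,
    maxsize: Optional[int] = None,
    topn: Optional[int] = None,
) -> list[SequenceRecord]:
    """Stable sort by decreasing length or abundance; ties keep input order."""
    if key == "length":
        keyfun = lambda r: -len(r.sequence)
    elif key == "size":
        keyfun = lambda r: -r.abundance
    else:
        raise ValueError("key must be 'length' or 'size'")
    out = [
        r
        for r in records
        if r.abundance >= minsize and (maxsize is None or r.abundance <= maxsize)
    ]
    out = sorted(out, key=lambda r: (keyfun(r), r.ordinal))
    if topn is not None:
        out = out[:topn]
    return out


def shuffle(
    records: Sequence[SequenceRecord], state: Optional[np.random.Generator] = None
) -> list[SequenceRecord]:
    """Uniform random permutation (Fisher–Yates via the generator)."""
    state = state or random_state()
    order = state.permutation(len(records))
    return [records[i] for i in order]


def subsample(
    records: Sequence[SequenceRecord],
    size: Optional[int] = None,
    pct: Optional[float] = None,
    *,
    sizein: bool = False,
    state: Optional[np.random.Generator] = None,
) -> list[SequenceRecord]:
    """Random subsample of ``size`` units or ``pct`` percent of them.

    Units are reads when ``sizein`` is set (each record counts
    ``abundance`` times; output abundances are multivariate-hypergeometric
    and records drawn to zero are dropped) and records otherwise.
    ``pct`` is converted to a unit count by rounding half up.
    """
    state = state or random_state()
    if (size is None) == (pct is None):
        raise ValueError("specify exactly one of size and pct")
    total = sum(r.abundance for r in records) if sizein else len(records)
    if pct is not None:
        if not 0 <= pct <= 100:
            raise ValueError("pct must be within [0, 100]")
        size = int(pct / 100.0 * total + 0.5)
    if size > total:
        raise ValueError(f"sample size {size} exceeds {total} available units")
    if sizein:
        remaining_total = total
        remaining_draw = size
        out = []
        for record in records:
            a = record.abundance
            if remaining_draw == 0:
                break
            drawn = int(
                state.hypergeometric(a, remaining_total - a, remaining_draw)
            ) if remaining_total > a else remaining_draw
            remaining_total -= a
            remaining_draw -= drawn
            if drawn > 0:
                out.append(record.copy(abundance=drawn))
        return out
    chosen = sorted(state.choice(len(records), size=size, replace=False).tolist())
    return [records[i] for i in chosen]
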
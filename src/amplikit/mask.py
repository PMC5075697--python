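"""Low-complexity masking with the DUST triplet-score algorithm.

A sliding window (64 bases, step 32) is scanned; within a window every
subinterval is scored as sum(c_t * (c_t - 1) / 2) over its triplet counts
c_t, divided by one less than its number of triplets.  The best-scoring
subinterval is masked when 10 * score exceeds the level (20 by default).
Soft masking lowercases the masked stretch — lossless, and the word
indexer skips lowercase — while hard masking substitutes N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["MaskInterval", "dust_mask", "apply_mask", "dust_mask_sequence"]

_TRIPLET_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

DEFAULT_WINDOW = 64
DEFAULT_STEP = 32
DEFAULT_LEVEL = 20


@dataclass(frozen=True)
class MaskInterval:
    """0-based half-open masked span on the unmasked sequence."""

    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


def _triplet_codes(sequence: str) -> list:
    """Per-position triplet code, or None where the triplet has non-ACGT."""
    upper = sequence.upper()
    codes = []
    for i in range(len(upper) - 2):
        try:
            codes.append(
                16 * _TRIPLET_CODE[upper[i]]
                + 4 * _TRIPLET_CODE[upper[i + 1]]
                + _TRIPLET_CODE[upper[i + 2]]
            )
        except KeyError:
            codes.append(None)
    return codes


def dust_mask(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    level: int = DEFAULT_LEVEL,
    step: int = DEFAULT_STEP,
) -> list[MaskInterval]:
    """Low-complexity intervals of ``sequence`` (sorted, non-overlapping).

    Triplets containing non-ACGT symbols are skipped.  Overlapping or
    adjacent masked spans from successive windows are merged.
    """
    if level <= 0:
        raise ValueError("level must be > 0")
    n = len(sequence)
    if n < 3:
        return []
    triplets = _triplet_codes(sequence)
    raw: list[tuple[int, int]] = []
    start = 0
    while True:
        wend = min(start + window, n)
        tcodes = triplets[start : max(start, wend - 2)]
        best = _best_subinterval(tcodes, level)
        if best is not None:
            ts, te = best  # triplet index range, inclusive
            raw.append((start + ts, start + te + 3))
        if wend >= n:
            break
        start += step
    return _merge(raw)


def _best_subinterval(tcodes: Sequence, level: int):
    """Maximal-scoring triplet run [s, e] with 10*score > level, else None."""
    best_score = 0.0
    best = None
    n = len(tcodes)
    for s in range(n):
        counts: dict[int, int] = {}
        pairs = 0  # sum of c*(c-1)/2
        length = 0
        for e in range(s, n):
            code = tcodes[e]
            if code is None:
                break
            prev = counts.get(code, 0)
            pairs += prev
            counts[code] = prev + 1
            length += 1
            if length > 1:
                score = pairs / (length - 1)
                if 10 * score > level and score > best_score:
                    best_score = score
                    best = (s, e)
    return best


def _merge(spans: Iterable[tuple[int, int]]) -> list[MaskInterval]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [MaskInterval(s, e) for s, e in merged]


def apply_mask(sequence: str, intervals: Iterable[MaskInterval], mode: str = "soft") -> str:
    """Lowercase (``soft``) or replace with N (``hard``) within intervals."""
    if mode not in ("soft", "hard"):
        raise ValueError("mode must be 'soft' or 'hard'")
    chars = list(sequence)
    for iv in intervals:
        if iv.end > len(chars):
            raise ValueError(f"interval {iv} beyond sequence length {len(chars)}")
        for p in range(iv.start, iv.end):
            chars[p] = chars[p].lower() if mode == "soft" else "N"
    return "".join(chars)


def dust_mask_sequence(sequence: str, hard: bool = False) -> str:
    """Convenience: DUST with defaults applied to a fresh uppercase copy."""
    intervals = dust_mask(sequence)
    return apply_mask(sequence.upper(), intervals, "hard" if hard else "soft")
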
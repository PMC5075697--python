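"""FASTQ inspection, statistics, filtering and encoding conversion."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .seqio import ParseError, SequenceRecord

__all__ = [
    "fastq_chars",
    "expected_errors",
    "FilterOptions",
    "fastq_filter",
    "fastq_convert",
    "fastq_stats",
    "fastq_eestats",
]


def fastq_chars(records: Sequence[SequenceRecord], quality_offset: int = 33) -> dict:
    """Inspect the quality-character range and guess the Phred offset.

    Any character code below 59 forces Phred+33 (Phred+64 would imply a
    negative score).  Codes reaching 75 or more with none below 64
    indicate Phred+64 (Phred+33 would imply scores above 41).  A range
    confined to [59, 75) is consistent with both encodings: it is
    reported as ambiguous, guessed as 33, with both interpretations
    listed.  Also reports, per final quality character, how long the
    constant run at the 3' end of a read tends to be (a crude
    fingerprint of trailing-quality conventions).
    """
    min_code = None
    max_code = None
    tail_lengths: dict[str, list[int]] = {}
    n_bases = 0
    for record in records:
        if record.qualities is None:
            raise ParseError(f"record {record.label!r} has no qualities: not FASTQ")
        codes = [q + quality_offset for q in record.qualities]
        n_bases += len(codes)
        for c in codes:
            if min_code is None or c < min_code:
                min_code = c
            if max_code is None or c > max_code:
                max_code = c
        if codes:
            last = codes[-1]
            run = 0
            for c in reversed(codes):
                if c != last:
                    break
                run += 1
            tail_lengths.setdefault(chr(last), []).append(run)
    if min_code is None or n_bases == 0:
        raise ParseError("no quality characters found: not FASTQ")
    if min_code < 59:
        guess, ambiguous = 33, False
    elif min_code >= 64 and max_code >= 75:
        guess, ambiguous = 64, False
    else:
        guess, ambiguous = 33, True
    report = {
        "min_char": chr(min_code),
        "max_char": chr(max_code),
        "guessed_offset": guess,
        "ambiguous": ambiguous,
        "interpretations": [33, 64] if ambiguous else [guess],
        "tail_stats": {
            ch: {
                "count": len(runs),
                "max_run": max(runs),
                "mean_run": sum(runs) / len(runs),
            }
            for ch, runs in sorted(tail_lengths.items())
        },
    }
    return report


def expected_errors(qualities: Sequence[int]) -> float:
    """EE = sum of per-base error probabilities 10^(-q/10)."""
    return float(sum(10.0 ** (-q / 10.0) for q in qualities))


@dataclass(frozen=True)
class FilterOptions:
    """Truncation and filtering criteria, applied in a fixed order:

    strip left/right -> truncate at the first low-quality base
    (``truncqual``) -> truncate to ``trunclen`` (discarding shorter
    reads) -> length window -> N count -> expected errors (absolute and
    per-base), all computed on the read as truncated.
    """

    stripleft: int = 0
    stripright: int = 0
    truncqual: Optional[int] = None
    trunclen: Optional[int] = None
    minlen: int = 1
    maxlen: Optional[int] = None
    maxns: Optional[int] = None
    maxee: Optional[float] = None
    maxee_rate: Optional[float] = None


def fastq_filter(
    records: Sequence[SequenceRecord], options: Optional[FilterOptions] = None
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (kept, discarded) under the filter options."""
    options = options or FilterOptions()
    kept: list[SequenceRecord] = []
    discarded: list[SequenceRecord] = []
    for record in records:
        seq = record.sequence
        quals = record.qualities
        start = options.stripleft
        end = len(seq) - options.stripright
        if start >= end:
            discarded.append(record)
            continue
        seq = seq[start:end]
        quals = None if quals is None else quals[start:end]
        if options.truncqual is not None and quals is not None:
            for pos, q in enumerate(quals):
                if q < options.truncqual:
                    seq, quals = seq[:pos], quals[:pos]
                    break
        if options.trunclen is not None:
            if len(seq) < options.trunclen:
                discarded.append(record)
                continue
            seq = seq[: options.trunclen]
            quals = None if quals is None else quals[: options.trunclen]
        if len(seq) < options.minlen or (
            options.maxlen is not None and len(seq) > options.maxlen
        ):
            discarded.append(record)
            continue
        if options.maxns is not None and seq.upper().count("N") > options.maxns:
            discarded.append(record)
            continue
        if quals is not None and (options.maxee is not None or options.maxee_rate is not None):
            ee = expected_errors(quals)
            if options.maxee is not None and ee > options.maxee:
                discarded.append(record)
                continue
            if options.maxee_rate is not None and len(seq) and ee / len(seq) > options.maxee_rate:
                discarded.append(record)
                continue
        kept.append(record.copy(sequence=seq, qualities=quals))
    return kept, discarded


def fastq_convert(
    records: Sequence[SequenceRecord],
    qmin_out: int = 0,
    qmax_out: int = 41,
) -> list[SequenceRecord]:
    """Clamp quality values into [qmin_out, qmax_out].

    Records hold offset-free Phred scores, so converting between
    encodings is a matter of re-writing with another offset
    (``seqio.write_fastq``); this step applies the output clamp.
    """
    out = []
    for record in records:
        if record.qualities is None:
            raise ParseError(f"record {record.label!r} has no qualities")
        quals = [min(max(q, qmin_out), qmax_out) for q in record.qualities]
        out.append(record.copy(qualities=quals))
    return out


def _quartiles(values: list[int]) -> tuple[float, float, float]:
    ordered = sorted(values)
    n = len(ordered)

    def pick(frac: float) -> float:
        if n == 1:
            return float(ordered[0])
        pos = frac * (n - 1)
        lo = int(pos)
        hi = min(lo + 1, n - 1)
        return ordered[lo] + (pos - lo) * (ordered[hi] - ordered[lo])

    return pick(0.25), pick(0.5), pick(0.75)


def fastq_stats(records: Sequence[SequenceRecord]) -> list[dict]:
    """Per-position quality table: count, min/quartiles/max, mean EE.

    One row per read position (1-based); the exact column set is this
    package's own format.
    """
    columns: list[list[int]] = []
    for record in records:
        if record.qualities is None:
            raise ParseError(f"record {record.label!r} has no qualities")
        for pos, q in enumerate(record.qualities):
            if pos >= len(columns):
                columns.append([])
            columns[pos].append(q)
    rows = []
    for pos, quals in enumerate(columns):
        q1, med, q3 = _quartiles(quals)
        rows.append(
            {
                "position": pos + 1,
                "count": len(quals),
                "min": min(quals),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": max(quals),
                "mean_error_prob": sum(10.0 ** (-q / 10.0) for q in quals) / len(quals),
            }
        )
    return rows


def fastq_eestats(records: Sequence[SequenceRecord]) -> list[dict]:
    """Expected-errors-vs-truncation-length table (quartiles per length)."""
    ee_by_len: list[list[float]] = []
    for record in records:
        if record.qualities is None:
            raise ParseError(f"record {record.label!r} has no qualities")
        running = 0.0
        for pos, q in enumerate(record.qualities):
            running += 10.0 ** (-q / 10.0)
            if pos >= len(ee_by_len):
                ee_by_len.append([])
            ee_by_len[pos].append(running)
    rows = []
    for pos, values in enumerate(ee_by_len):
        q1, med, q3 = _quartiles([round(v, 6) for v in values])
        rows.append(
            {
                "length": pos + 1,
                "count": len(values),
                "ee_q1": q1,
                "ee_median": med,
                "ee_q3": q3,
                "ee_mean": sum(values) / len(values),
            }
        )
    return rows
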
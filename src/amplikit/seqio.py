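"""Reading and writing FASTA/FASTQ with abundance annotations.

Both formats are auto-detected from the first byte (``>`` vs ``@``) and may
arrive gzip-compressed; the gzip magic is sniffed and decompression is
transparent.  Records carry an abundance (the ``;size=N`` annotation used
throughout amplicon pipelines), the 0-based position in the input stream,
and, for FASTQ, per-base Phred scores.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "SequenceRecord",
    "ParseError",
    "read_sequences",
    "parse_abundance",
    "strip_abundance",
    "annotate_abundance",
    "write_fasta",
    "write_fastq",
    "relabel_digest",
    "reverse_complement",
    "normalize_sequence",
]

_GZIP_MAGIC = b"\x1f\x8b"

# IUPAC nucleotide complement (case handled separately)
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)
_IUPAC_SET = frozenset("ACGTURYSWKMBVDHNacgturyswkmbvdhn")

_NORM_TABLE = str.maketrans(
    "acgtunbdhvrykmswU", "ACGTTNBDHVRYKMSWT"
)

_SIZE_RE = re.compile(r";size=(\d+);?")


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input or bad annotations."""


@dataclass
class SequenceRecord:
    """One nucleotide sequence with label, qualities and abundance.

    ``label`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder.  ``qualities`` is ``None`` for FASTA
    records and a list of Phred scores (one per base) for FASTQ.
    ``abundance`` defaults to 1 and is never below 1.  ``ordinal`` is the
    0-based position of the record in its input stream.
    """

    label: str
    sequence: str
    description: str = ""
    qualities: Optional[list[int]] = None
    abundance: int = 1
    ordinal: int = 0

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ParseError(
                f"record {self.label!r}: abundance must be >= 1, got {self.abundance}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ParseError(
                f"record {self.label!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def normalized(self) -> str:
        """Sequence upper-cased with U converted to T (comparison form)."""
        return normalize_sequence(self.sequence)

    def copy(self, **changes) -> "SequenceRecord":
        return replace(self, **changes)


def normalize_sequence(sequence: str) -> str:
    """Upper-case and convert U to T; the form used for all comparisons."""
    return sequence.translate(_NORM_TABLE)


# ---------------------------------------------------------------------------
# reading


def _open_bytes(source) -> io.BufferedReader:
    if isinstance(source, (str, Path)):
        handle = open(source, "rb")
    elif isinstance(source, (bytes, bytearray)):
        handle = io.BytesIO(bytes(source))
    else:
        handle = source
    if hasattr(handle, "peek"):
        head = handle.peek(2)[:2]
    elif handle.seekable():
        pos = handle.tell()
        head = handle.read(2)
        handle.seek(pos)
    else:
        head = b""
    if head == _GZIP_MAGIC:
        return gzip.open(handle, "rb")  # type: ignore[return-value]
    return handle


def _split_header(line: str) -> tuple[str, str]:
    parts = line.split(None, 1)
    if not parts:
        raise ParseError("empty header line")
    label = parts[0]
    description = parts[1] if len(parts) > 1 else ""
    return label, description


def read_sequences(
    source,
    format_hint: str = "auto",
    *,
    sizein: bool = False,
    quality_offset: int = 33,
) -> list[SequenceRecord]:
    """Parse a FASTA or FASTQ source into records in file order.

    ``source`` may be a path, raw bytes, or a binary file object; gzip
    input is decompressed transparently.  With ``sizein`` the ``;size=N``
    annotation is parsed into ``abundance`` and stripped from the label.
    FASTQ quality characters are converted to Phred scores using
    ``quality_offset`` (33 by default, 64 for legacy Illumina).
    """
    stream = _open_bytes(source)
    text = io.TextIOWrapper(stream, encoding="ascii")
    first = text.read(1)
    if not first:
        raise ParseError("empty input")
    if format_hint == "auto":
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ParseError(
                f"unrecognised leading character {first!r}: not FASTA or FASTQ"
            )
    else:
        fmt = format_hint
    records = []
    if fmt == "fasta":
        parser = _parse_fasta(first, text)
    else:
        parser = _parse_fastq(first, text, quality_offset)
    for ordinal, (label, description, sequence, qualities) in enumerate(parser):
        abundance = 1
        if sizein:
            label, abundance = parse_abundance(label, sizein=True)
        records.append(
            SequenceRecord(
                label=label,
                description=description,
                sequence=sequence,
                qualities=qualities,
                abundance=abundance,
                ordinal=ordinal,
            )
        )
    return records


def _parse_fasta(first: str, text: io.TextIOWrapper) -> Iterator[tuple]:
    if first != ">":
        raise ParseError("FASTA input must start with '>'")
    header = text.readline().rstrip("\n")
    while True:
        label, description = _split_header(header)
        chunks = []
        line = text.readline()
        while line and not line.startswith(">"):
            chunks.append(line.strip())
            line = text.readline()
        sequence = "".join(chunks)
        _check_alphabet(label, sequence)
        yield label, description, sequence, None
        if not line:
            return
        header = line[1:].rstrip("\n")


def _parse_fastq(first: str, text: io.TextIOWrapper, offset: int) -> Iterator[tuple]:
    if first != "@":
        raise ParseError("FASTQ input must start with '@'")
    header = text.readline().rstrip("\n")
    while True:
        label, description = _split_header(header)
        sequence = text.readline().rstrip("\n")
        plus = text.readline()
        if not plus.startswith("+"):
            raise ParseError(f"record {label!r}: expected '+' separator line")
        qual_line = text.readline().rstrip("\n")
        if len(qual_line) != len(sequence):
            raise ParseError(
                f"record {label!r}: sequence and quality lengths differ "
                f"({len(sequence)} vs {len(qual_line)})"
            )
        _check_alphabet(label, sequence)
        qualities = [ord(c) - offset for c in qual_line]
        if any(q < 0 for q in qualities):
            raise ParseError(
                f"record {label!r}: quality character below offset {offset}"
            )
        yield label, description, sequence, qualities
        line = text.readline()
        if not line:
            return
        if not line.startswith("@"):
            raise ParseError(f"after record {label!r}: expected '@', got {line[:1]!r}")
        header = line[1:].rstrip("\n")


def _check_alphabet(label: str, sequence: str) -> None:
    bad = set(sequence) - _IUPAC_SET
    if bad:
        raise ParseError(
            f"record {label!r}: non-IUPAC symbol(s) {sorted(bad)!r}"
        )


# ---------------------------------------------------------------------------
# abundance annotations


def parse_abundance(header: str, sizein: bool = True) -> tuple[str, int]:
    """Extract a ``;size=N`` annotation from a label.

    Returns the label with the annotation removed and the abundance.  When
    ``sizein`` is off the annotation is left in place and abundance is 1.
    """
    if not sizein:
        return header, 1
    match = _SIZE_RE.search(header)
    if match is None:
        if "size=" in header:
            raise ParseError(f"malformed abundance annotation in {header!r}")
        return header, 1
    abundance = int(match.group(1))
    if abundance < 1:
        raise ParseError(f"abundance annotation size={abundance} in {header!r}: must be >= 1")
    clean = header[: match.start()] + header[match.end():]
    clean = clean.rstrip(";")
    return clean, abundance


def strip_abundance(header: str) -> str:
    return parse_abundance(header, sizein=True)[0]


def annotate_abundance(label: str, abundance: int) -> str:
    """Append ``;size=N;`` to a label (existing annotation replaced)."""
    clean, _ = parse_abundance(label, sizein=True)
    return f"{clean};size={abundance};"


# ---------------------------------------------------------------------------
# writing


def _format_label(record: SequenceRecord, sizeout: bool, keep_description: bool) -> str:
    label = annotate_abundance(record.label, record.abundance) if sizeout else record.label
    if keep_description and record.description:
        return f"{label} {record.description}"
    return label


def write_fasta(
    records: Iterable[SequenceRecord],
    handle=None,
    *,
    width: int = 80,
    sizeout: bool = False,
    keep_description: bool = True,
) -> Optional[bytes]:
    """Write records as FASTA; ``width`` 0 turns line wrapping off.

    With no ``handle`` the serialised bytes are returned.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    out = io.BytesIO() if handle is None else handle
    for record in records:
        header = _format_label(record, sizeout, keep_description)
        out.write(f">{header}\n".encode("ascii"))
        seq = record.sequence
        if width == 0 or not seq:
            out.write(seq.encode("ascii") + b"\n")
        else:
            for start in range(0, len(seq), width):
                out.write(seq[start : start + width].encode("ascii") + b"\n")
    if handle is None:
        return out.getvalue()
    return None


def write_fastq(
    records: Iterable[SequenceRecord],
    handle=None,
    *,
    quality_offset: int = 33,
    sizeout: bool = False,
    keep_description: bool = True,
) -> Optional[bytes]:
    """Write records as FASTQ (4 lines per record, no wrapping)."""
    out = io.BytesIO() if handle is None else handle
    for record in records:
        if record.qualities is None:
            raise ValueError(f"record {record.label!r} has no qualities; cannot write FASTQ")
        header = _format_label(record, sizeout, keep_description)
        qual = "".join(chr(q + quality_offset) for q in record.qualities)
        out.write(
            f"@{header}\n{record.sequence}\n+\n{qual}\n".encode("ascii")
        )
    if handle is None:
        return out.getvalue()
    return None


# ---------------------------------------------------------------------------
# relabelling and reverse complement


def relabel_digest(record: SequenceRecord, algorithm: str = "sha1") -> str:
    """Hex digest of the normalized sequence (U->T, upper case).

    SHA-1 gives a 40-character label, MD5 a 32-character one; records with
    the same comparison-form sequence always receive the same label.
    """
    if not record.sequence:
        raise ValueError("cannot digest an empty sequence")
    data = record.normalized.encode("ascii")
    if algorithm == "sha1":
        return hashlib.sha1(data).hexdigest()
    if algorithm == "md5":
        return hashlib.md5(data).hexdigest()
    raise ValueError(f"unknown digest algorithm {algorithm!r}")


def reverse_complement(record_or_sequence):
    """IUPAC-aware reverse complement; qualities are reversed in step."""
    if isinstance(record_or_sequence, str):
        _check_alphabet("<sequence>", record_or_sequence)
        return record_or_sequence.translate(_COMP_TABLE)[::-1]
    record = record_or_sequence
    _check_alphabet(record.label, record.sequence)
    return record.copy(
        sequence=record.sequence.translate(_COMP_TABLE)[::-1],
        qualities=None if record.qualities is None else record.qualities[::-1],
    )
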
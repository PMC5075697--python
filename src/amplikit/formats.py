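"""Tabular result writers: uc, blast6 and simple pairwise alignment text.

The uc format is the 10-column interoperability surface shared by the
USEARCH-family tools: record type S (cluster seed), H (hit), C (cluster
summary) or N (no hit), cluster number, length or cluster size, percent
identity, strand, two unused columns, a compressed alignment (CIGAR or
``*``), query label and target label.
"""

from __future__ import annotations

import io
from typing import Sequence

from .align import AlignmentResult
from .cluster import Cluster
from .search import Hit
from .seqio import SequenceRecord

__all__ = ["uc_search_lines", "uc_cluster_lines", "blast6_lines", "render_alignment"]


def _uc_row(
    rtype: str,
    cluster_no: int,
    size_or_len,
    identity,
    strand: str,
    cigar: str,
    query: str,
    target: str,
) -> str:
    ident = "*" if identity is None else f"{100.0 * identity:.1f}"
    return "\t".join(
        [rtype, str(cluster_no), str(size_or_len), ident, strand, "*", "*",
         cigar, query, target]
    )


def uc_search_lines(
    queries: Sequence[SequenceRecord], hits_per_query: Sequence[list[Hit]],
    db: Sequence[SequenceRecord],
) -> list[str]:
    """H records for each hit, N records for queries with none."""
    lines = []
    for query, hits in zip(queries, hits_per_query):
        if not hits:
            lines.append(_uc_row("N", -1, len(query), None, "*", "*", query.label, "*"))
            continue
        for hit in hits:
            lines.append(
                _uc_row("H", hit.target_ordinal, len(query), hit.identity,
                        hit.strand, hit.alignment.cigar, query.label,
                        db[hit.target_ordinal].label)
            )
    return lines


def uc_cluster_lines(clusters: Sequence[Cluster]) -> list[str]:
    """S and H records per cluster, then C summaries."""
    lines = []
    for number, clust in enumerate(clusters):
        lines.append(
            _uc_row("S", number, len(clust.centroid), None, "*", "*",
                    clust.centroid.label, "*")
        )
        for member, hit in clust.members:
            lines.append(
                _uc_row("H", number, len(member), hit.identity, hit.strand,
                        hit.alignment.cigar, member.label, clust.centroid.label)
            )
    for number, clust in enumerate(clusters):
        lines.append(
            _uc_row("C", number, clust.size, None, "*", "*",
                    clust.centroid.label, "*")
        )
    return lines


def blast6_lines(
    queries: Sequence[SequenceRecord], hits_per_query: Sequence[list[Hit]],
    db: Sequence[SequenceRecord],
) -> list[str]:
    """12-column blast6 rows (no E-value statistics for global alignment:
    the e-value and bit-score columns are written as -1 and 0)."""
    lines = []
    for query, hits in zip(queries, hits_per_query):
        for hit in hits:
            aln = hit.alignment
            # 1-based coordinates of the aligned (non terminal gap) region
            qlo, qhi, tlo, thi = _aligned_span(aln, len(query))
            lines.append(
                "\t".join(
                    [
                        query.label, db[hit.target_ordinal].label,
                        f"{100.0 * hit.identity:.1f}", str(aln.columns),
                        str(aln.mismatches), str(aln.internal_gap_runs),
                        str(qlo), str(qhi), str(tlo), str(thi), "-1", "0",
                    ]
                )
            )
    return lines


def _aligned_span(aln: AlignmentResult, qlen: int) -> tuple[int, int, int, int]:
    from ._kernels import MOVE_DIAG, MOVE_E

    i = j = 0
    qlo = qhi = tlo = thi = None
    for mv in aln.moves:
        if mv == MOVE_DIAG:
            if qlo is None:
                qlo, tlo = i + 1, j + 1
            qhi, thi = i + 1, j + 1
            i += 1
            j += 1
        elif mv == MOVE_E:
            j += 1
        else:
            i += 1
    if qlo is None:
        return 0, 0, 0, 0
    return qlo, qhi, tlo, thi


def render_alignment(
    query: SequenceRecord,
    target: SequenceRecord,
    result: AlignmentResult,
    width: int = 60,
) -> str:
    """Human-readable pairwise alignment block for alnout."""
    qrow, trow = result.aligned_strings(query.sequence, target.sequence)
    marks = "".join(
        "|" if qc.upper() == tc.upper() and qc != "-" else " "
        for qc, tc in zip(qrow, trow)
    )
    out = io.StringIO()
    out.write(f"Query >{query.label} ({len(query)} nt)\n")
    out.write(f"Target >{target.label} ({len(target)} nt)\n\n")
    for start in range(0, len(qrow), width):
        out.write(f"Qry {qrow[start:start + width]}\n")
        out.write(f"    {marks[start:start + width]}\n")
        out.write(f"Tgt {trow[start:start + width]}\n\n")
    out.write(
        f"{result.columns} cols, {result.matches} ids "
        f"({100.0 * result.matches / max(1, result.columns):.1f}%), "
        f"{result.internal_gap_columns + result.terminal_gap_columns} gaps\n"
    )
    return out.getvalue()
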
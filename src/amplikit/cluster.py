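"""Greedy centroid-based de novo clustering (OTU picking).

Sequences are processed in a chosen order — user-supplied (``smallmem``),
length descending (``fast``) or abundance descending (``size``) — and each
is searched against the centroids collected so far.  A query joins the
accepted centroid of highest identity (distance-based greedy clustering,
DGC) or, with ``sizeorder``, the most abundant accepted centroid
(abundance-based, AGC); with no acceptance it founds a new cluster.  The
outcome therefore depends on the input order and on the search budgets
(``maxaccepts``/``maxrejects``), exactly like the tools this command set
interoperates with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .align import global_align
from .kmer import WordIndex
from .search import Hit, SearchOptions, apply_query_mask, usearch_global
from .seqio import SequenceRecord

__all__ = ["Cluster", "cluster_records", "center_star_msa", "consensus_sequence"]


@dataclass
class Cluster:
    centroid: SequenceRecord
    members: list[tuple[SequenceRecord, Hit]] = field(default_factory=list)

    @property
    def total_abundance(self) -> int:
        return self.centroid.abundance + sum(m.abundance for m, _ in self.members)

    @property
    def size(self) -> int:
        return 1 + len(self.members)

    def records(self) -> list[SequenceRecord]:
        return [self.centroid] + [m for m, _ in self.members]


def _sort_records(records: Sequence[SequenceRecord], mode: str) -> list[SequenceRecord]:
    if mode == "smallmem":
        return list(records)
    if mode == "fast":
        return sorted(records, key=lambda r: (-len(r.sequence), -r.abundance, r.ordinal))
    if mode == "size":
        return sorted(records, key=lambda r: (-r.abundance, -len(r.sequence), r.ordinal))
    raise ValueError(f"unknown clustering mode {mode!r}")


def cluster_records(
    records: Sequence[SequenceRecord],
    mode: str = "smallmem",
    options: Optional[SearchOptions] = None,
    *,
    sizeorder: bool = False,
    threads: int = 1,
) -> list[Cluster]:
    """Greedy centroid clustering of ``records`` at the options' identity.

    ``threads`` is accepted for interface compatibility; processing is
    sequential and the result is identical for any value, which is the
    determinism contract callers rely on.
    """
    del threads  # results are thread-count invariant by construction
    options = options or SearchOptions(id_threshold=0.97)
    ordered = _sort_records(records, mode)
    clusters: list[Cluster] = []
    centroid_db: list[SequenceRecord] = []
    index = WordIndex(k=options.wordlength, soft_mask=True)
    for record in ordered:
        hits = usearch_global(record, centroid_db, index, options)
        if hits:
            if sizeorder:
                # AGC: most abundant accepted centroid; ties by identity
                # then centroid creation order
                best = max(
                    hits,
                    key=lambda h: (
                        centroid_db[h.target_ordinal].abundance,
                        h.identity,
                        -h.target_ordinal,
                    ),
                )
            else:
                # DGC: hits arrive sorted by identity desc, ordinal asc
                best = hits[0]
            clusters[best.target_ordinal].members.append((record, best))
        else:
            clusters.append(Cluster(centroid=record))
            centroid_db.append(record)
            index.add(apply_query_mask(record.sequence, options.dbmask))
    return clusters


def center_star_msa(clust: Cluster) -> tuple[list[str], str, list[dict]]:
    """Multiple alignment of a cluster by the center-star method.

    Each member's pairwise alignment to the centroid is merged on centroid
    coordinates ("once a gap, always a gap"): the insertion length kept
    between two centroid positions is the longest insertion any member
    made there.  Returns (rows, consensus, profile); rows are ordered
    centroid first, then members; the consensus keeps gap columns (the
    caller may strip them), choosing per column the abundance-weighted
    most frequent symbol with ties broken by the fixed order A<C<G<T and
    any nucleotide preferred over a gap.
    """
    members = []
    for record, hit in clust.members:
        aln = hit.alignment
        if aln is None:
            aln = global_align(record.sequence, clust.centroid.sequence)
        members.append((record, aln))

    centroid_seq = clust.centroid.sequence
    c_len = len(centroid_seq)
    # ins[k]: columns inserted before centroid position k (k = 0..c_len)
    ins = [0] * (c_len + 1)
    layouts = []
    for record, aln in members:
        rows = aln.aligned_strings(record.sequence, centroid_seq)
        layouts.append(rows)
        run = 0
        k = 0
        for qc, cc in zip(*rows):
            if cc == "-":
                run += 1
            else:
                ins[k] = max(ins[k], run)
                run = 0
                k += 1
        ins[c_len] = max(ins[c_len], run)

    def lay_out(member_row: Optional[str], centroid_row: Optional[str]) -> str:
        # place one sequence on the master coordinate system
        out = []
        if member_row is None:  # the centroid itself
            for k in range(c_len + 1):
                out.append("-" * ins[k])
                if k < c_len:
                    out.append(centroid_seq[k])
            return "".join(out)
        k = 0
        pending = []
        for qc, cc in zip(member_row, centroid_row):
            if cc == "-":
                pending.append(qc)
            else:
                out.append("-" * (ins[k] - len(pending)) + "".join(pending))
                pending = []
                out.append(qc)
                k += 1
        out.append("-" * (ins[c_len] - len(pending)) + "".join(pending))
        return "".join(out)

    rows = [lay_out(None, None)]
    for member_row, centroid_row in layouts:
        rows.append(lay_out(member_row, centroid_row))

    abundances = [clust.centroid.abundance] + [r.abundance for r, _ in clust.members]
    profile: list[dict] = []
    consensus = []
    for col in range(len(rows[0])):
        counts: dict[str, int] = {}
        for row, weight in zip(rows, abundances):
            symbol = row[col].upper()
            counts[symbol] = counts.get(symbol, 0) + weight
        profile.append(counts)
        consensus.append(
            max(counts, key=lambda s: (counts[s], s != "-", -ord(s)))
        )
    return rows, "".join(consensus), profile


def consensus_sequence(clust: Cluster) -> str:
    """Cluster consensus with gap columns removed."""
    _, consensus, _ = center_star_msa(clust)
    return consensus.replace("-", "")
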
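"""Deterministic synthetic amplicon data for tests and examples.

Every generator is a pure function of its parameters and seed, so fixture
files never need to be stored: clustered amplicon families with known
membership, labelled two-parent chimeras, and read pairs with a known
overlap and planted errors.  The quality model is a constant Phred score
with an optional linear 3' decay — deliberately simple, enough to
exercise every quality-dependent formula without imitating any particular
instrument's error profile.
"""

from __future__ import annotations

import numpy as np

from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "random_sequence",
    "mutate",
    "make_families",
    "make_chimeras",
    "make_read_pairs",
]

_BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(
    rng: np.random.Generator,
    sequence: str,
    substitution_rate: float,
    indel_rate: float = 0.0,
) -> str:
    """Point-mutate a template; substitutions always change the base."""
    out = []
    for ch in sequence:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(_BASES[rng.integers(0, 4)])  # insertion before ch
        if rng.random() < substitution_rate:
            choices = _BASES.replace(ch, "")
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(ch)
    return "".join(out)


def substitute_n(rng: np.random.Generator, sequence: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions (always changing)."""
    chars = list(sequence)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        choices = _BASES.replace(chars[pos], "")
        chars[pos] = choices[rng.integers(0, 3)]
    return "".join(chars)


def make_families(
    seed: int = 1,
    n_families: int = 5,
    members_per_family: int = 10,
    template_length: int = 300,
    member_divergence: float = 0.02,
    abundance_range: tuple[int, int] = (1, 50),
) -> tuple[list[SequenceRecord], list[int]]:
    """Clustered amplicon families with known membership.

    Independent random templates are, in expectation, about 75% divergent,
    far beyond any clustering threshold in use, so family membership is
    the unambiguous ground truth.  Each member carries between 1 and
    ``member_divergence * template_length`` substitutions relative to its
    template (a hard cap, so every member stays within the divergence
    bound by construction, the way separability benchmarks are built).
    The exact template itself is the family's most abundant record, as the
    true biological template typically is in amplicon data.  Returns
    (records, family_of_record).
    """
    rng = np.random.default_rng(seed)
    max_subs = max(1, int(member_divergence * template_length))
    records: list[SequenceRecord] = []
    truth: list[int] = []
    for fam in range(n_families):
        template = random_sequence(rng, template_length)
        for member in range(members_per_family):
            if member == 0:
                seq = template
                abundance = int(
                    rng.integers(abundance_range[1] + 1, 2 * abundance_range[1] + 1)
                )
            else:
                seq = substitute_n(rng, template, int(rng.integers(1, max_subs + 1)))
                abundance = int(
                    rng.integers(abundance_range[0], abundance_range[1] + 1)
                )
            records.append(
                SequenceRecord(
                    label=f"fam{fam}_m{member}",
                    sequence=seq,
                    abundance=abundance,
                    ordinal=len(records),
                )
            )
            truth.append(fam)
    return records, truth


def make_chimeras(
    seed: int = 1,
    n_chimeras: int = 20,
    template_length: int = 300,
    parent_divergence: tuple[float, float] = (0.03, 0.15),
    parent_abundance: int = 20,
    chimera_abundance: int = 1,
    breakpoint_window: float = 0.2,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[dict]]:
    """Two-parent chimeras with labelled parents and breakpoints.

    Each chimera takes the left part of parent A and the right part of
    parent B, with the breakpoint within ``breakpoint_window`` of the
    midpoint.  Parent mutual identity is 1 - d with d drawn from
    ``parent_divergence`` (the 85-97% band at the defaults).  Parents are
    always at least abskew=2 times as abundant as their chimera.
    Returns (parents, chimeras, truth rows).
    """
    rng = np.random.default_rng(seed)
    parents: list[SequenceRecord] = []
    chimeras: list[SequenceRecord] = []
    truth: list[dict] = []
    for k in range(n_chimeras):
        d = rng.uniform(*parent_divergence)
        pa_seq = random_sequence(rng, template_length)
        pb_seq = mutate(rng, pa_seq, d)
        half = template_length // 2
        jitter = int(breakpoint_window * template_length / 2)
        bp = half + int(rng.integers(-jitter, jitter + 1))
        chimera_seq = pa_seq[:bp] + pb_seq[bp:]
        pa = SequenceRecord(
            label=f"parentA_{k}", sequence=pa_seq,
            abundance=parent_abundance, ordinal=2 * k,
        )
        pb = SequenceRecord(
            label=f"parentB_{k}", sequence=pb_seq,
            abundance=parent_abundance, ordinal=2 * k + 1,
        )
        chim = SequenceRecord(
            label=f"chimera_{k}", sequence=chimera_seq,
            abundance=chimera_abundance, ordinal=k,
        )
        parents.extend([pa, pb])
        chimeras.append(chim)
        truth.append(
            {"chimera": chim.label, "parent_a": pa.label, "parent_b": pb.label,
             "breakpoint": bp, "parent_divergence": d}
        )
    return parents, chimeras, truth


def make_read_pairs(
    seed: int = 1,
    n_pairs: int = 100,
    read_length: int = 108,
    overlap: int = 18,
    quality: int = 35,
    quality_decay: int = 0,
    n_planted_errors: int = 0,
    stagger: bool = False,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[dict]]:
    """Paired reads from random templates with a known exact overlap.

    The template is ``2 * read_length - overlap`` long; the forward read
    is its prefix and the reverse read the reverse complement of its
    suffix.  With ``stagger`` the reads instead extend past each other
    (template shorter than the reads).  ``n_planted_errors`` substitutes
    bases of the reverse read inside the overlap at recorded columns.
    Returns (forward_reads, reverse_reads, truth rows).
    """
    rng = np.random.default_rng(seed)
    if stagger:
        template_length = overlap
    else:
        template_length = 2 * read_length - overlap
    forwards, reverses, truth = [], [], []
    for k in range(n_pairs):
        template = random_sequence(rng, template_length)
        if stagger:
            fwd_seq = template + random_sequence(rng, read_length - overlap)
            rev_template = random_sequence(rng, read_length - overlap) + template
            rev_seq = reverse_complement(rev_template)
        else:
            fwd_seq = template[:read_length]
            rev_seq = reverse_complement(template[-read_length:])
        quals = [
            max(2, quality - (quality_decay * p) // max(1, read_length - 1))
            for p in range(read_length)
        ]
        error_cols = []
        if n_planted_errors:
            # in plain orientation the reverse read starts at the overlap
            # (non-stagger) or contains it at its tail (stagger)
            rev_plain = reverse_complement(rev_seq)
            base = 0 if not stagger else len(rev_plain) - overlap
            cols = rng.choice(overlap, size=n_planted_errors, replace=False)
            chars = list(rev_plain)
            for c in sorted(int(c) for c in cols):
                idx = base + c
                chars[idx] = _BASES[(_BASES.index(chars[idx]) + 1) % 4]
                error_cols.append(idx)
            rev_seq = reverse_complement("".join(chars))
        forwards.append(
            SequenceRecord(label=f"pair{k}/1", sequence=fwd_seq,
                           qualities=list(quals), ordinal=k)
        )
        reverses.append(
            SequenceRecord(label=f"pair{k}/2", sequence=rev_seq,
                           qualities=list(quals), ordinal=k)
        )
        truth.append({"pair": k, "template": template, "overlap": overlap,
                      "error_positions": error_cols})
    return forwards, reverses, truth
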
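import pytest

from amplikit.align import compute_identity, global_align
from amplikit.fixtures import random_sequence, substitute_n
from amplikit.search import (
    SearchOptions,
    allpairs_global,
    build_index,
    search_exact,
    usearch_global,
)
from amplikit.seqio import SequenceRecord, reverse_complement


def make_db(rng, n, length=150):
    return [
        SequenceRecord(label=f"t{i}", sequence=random_sequence(rng, length), ordinal=i)
        for i in range(n)
    ]


def brute_force_hits(query, db, options):
    """Exhaustive oracle: align every target, filter by identity."""
    out = set()
    for t, target in enumerate(db):
        r = global_align(query.sequence, target.sequence, options.scoring)
        identity = compute_identity(r, len(query), len(target), options.iddef)
        if identity >= options.id_threshold:
            out.add(t)
    return out


class TestUsearchGlobal:
    def test_verbatim_query_single_hit(self, rng):
        db = make_db(rng, 10)
        query = db[4].copy(label="q")
        hits = usearch_global(query, db, options=SearchOptions(id_threshold=0.97))
        assert len(hits) == 1
        assert hits[0].target_ordinal == 4
        assert hits[0].identity == 1.0

    def test_no_shared_words_no_hits(self):
        db = [SequenceRecord(label="t", sequence="ACGT" * 20)]
        query = SequenceRecord(label="q", sequence="T" * 80)
        hits = usearch_global(query, db, options=SearchOptions(id_threshold=0.0))
        assert hits == []

    def test_empty_database(self):
        query = SequenceRecord(label="q", sequence="ACGTACGTACGT")
        assert usearch_global(query, [], options=SearchOptions()) == []

    @pytest.mark.parametrize("threshold", [0.5, 0.8, 0.97])
    def test_unlimited_budgets_match_brute_force(self, rng, threshold):
        db = make_db(rng, 30, length=120)
        # mix in some mutated copies so every threshold has genuine hits
        for i in range(5):
            db.append(
                SequenceRecord(
                    label=f"m{i}",
                    sequence=substitute_n(rng, db[i].sequence, 3 + 2 * i),
                    ordinal=len(db),
                )
            )
        options = SearchOptions(
            id_threshold=threshold, maxaccepts=0, maxrejects=0,
            minwordmatches=1, wordlength=5, qmask="none", dbmask="none",
        )
        index = build_index(db, options)
        for query in db[:10]:
            got = {h.target_ordinal for h in usearch_global(query, db, index, options)}
            assert got == brute_force_hits(query, db, options)

    def test_hits_sorted_by_identity_then_ordinal(self, rng):
        base = random_sequence(rng, 150)
        db = [
            SequenceRecord(label="far", sequence=substitute_n(rng, base, 12), ordinal=0),
            SequenceRecord(label="near", sequence=substitute_n(rng, base, 2), ordinal=1),
            SequenceRecord(label="self", sequence=base, ordinal=2),
        ]
        query = SequenceRecord(label="q", sequence=base)
        options = SearchOptions(id_threshold=0.5, maxaccepts=0, maxrejects=0,
                                qmask="none", dbmask="none")
        hits = usearch_global(query, db, options=options)
        identities = [h.identity for h in hits]
        assert identities == sorted(identities, reverse=True)
        assert hits[0].target_ordinal == 2

    def test_maxaccepts_stops_scan(self, rng):
        base = random_sequence(rng, 150)
        db = [
            SequenceRecord(label=f"t{i}", sequence=substitute_n(rng, base, 1), ordinal=i)
            for i in range(6)
        ]
        query = SequenceRecord(label="q", sequence=base)
        options = SearchOptions(id_threshold=0.9, maxaccepts=2, qmask="none", dbmask="none")
        assert len(usearch_global(query, db, options=options)) == 2

    def test_self_exclusion(self, rng):
        db = make_db(rng, 5)
        query = db[1]
        options = SearchOptions(id_threshold=0.97, self_exclude=True,
                                qmask="none", dbmask="none")
        assert usearch_global(query, db, options=options) == []

    def test_strand_both_finds_reverse_complement(self, rng):
        target = random_sequence(rng, 150)
        db = [SequenceRecord(label="t", sequence=target)]
        query = SequenceRecord(label="q", sequence=reverse_complement(target))
        plus_only = usearch_global(
            query, db, options=SearchOptions(id_threshold=0.9, strand="plus")
        )
        both = usearch_global(
            query, db, options=SearchOptions(id_threshold=0.9, strand="both")
        )
        assert plus_only == []
        assert len(both) == 1
        assert both[0].strand == "-"
        assert both[0].identity == 1.0

    def test_maxsubs_post_filter(self, rng):
        base = random_sequence(rng, 150)
        db = [SequenceRecord(label="t", sequence=substitute_n(rng, base, 4))]
        query = SequenceRecord(label="q", sequence=base)
        lax = SearchOptions(id_threshold=0.9, qmask="none", dbmask="none")
        strict = SearchOptions(id_threshold=0.9, maxsubs=3, qmask="none", dbmask="none")
        assert len(usearch_global(query, db, options=lax)) == 1
        assert usearch_global(query, db, options=strict) == []


class TestSearchExact:
    def test_exact_full_length_match(self):
        db = [SequenceRecord(label="t", sequence="ACGTACGTACGT")]
        query = SequenceRecord(label="q", sequence="ACGTACGTACGT")
        hits = search_exact(query, db)
        assert len(hits) == 1
        assert hits[0].identity == 1.0

    def test_strict_prefix_not_matched(self):
        db = [SequenceRecord(label="t", sequence="ACGTACGTACGT")]
        query = SequenceRecord(label="q", sequence="ACGTACGT")
        assert search_exact(query, db) == []

    def test_u_normalized_before_hashing(self):
        db = [SequenceRecord(label="t", sequence="ACGT")]
        query = SequenceRecord(label="q", sequence="ACGU")
        assert len(search_exact(query, db)) == 1


class TestAllpairs:
    def test_three_identical_records(self):
        records = [
            SequenceRecord(label=f"r{i}", sequence="ACGTACGTACGT", ordinal=i)
            for i in range(3)
        ]
        hits = allpairs_global(records, SearchOptions(id_threshold=0.9))
        assert len(hits) == 3
        assert all(h.identity == 1.0 for h in hits)

    def test_identity_threshold_one_on_distinct_records(self, rng):
        records = make_db(rng, 5)
        assert allpairs_global(records, SearchOptions(id_threshold=1.0)) == []

    def test_pair_identities_compose_from_global_align(self, rng):
        records = make_db(rng, 6, length=80)
        options = SearchOptions(id_threshold=0.0)
        for hit in allpairs_global(records, options):
            a = records[hit.query_ordinal]
            b = records[hit.target_ordinal]
            r = global_align(a.sequence, b.sequence, options.scoring)
            assert hit.identity == pytest.approx(
                compute_identity(r, len(a), len(b), options.iddef)
            )

    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            allpairs_global([SequenceRecord(label="x", sequence="ACGT")])
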
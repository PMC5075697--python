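from amplikit.cluster import Cluster, center_star_msa, cluster_records, consensus_sequence
from amplikit.fixtures import make_families, random_sequence
from amplikit.search import SearchOptions
from amplikit.seqio import SequenceRecord


def options(id_threshold=0.97, **kw):
    return SearchOptions(id_threshold=id_threshold, **kw)


def toy_options(id_threshold, **kw):
    # short or repetitive toy sequences: no masking, 3-mers, 1 shared word
    kw.setdefault("wordlength", 3)
    kw.setdefault("minwordmatches", 1)
    kw.setdefault("qmask", "none")
    kw.setdefault("dbmask", "none")
    return SearchOptions(id_threshold=id_threshold, **kw)


def predicted_labels(clusters, n):
    out = [None] * n
    for k, c in enumerate(clusters):
        for r in c.records():
            out[r.ordinal] = k
    return out


class TestClustering:
    def test_all_identical_single_cluster(self):
        records = [
            SequenceRecord(label=f"r{i}", sequence="ACGTACGTACGTACGT" * 4, ordinal=i)
            for i in range(5)
        ]
        clusters = cluster_records(records, "smallmem", toy_options(0.97))
        assert len(clusters) == 1
        assert clusters[0].size == 5

    def test_two_separated_families_exact_membership(self, rng):
        records, truth = make_families(seed=77, n_families=2, members_per_family=6)
        clusters = cluster_records(records, "size", options())
        assert len(clusters) == 2
        pred = predicted_labels(clusters, len(records))
        mapping = {}
        for fam, assigned in zip(truth, pred):
            mapping.setdefault(fam, assigned)
            assert mapping[fam] == assigned

    def test_partition_and_abundance_conservation(self):
        records, _ = make_families(seed=3, n_families=4, members_per_family=7)
        clusters = cluster_records(records, "fast", options())
        seen = sorted(r.ordinal for c in clusters for r in c.records())
        assert seen == list(range(len(records)))
        assert sum(c.total_abundance for c in clusters) == sum(
            r.abundance for r in records
        )

    def test_every_member_meets_identity_threshold(self):
        records, _ = make_families(seed=11, n_families=3, members_per_family=6)
        clusters = cluster_records(records, "fast", options())
        for c in clusters:
            for _, hit in c.members:
                assert hit.identity >= 0.97

    def test_mode_equivalence_presorted_smallmem(self):
        records, _ = make_families(seed=5, n_families=3, members_per_family=6)
        opts = options()
        by_length = sorted(
            records, key=lambda r: (-len(r.sequence), -r.abundance, r.ordinal)
        )
        fast = cluster_records(records, "fast", opts)
        smallmem = cluster_records(by_length, "smallmem", opts)
        key = lambda cs: [
            sorted(r.label for r in c.records()) for c in cs
        ]
        assert key(fast) == key(smallmem)

    def test_dgc_vs_agc_divergence(self, rng):
        # query matches centroid C1 closer (0.99) but C2 (0.973) is far
        # more abundant: DGC joins C1, AGC (sizeorder) joins C2.  The
        # substituted positions are disjoint so C1-C2 identity (0.963)
        # stays below the threshold and C2 founds its own cluster.
        base = random_sequence(rng, 300)

        def sub_at(seq, positions):
            chars = list(seq)
            for p in positions:
                chars[p] = "ACGT"[("ACGT".index(chars[p]) + 1) % 4]
            return "".join(chars)

        c1 = SequenceRecord(label="c1", sequence=sub_at(base, range(100, 103)),
                            abundance=5, ordinal=0)
        c2 = SequenceRecord(label="c2", sequence=sub_at(base, range(200, 208)),
                            abundance=50, ordinal=1)
        query = SequenceRecord(label="q", sequence=base, abundance=1, ordinal=2)
        opts = options(0.97, maxaccepts=2)
        dgc = cluster_records([c1, c2, query], "smallmem", opts)
        agc = cluster_records([c1, c2, query], "smallmem", opts, sizeorder=True)
        dgc_home = [c.centroid.label for c in dgc if any(m.label == "q" for m, _ in c.members)]
        agc_home = [c.centroid.label for c in agc if any(m.label == "q" for m, _ in c.members)]
        assert dgc_home == ["c1"]
        assert agc_home == ["c2"]

    def test_thread_count_does_not_change_output(self):
        records, _ = make_families(seed=9, n_families=3, members_per_family=5)
        one = cluster_records(records, "fast", options(), threads=1)
        eight = cluster_records(records, "fast", options(), threads=8)
        key = lambda cs: [
            (c.centroid.label, sorted(m.label for m, _ in c.members)) for c in cs
        ]
        assert key(one) == key(eight)

    def test_cluster_numbering_follows_creation_order(self, rng):
        a = random_sequence(rng, 200)
        b = random_sequence(rng, 200)
        records = [
            SequenceRecord(label="first", sequence=a, ordinal=0),
            SequenceRecord(label="second", sequence=b, ordinal=1),
        ]
        clusters = cluster_records(records, "smallmem", options())
        assert [c.centroid.label for c in clusters] == ["first", "second"]


class TestCenterStar:
    def test_singleton_cluster(self):
        record = SequenceRecord(label="c", sequence="ACGTACGT", abundance=2)
        rows, consensus, profile = center_star_msa(Cluster(centroid=record))
        assert rows == ["ACGTACGT"]
        assert consensus == "ACGTACGT"
        assert len(profile) == 8

    CSEQ = "ACGTTGCAGCTTAGGCATCAGGCA"  # 24 nt, no internal repeats

    def test_member_insertion_opens_centroid_gap(self):
        centroid = SequenceRecord(label="c", sequence=self.CSEQ, ordinal=0)
        member = SequenceRecord(
            label="m", sequence=self.CSEQ[:12] + "T" + self.CSEQ[12:], ordinal=1
        )
        clusters = cluster_records([centroid, member], "smallmem", toy_options(0.9))
        assert len(clusters) == 1
        rows, consensus, _ = center_star_msa(clusters[0])
        assert len(rows) == 2
        assert len(rows[0]) == 25
        assert rows[0].count("-") == 1
        assert rows[1] == member.sequence

    def test_consensus_weighted_by_abundance(self):
        mutated = self.CSEQ[:10] + "C" + self.CSEQ[11:]  # T -> C at position 10
        assert mutated != self.CSEQ
        centroid = SequenceRecord(label="c", sequence=self.CSEQ, abundance=1, ordinal=0)
        member = SequenceRecord(label="m", sequence=mutated, abundance=10, ordinal=1)
        clusters = cluster_records([centroid, member], "smallmem", toy_options(0.9))
        assert clusters[0].size == 2
        _, consensus, _ = center_star_msa(clusters[0])
        assert consensus == mutated

    def test_consensus_tie_resolved_by_symbol_order(self):
        mutated = self.CSEQ[:10] + "C" + self.CSEQ[11:]  # T vs C, equal weight
        centroid = SequenceRecord(label="c", sequence=self.CSEQ, abundance=3, ordinal=0)
        member = SequenceRecord(label="m", sequence=mutated, abundance=3, ordinal=1)
        clusters = cluster_records([centroid, member], "smallmem", toy_options(0.9))
        _, consensus, _ = center_star_msa(clusters[0])
        # tied column: C wins over T in the fixed order A<C<G<T
        assert consensus == mutated

    def test_rows_equal_length(self):
        records, _ = make_families(seed=21, n_families=1, members_per_family=8)
        clusters = cluster_records(records, "size", options())
        rows, consensus, profile = center_star_msa(clusters[0])
        assert len({len(r) for r in rows}) == 1
        assert len(consensus) == len(rows[0]) == len(profile)

    def test_consout_strips_gaps(self):
        centroid = SequenceRecord(label="c", sequence="ACGTACGT", ordinal=0)
        member = SequenceRecord(label="m", sequence="ACGTTACGT", ordinal=1)
        clusters = cluster_records([centroid, member], "smallmem", toy_options(0.8))
        assert "-" not in consensus_sequence(clusters[0])
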
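"""Back-splice detection: QC rules, index correctness against a brute-force
scan, anchor/junction logic on planted and constructed reads, the support
filter, classification, and BED round trips."""

import numpy as np
import pytest

from circena import detect, simulate
from circena.detect import (
    CircRecord,
    GenomeIndex,
    JunctionCandidate,
    ReadRecord,
    build_index,
    call_junction,
    classify_circ,
    collapse_candidates,
    find_anchors,
    map_linear,
    qc_filter_reads,
    read_bed,
    summarize_catalog,
    write_bed,
)
from circena.reference import Gene, ReferenceBundle, revcomp


def q(phred: int, n: int) -> str:
    return chr(phred + 33) * n


class TestQCFilter:
    def test_high_n_fraction_discarded(self):
        seq = "N" * 11 + "A" * 89
        reads = [ReadRecord("r1", seq, q(30, 100))]
        clean, report = qc_filter_reads(reads)
        assert clean == [] and report.failed_n_fraction == 1

    def test_clean_read_retained(self):
        reads = [ReadRecord("r1", "A" * 100, q(30, 100))]
        clean, report = qc_filter_reads(reads)
        assert len(clean) == 1 and report.passed == 1

    def test_low_quality_majority_discarded(self):
        # 51 bases at Q20: Q <= 20 counts as low-quality, 51% > 50%
        quality = q(20, 51) + q(30, 49)
        reads = [ReadRecord("r1", "A" * 100, quality)]
        clean, report = qc_filter_reads(reads)
        assert clean == [] and report.failed_low_quality == 1

    def test_exact_boundaries_are_retained(self):
        # exactly 10% N and exactly 50% low-quality both pass (> rules)
        reads = [
            ReadRecord("n10", "N" * 10 + "A" * 90, q(30, 100)),
            ReadRecord("q50", "A" * 100, q(20, 50) + q(30, 50)),
        ]
        clean, _ = qc_filter_reads(reads)
        assert [r.id for r in clean] == ["n10", "q50"]

    def test_adapter_containing_read_discarded(self):
        reads = [ReadRecord("r1", "ACGT" * 25, q(30, 100))]
        clean, report = qc_filter_reads(reads, adapter="GTAC")
        assert clean == [] and report.failed_adapter == 1

    def test_length_mismatch_is_a_parse_error(self):
        with pytest.raises(detect.FastqParseError):
            ReadRecord("r1", "ACGT", "II")


class TestGenomeIndex:
    def test_tiny_genome_enumerable_by_hand(self):
        bundle = ReferenceBundle(sequences={"c": "ACGTACGT"}, genes=[])
        index = build_index(bundle, k=4)
        hits = index.lookup("ACGT")
        plus = [(c, o) for c, o, s in hits if s == "+"]
        assert sorted(plus) == [("c", 0), ("c", 4)]
        # ACGT is its own reverse complement: minus hits at the same loci
        minus = [(c, o) for c, o, s in hits if s == "-"]
        assert sorted(minus) == [("c", 0), ("c", 4)]

    def test_absent_kmer_gives_empty_list(self):
        bundle = ReferenceBundle(sequences={"c": "AAAAAAAA"}, genes=[])
        assert build_index(bundle, k=4).lookup("CCCC") == []

    def test_positions_dereference_to_their_kmer(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        bundle = ReferenceBundle(sequences={"c": seq}, genes=[])
        index = build_index(bundle, k=6)
        for kmer, hits in list(index.positions.items())[::17]:
            for chrom, off, strand in hits:
                piece = seq[off : off + 6]
                assert (piece if strand == "+" else revcomp(piece)) == kmer

    def test_lookups_match_brute_force_scan(self):
        """Random lookups equal a naive full scan of both strands."""
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        bundle = ReferenceBundle(sequences={"g": seq}, genes=[])
        k = 20
        index = build_index(bundle, k=k)
        rc = revcomp(seq)
        n = len(seq)
        for _ in range(100):
            start = int(rng.integers(0, n - k + 1))
            kmer = seq[start : start + k] if rng.random() < 0.5 else revcomp(
                seq[start : start + k]
            )
            expected = set()
            for i in range(n - k + 1):
                if seq[i : i + k] == kmer:
                    expected.add(("g", i, "+"))
                if rc[i : i + k] == kmer:
                    # rc offset i corresponds to plus offset n - k - i
                    expected.add(("g", n - k - i, "-"))
            assert set(index.lookup(kmer)) == expected

    def test_non_acgtn_reference_rejected(self):
        with pytest.raises(Exception):
            ReferenceBundle(sequences={"c": "ACGTX"}, genes=[])

    def test_n_kmers_not_indexed(self):
        bundle = ReferenceBundle(sequences={"c": "ACGTNACGT"}, genes=[])
        index = build_index(bundle, k=4)
        assert all("N" not in kmer for kmer in index.positions)


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5_000))
    bundle = ReferenceBundle(sequences={"chr1": seq}, genes=[])
    return bundle, build_index(bundle, k=20)


class TestMapLinear:
    def test_exact_substring_maps_with_zero_mismatches(self, toy_genome):
        bundle, index = toy_genome
        read = ReadRecord("r", bundle.sequences["chr1"][1000:1100], q(40, 100))
        aln = map_linear(read, index, bundle)
        assert aln and (aln.start, aln.strand, aln.mismatches) == (1000, "+", 0)

    def test_reverse_complement_maps_on_minus(self, toy_genome):
        bundle, index = toy_genome
        read = ReadRecord(
            "r", revcomp(bundle.sequences["chr1"][2000:2100]), q(40, 100)
        )
        aln = map_linear(read, index, bundle)
        assert aln and (aln.start, aln.strand) == (2000, "-")

    def test_mismatch_budget_enforced(self, toy_genome):
        bundle, index = toy_genome
        seq = list(bundle.sequences["chr1"][1000:1100])
        for pos in (40, 50, 60):
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        aln = map_linear(ReadRecord("r", "".join(seq), q(40, 100)), index, bundle)
        assert aln is None  # 3 mismatches > default budget of 2

    def test_backsplice_read_does_not_map(self, sim_reference, sim_reads):
        bundle, _ = sim_reference
        index = build_index(bundle, k=20)
        bs = next(r for r in sim_reads if r.junction is not None)
        read = ReadRecord(bs.id, bs.sequence, bs.quality)
        assert map_linear(read, index, bundle) is None


class TestAnchorsAndJunctions:
    def test_planted_reads_yield_exact_breakpoints(self, sim_reference,
                                                   sim_reads):
        bundle, truth = sim_reference
        index = build_index(bundle, k=20)
        n_called = 0
        for r in sim_reads:
            if r.junction is None or not r.id.startswith("junc"):
                continue
            read = ReadRecord(r.id, r.sequence, r.quality)
            anchors = find_anchors(read, index)
            assert anchors is not None, r.id
            cand = call_junction(read, anchors, bundle)
            assert cand is not None, r.id
            assert cand.key == r.junction
            n_called += 1
        assert n_called >= 50

    def test_repeated_anchor_rejected(self):
        # head 20-mer occurs twice: uniqueness is violated
        rng = np.random.default_rng(5)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        filler = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        seq = core + filler + core + filler[::-1]
        bundle = ReferenceBundle(sequences={"c": seq}, genes=[])
        index = build_index(bundle, k=20)
        read = ReadRecord("r", core + filler[:20], q(40, 40))
        assert find_anchors(read, index) is None

    def test_colinear_orientation_rejected(self, sim_reference, sim_reads):
        """Reads spanning a linear exon-exon splice have head upstream of
        tail and must not be called as circular."""
        bundle, _ = sim_reference
        index = build_index(bundle, k=20)
        tested = 0
        for r in sim_reads:
            if r.junction is not None:
                continue
            read = ReadRecord(r.id, r.sequence, r.quality)
            if map_linear(read, index, bundle) is not None:
                continue  # contiguous: not a splice-spanning read
            anchors = find_anchors(read, index)
            if anchors is None:
                continue
            assert call_junction(read, anchors, bundle) is None, r.id
            tested += 1
        assert tested > 0

    def test_mutated_flanks_rejected(self, sim_reference, sim_reads):
        """Reads from decoys whose acceptor flank is not AG are rejected."""
        bundle, truth = sim_reference
        index = build_index(bundle, k=20)
        decoy_keys = {(j.chrom, j.start, j.end, j.strand)
                      for j in truth.flank_decoys}
        tested = 0
        for r in sim_reads:
            if r.junction not in decoy_keys:
                continue
            read = ReadRecord(r.id, r.sequence, r.quality)
            anchors = find_anchors(read, index)
            assert anchors is not None
            assert call_junction(read, anchors, bundle) is None, r.id
            tested += 1
        assert tested > 0


def make_candidate(sample, read_id, seq, key=("chr1", 100, 600, "+")):
    chrom, s, e, strand = key
    return JunctionCandidate(
        chrom=chrom, start=s, end=e, strand=strand, read_id=read_id,
        sample=sample, read_seq=seq, mismatches=0, flanks=("AG", "GT"),
    )


class TestCollapse:
    def test_two_unique_reads_in_one_sample_retained(self):
        cands = [
            make_candidate("s1", "r1", "AAAA"),
            make_candidate("s1", "r2", "CCCC"),
        ]
        records = collapse_candidates(cands)
        assert len(records) == 1
        assert records[0].support == {"s1": 2}

    def test_one_read_per_sample_discarded(self):
        cands = [
            make_candidate(f"s{i}", f"r{i}", f"SEQ{i}".replace("S", "A")
                           .replace("E", "C").replace("Q", "G"))
            for i in range(4)
        ]
        assert collapse_candidates(cands) == []

    def test_duplicate_sequences_count_once(self):
        cands = [
            make_candidate("s1", "r1", "AAAA"),
            make_candidate("s1", "r2", "AAAA"),  # PCR duplicate
        ]
        assert collapse_candidates(cands) == []

    def test_ids_sequential_in_coordinate_order(self):
        cands = []
        for i, key in enumerate(
            [("chr2", 50, 500, "+"), ("chr1", 900, 1400, "-"),
             ("chr1", 100, 600, "+")]
        ):
            cands.append(make_candidate("s1", f"a{i}", f"AA{i}A", key))
            cands.append(make_candidate("s1", f"b{i}", f"CC{i}C", key))
        records = collapse_candidates(cands)
        assert [r.circ_id for r in records] == [
            "circ_000001", "circ_000002", "circ_000003"
        ]
        assert [r.key for r in records] == [
            ("chr1", 100, 600, "+"), ("chr1", 900, 1400, "-"),
            ("chr2", 50, 500, "+"),
        ]


@pytest.fixture(scope="module")
def annotated_bundle():
    seq = "A" * 3000
    gene = Gene("g1", "chr1", "+", 100, 1100,
                exons=[(100, 300), (500, 700), (900, 1100)])
    gene_minus = Gene("g2", "chr1", "-", 1500, 2100,
                      exons=[(1500, 1700), (1900, 2100)])
    return ReferenceBundle(sequences={"chr1": seq}, genes=[gene, gene_minus])


class TestClassify:
    def rec(self, start, end, strand="+"):
        return CircRecord("c", "chr1", start, end, strand, {"s1": 2})

    def test_exon_boundary_circle_is_exonic(self, annotated_bundle):
        r = classify_circ(self.rec(100, 700), annotated_bundle)
        assert (r.circ_class, r.gene_id) == ("exonic", "g1")
        assert r.spliced_length == 400  # two 200 bp exons

    def test_intron_interior_circle_is_intronic(self, annotated_bundle):
        r = classify_circ(self.rec(320, 480), annotated_bundle)
        assert (r.circ_class, r.gene_id) == ("intronic", "g1")

    def test_opposite_strand_overlap_is_antisense(self, annotated_bundle):
        r = classify_circ(self.rec(1550, 2000, "+"), annotated_bundle)
        assert r.circ_class == "antisense"
        assert r.gene_id == "g2"  # the opposite-strand gene is recorded

    def test_no_gene_overlap_is_intergenic(self, annotated_bundle):
        r = classify_circ(self.rec(2500, 2900), annotated_bundle)
        assert (r.circ_class, r.gene_id) == ("intergenic", None)


class TestSummary:
    def test_empty_catalog_all_zero(self):
        s = summarize_catalog([])
        assert s["n_circ"] == 0 and s["per_chromosome"] == {}
        assert sum(s["length_histogram"]["counts"]) == 0

    def test_one_record_per_chromosome(self):
        records = [
            CircRecord(f"c{i}", f"chr{i}", 0, 300, "+", {"s1": 2})
            for i in range(1, 4)
        ]
        s = summarize_catalog(records)
        assert s["per_chromosome"] == {"chr1": 1, "chr2": 1, "chr3": 1}

    def test_group_overlap_equals_set_arithmetic(self):
        rng = np.random.default_rng(3)
        sample_groups = {f"s{i}": f"G{i % 4}" for i in range(8)}
        records = []
        for i in range(40):
            support = {
                s: int(rng.integers(0, 3)) for s in sample_groups
                if rng.random() < 0.5
            }
            records.append(
                CircRecord(f"c{i}", "chr1", i * 10, i * 10 + 300, "+", support)
            )
        s = summarize_catalog(records, sample_groups)
        presence = {g: set(ids) for g, ids in s["group_presence"].items()}
        # brute-force oracle for the 4-way intersection
        expected = set.intersection(*presence.values()) if presence else set()
        key = "&".join(sorted(presence))
        assert s["group_overlap"][key] == len(expected)


class TestBedRoundTrip:
    def test_write_read_write_byte_stable(self, tmp_path, sim_reference,
                                          sim_reads):
        bundle, _ = sim_reference
        reads = simulate.as_read_records(sim_reads)
        result = detect.detect_circrnas(bundle, reads)
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(result.records, p1)
        write_bed(read_bed(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_preserves_records(self, tmp_path):
        records = [
            CircRecord("circ_000001", "chr1", 10, 500, "+", {"s1": 3, "s2": 1},
                       "exonic", "g1"),
            CircRecord("circ_000002", "chr2", 20, 400, "-", {"s2": 2},
                       "intergenic", None),
        ]
        path = tmp_path / "cat.bed"
        write_bed(records, path)
        back = read_bed(path)
        assert [(r.key, r.support, r.circ_class, r.gene_id) for r in back] == [
            (r.key, r.support, r.circ_class, r.gene_id) for r in records
        ]


class TestGtfRoundTrip:
    def test_coordinates_survive_gtf_io(self, tmp_path, sim_reference):
        bundle, _ = sim_reference
        fa, gtf = tmp_path / "g.fa", tmp_path / "g.gtf"
        bundle.write_fasta(fa)
        bundle.write_gtf(gtf)
        back = ReferenceBundle.from_files(fa, gtf)
        assert back.sequences == bundle.sequences
        assert [(g.gene_id, g.chrom, g.strand, g.start, g.end, g.exons)
                for g in back.genes] == [
            (g.gene_id, g.chrom, g.strand, g.start, g.end, g.exons)
            for g in bundle.genes
        ]


def test_no_read_is_both_linear_and_junction(sim_reference, sim_reads):
    """Exclusivity: the pipeline discards linearly mapped reads before the
    junction search, so the two read sets cannot intersect."""
    bundle, _ = sim_reference
    index = build_index(bundle, k=20)
    linear_ids, junction_ids = set(), set()
    for r in simulate.as_read_records(sim_reads):
        if map_linear(r, index, bundle) is not None:
            linear_ids.add(r.id)
            continue
        anchors = find_anchors(r, index)
        if anchors and call_junction(r, anchors, bundle):
            junction_ids.add(r.id)
    assert linear_ids and junction_ids
    assert not linear_ids & junction_ids
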
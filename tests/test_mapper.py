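"""Long-read mapping: oligo search vs. a brute-force Hamming oracle,
cassette extraction filters, insert alignment vs. full Smith-Waterman,
location resolution, and planted-truth recovery of the whole pipeline."""

import numpy as np
import pytest
from Bio.Align import PairwiseAligner

from bobaseq.mapper import (
    AlignParams,
    DEFAULT_OLIGOS,
    GenomeIndex,
    OligoSet,
    align_insert,
    annotate_genes,
    build_map,
    demultiplex,
    expected_error,
    extract_cassette,
    find_oligo,
    resolve_locations,
)
from bobaseq.model import Genome, GeneAnnotation, revcomp
from bobaseq.simulate import ErrorModel, sim_longreads, sim_truth


def _read(seq, q=40, rid="r"):
    return (rid, seq, [q] * len(seq))


def _cassette(barcode, insert, oligos=DEFAULT_OLIGOS, pad="TTTTT"):
    a1, a2, a3, a4 = oligos.oligos()
    return pad + a1 + barcode + a2 + "GATTACAGAT" + a3 + insert + a4 + pad


class TestFindOligo:
    def test_exact_single_hit(self):
        oligo = "ACGTACGTACGTACG"
        seq = "TTT" + oligo + "GGG"
        assert find_oligo(seq, oligo, 0) == [(3, 0)]

    def test_two_hits_feed_concatemer_detection(self):
        oligo = "ACGTACGTACGTACG"
        seq = oligo + "TTTT" + oligo
        assert [p for p, _m in find_oligo(seq, oligo, 0)] == [0, 19]

    def test_equivalence_with_bruteforce_hamming_scan(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(rng.choice(bases, 500))
            oligo = "".join(rng.choice(bases, 15))
            tol = int(rng.integers(0, 4))
            brute = [
                (i, sum(a != b for a, b in zip(seq[i : i + 15], oligo)))
                for i in range(len(seq) - 14)
                if sum(a != b for a, b in zip(seq[i : i + 15], oligo)) <= tol
            ]
            assert find_oligo(seq, oligo, tol) == brute


class TestExpectedError:
    @pytest.mark.parametrize(
        "quals,expected",
        [
            ([20] * 100, 1.0),
            ([20] * 1500, 15.0),
            ([10] * 10 + [30] * 10, 1.01),
            ([], 0.0),
        ],
    )
    def test_summation(self, quals, expected):
        assert expected_error(quals) == pytest.approx(expected)

    def test_filter_boundary(self):
        # a 1500-bp Q20 insert has expected error 15 > 10 and is rejected
        assert expected_error([20] * 1500) > 10.0


class TestExtractCassette:
    def test_planted_round_trip_both_orientations(self):
        barcode, insert = "A" * 10 + "C" * 10, "ACGT" * 200
        seq = _cassette(barcode, insert)
        for oriented, name in ((seq, "forward"), (revcomp(seq), "reverse")):
            ex = extract_cassette(_read(oriented), DEFAULT_OLIGOS)
            assert ex.accepted
            assert ex.barcode == barcode
            assert ex.insert_seq == insert
            assert ex.orientation == name

    def test_concatemer_rejected(self):
        one = _cassette("A" * 20, "ACGT" * 100)
        ex = extract_cassette(_read(one + one), DEFAULT_OLIGOS)
        assert ex.reject_reason == "concatemer"

    def test_bad_barcode_length_rejected(self):
        ex = extract_cassette(
            _read(_cassette("A" * 19, "ACGT" * 100)), DEFAULT_OLIGOS
        )
        assert ex.reject_reason == "bad_barcode_length"

    def test_read_without_anchors_rejected(self):
        ex = extract_cassette(_read("ACGT" * 100), DEFAULT_OLIGOS)
        assert ex.reject_reason == "no_oligos"

    def test_oligo_set_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            OligoSet("A" * 15, "A" * 15, "C" * 15, "G" * 15)


class TestDemultiplex:
    I5A, I7A = "A" * 16, "C" * 16
    I5B, I7B = "G" * 16, "T" * 16

    def pairs(self):
        return {(self.I5A, self.I7A): "libA", (self.I5B, self.I7B): "libB"}

    def test_exact_and_one_mismatch(self):
        body = "ACGT" * 50
        exact = self.I5A + body + revcomp(self.I7A)
        near = ("T" + self.I5A[1:]) + body + revcomp(self.I7A)
        out, unassigned = demultiplex(
            [_read(exact, rid="r1"), _read(near, rid="r2")], self.pairs()
        )
        assert {r[0] for r in out["libA"]} == {"r1", "r2"}
        assert unassigned == 0

    def test_unassigned_bin(self):
        out, unassigned = demultiplex([_read("ACGT" * 30)], self.pairs())
        assert unassigned == 1 and not out

    def test_index_collision_rejected_at_load(self):
        near_a = ("T" + self.I5A[1:], self.I7A)
        with pytest.raises(ValueError, match="collision"):
            demultiplex([], {(self.I5A, self.I7A): "x", near_a: "y"})


def _sw_oracle(insert, genome_seq):
    """Full Smith-Waterman (independent of the seed-and-extend path):
    best local alignment of the insert against either strand."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    best = None
    for strand, q in (("+", insert), ("-", revcomp(insert))):
        aln = aligner.align(genome_seq, q)[0]
        blocks = aln.aligned[0]
        start, end = int(blocks[0][0]), int(blocks[-1][1])
        counts = aln.counts()
        ident = counts.identities / (
            counts.identities + counts.mismatches + counts.gaps
        )
        if best is None or aln.score > best[0]:
            best = (aln.score, strand, start, end, ident)
    return best


class TestAlignInsert:
    def test_error_free_substring_maps_exactly(self, toy_truth):
        genome = toy_truth.genome
        seq = genome.contigs["chr"]
        insert = seq[5000:8000]
        (top, *_rest) = align_insert(insert, genome)
        assert (top.contig_id, top.start, top.end, top.strand) == ("chr", 5000, 8000, "+")
        assert top.pct_identity == 1.0
        assert top.pct_coverage == 1.0

    def test_reverse_strand_recovered(self, toy_truth):
        seq = toy_truth.genome.contigs["chr"]
        insert = revcomp(seq[10000:12500])
        (top, *_rest) = align_insert(insert, toy_truth.genome)
        assert (top.start, top.end, top.strand) == (10000, 12500, "-")

    def test_agrees_with_smith_waterman_on_noisy_insert(self, toy_truth):
        rng = np.random.default_rng(3)
        seq = toy_truth.genome.contigs["chr"][:30000]
        genome = Genome("sub", {"chr": seq})
        true_start, true_end = 4000, 7000
        insert = list(seq[true_start:true_end])
        # 3% random substitutions
        for i in rng.choice(len(insert), size=int(0.03 * len(insert)), replace=False):
            insert[i] = "ACGT"[(("ACGT".index(insert[i])) + 1) % 4]
        insert = "".join(insert)
        (top, *_rest) = align_insert(insert, genome)
        assert abs(top.start - true_start) <= 5 and abs(top.end - true_end) <= 5
        assert top.pct_identity >= 0.95
        _score, strand, o_start, o_end, o_ident = _sw_oracle(insert, seq)
        assert strand == top.strand == "+"
        band = int(0.15 * len(insert))
        assert abs(top.start - o_start) <= band and abs(top.end - o_end) <= band
        assert abs(top.pct_identity - o_ident) <= 0.005

    def test_random_insert_finds_nothing(self, toy_truth):
        rng = np.random.default_rng(9)
        junk = "".join(rng.choice(list("ACGT"), 3000))
        hits = align_insert(junk, toy_truth.genome)
        assert hits == []
        _score, _strand, o_start, o_end, o_ident = _sw_oracle(
            junk, toy_truth.genome.contigs["chr"][:30000]
        )
        assert o_ident < 0.90 or (o_end - o_start) < 0.8 * len(junk)

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError, match="shorter than seed"):
            GenomeIndex(Genome("t", {"c": "ACGTACG"}), k=15)


class TestResolveLocations:
    def test_overlapping_locations_take_top_read_count(self):
        locs = [("c1", 100, 3100, "+")] * 5 + [("c1", 95, 3105, "+")] * 2
        rec = resolve_locations("A" * 20, locs)
        assert (rec.start, rec.end) == (100, 3100)
        assert rec.read_support == 7  # overlapping group pools its reads
        assert not rec.multi_locus

    def test_distant_equal_counts_flagged_multilocus(self):
        locs = [("c1", 0, 3000, "+")] * 4 + [("c2", 0, 3000, "+")] * 4
        rec = resolve_locations("A" * 20, locs)
        assert rec.multi_locus
        assert len(rec.alt_locations) == 1
        assert rec.alt_locations[0][3] == 4

    def test_single_read(self):
        rec = resolve_locations("A" * 20, [("c1", 7, 1000, "-")])
        assert (rec.contig_id, rec.start, rec.end, rec.strand) == ("c1", 7, 1000, "-")
        assert rec.read_support == 1 and not rec.multi_locus


class TestAnnotateGenes:
    GENES = [
        GeneAnnotation("gIn", "c1", 1500, 2400, "+"),
        GeneAnnotation("gPartial", "c1", 3500, 4200, "+"),
        GeneAnnotation("gOpp", "c1", 2500, 2800, "-"),
        GeneAnnotation("gOther", "c2", 0, 300, "+"),
    ]

    def test_full_containment_only(self):
        rec = resolve_locations("A" * 20, [("c1", 1000, 4000, "+")])
        annotate_genes(rec, self.GENES)
        assert rec.contained_gene_tags == ["gIn", "gOpp"]

    def test_orientation_vs_promoter(self):
        rec = resolve_locations("A" * 20, [("c1", 1000, 4000, "+")])
        assert rec.gene_orientation(self.GENES[0]) == "same"
        assert rec.gene_orientation(self.GENES[2]) == "opposite"
        rec_minus = resolve_locations("C" * 20, [("c1", 1000, 4000, "-")])
        assert rec_minus.gene_orientation(self.GENES[0]) == "opposite"

    def test_zero_gene_fragment(self):
        rec = resolve_locations("A" * 20, [("c1", 0, 900, "+")])
        annotate_genes(rec, self.GENES)
        assert rec.contained_gene_tags == []


class TestBuildMap:
    def _truth_by_barcode(self, truth):
        return {r.barcode: r for r in truth.true_map}

    def test_error_free_reads_recover_truth_exactly(self, toy_truth):
        reads = sim_longreads(
            toy_truth.true_map, toy_truth.genome, seed=21, depth=5,
            error_model=ErrorModel(0, 0, 0),
        )
        records, summary = build_map(reads, toy_truth.genome, toy_truth.genes)
        tm = self._truth_by_barcode(toy_truth)
        assert summary.no_oligos == summary.concatemer == 0
        for rec in records:
            t = tm[rec.barcode]
            assert (rec.contig_id, rec.start, rec.end, rec.strand) == (
                t.contig_id, t.start, t.end, t.strand,
            )
            assert rec.contained_gene_tags == t.contained_gene_tags
        # every truth barcode that received >= 1 read is recovered
        assert len(records) == summary.barcodes_seen

    def test_one_pct_substitutions_recover_intervals(self, toy_truth):
        reads = sim_longreads(
            toy_truth.true_map, toy_truth.genome, seed=22, depth=8,
            error_model=ErrorModel(sub=0.01, ins=0.0, dele=0.0),
        )
        # Q20 bases put a 3-kb insert far above the default expected-error
        # cap, so raise it to exercise alignment robustness in isolation.
        params = AlignParams(max_expected_error=1e9)
        records, _ = build_map(reads, toy_truth.genome, toy_truth.genes, params=params)
        tm = self._truth_by_barcode(toy_truth)
        recovered = {
            r.barcode: r for r in records if r.barcode in tm and not r.multi_locus
        }
        close = sum(
            1
            for b, r in recovered.items()
            if abs(r.start - tm[b].start) <= 5 and abs(r.end - tm[b].end) <= 5
        )
        assert len(recovered) >= 0.99 * len(tm)
        assert close >= 0.99 * len(recovered)

    def test_expected_error_filter_rejects_low_quality(self, toy_truth):
        reads = sim_longreads(
            toy_truth.true_map[:20], toy_truth.genome, seed=23, depth=3,
            error_model=ErrorModel(sub=0.01, ins=0.0, dele=0.0),  # Q20
        )
        _, summary = build_map(reads, toy_truth.genome, toy_truth.genes)
        assert summary.high_expected_error > 0
        assert summary.barcodes_mapped == 0

    def test_zero_reads(self, toy_truth):
        records, summary = build_map([], toy_truth.genome, toy_truth.genes)
        assert records == [] and summary.total_reads == 0

    def test_read_order_invariance(self, toy_truth):
        reads = sim_longreads(
            toy_truth.true_map[:40], toy_truth.genome, seed=24, depth=4
        )
        fwd, _ = build_map(reads, toy_truth.genome, toy_truth.genes)
        rev, _ = build_map(reads[::-1], toy_truth.genome, toy_truth.genes)
        assert fwd == rev

    def test_every_record_has_support_and_barcode_length(self, toy_truth):
        reads = sim_longreads(
            toy_truth.true_map[:60], toy_truth.genome, seed=25, depth=4
        )
        records, _ = build_map(reads, toy_truth.genome, toy_truth.genes)
        assert all(r.read_support >= 1 and len(r.barcode) == 20 for r in records)
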
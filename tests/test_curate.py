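"""Hit curation: protein alignment vs. a dynamic-programming oracle, region
clustering, candidate scoring, causative selection, confirmation rules, and
recovery of planted beneficial genes end to end."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from bobaseq.curate import (
    CandidateScore,
    ScreenContext,
    SimilarityCache,
    cluster_protein_hits,
    cluster_regions,
    confirm_hit,
    curate,
    protein_align,
    score_candidates,
    select_causative,
)
from bobaseq.fitness import (
    FitnessRecord,
    InclusionRules,
    call_significant,
    fitness_table,
)
from bobaseq.model import BarcodeFragmentRecord, GeneAnnotation, SampleMeta
from bobaseq.simulate import sim_screen, sim_truth, strain_effect

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _rand_protein(rng, n):
    return "".join(rng.choice(list(AA), n))


def _mutate_protein(rng, seq, frac):
    out = list(seq)
    for i in rng.choice(len(seq), size=int(frac * len(seq)), replace=False):
        out[i] = AA[(AA.index(out[i]) + int(rng.integers(1, 20))) % 20]
    return "".join(out)


def _gotoh_local(a, b, gap_open=-11, gap_extend=-1):
    """Independent Smith-Waterman with affine gaps (full DP + traceback).

    Returns (score, identity, coverage-over-shorter), computed the same way
    the implementation defines them, but by exhaustive dynamic programming.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    F = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 diag, 2 up(E), 3 left(F)
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] + gap_open, E[i - 1, j] + gap_extend)
            F[i, j] = max(H[i, j - 1] + gap_open, F[i, j - 1] + gap_extend)
            diag = H[i - 1, j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            if H[i, j] == diag and H[i, j] > 0:
                ptr[i, j] = 1
            elif H[i, j] == E[i, j]:
                ptr[i, j] = 2
            elif H[i, j] == F[i, j]:
                ptr[i, j] = 3
            if H[i, j] > best:
                best, best_ij = H[i, j], (i, j)
    # traceback
    i, j = best_ij
    ident = cols = 0
    end_a, end_b = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        if ptr[i, j] == 1:
            cols += 1
            ident += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif ptr[i, j] == 2:
            # walk the whole gap run
            while E[i, j] == E[i - 1, j] + gap_extend and i > 1:
                cols += 1
                i -= 1
            cols += 1
            i -= 1
        elif ptr[i, j] == 3:
            while F[i, j] == F[i, j - 1] + gap_extend and j > 1:
                cols += 1
                j -= 1
            cols += 1
            j -= 1
        else:
            break
    span_a, span_b = end_a - i, end_b - j
    coverage = (span_a if n <= m else span_b) / min(n, m)
    identity = ident / cols if cols else 0.0
    return best, identity, coverage


class TestProteinAlign:
    def test_identical_sequences(self):
        rng = np.random.default_rng(1)
        p = _rand_protein(rng, 80)
        sim = protein_align(p, p)
        assert sim.pct_identity == 1.0 and sim.coverage == 1.0

    def test_prefix_has_full_coverage_of_shorter(self):
        rng = np.random.default_rng(2)
        p = _rand_protein(rng, 100)
        sim = protein_align(p, p[:50])
        assert sim.coverage == pytest.approx(1.0)
        assert sim.pct_identity == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = _rand_protein(rng, 120), _rand_protein(rng, 90)
        ab, ba = protein_align(a, b), protein_align(b, a)
        assert ab.pct_identity == pytest.approx(ba.pct_identity, abs=1e-9)
        assert ab.coverage == pytest.approx(ba.coverage, abs=1e-9)

    def test_against_dynamic_programming_oracle(self):
        from bobaseq.curate import _ALIGNER

        rng = np.random.default_rng(4)
        for trial in range(20):
            a = _rand_protein(rng, 200)
            if trial % 2 == 0:  # related pair: near-unique optimal path
                b = _mutate_protein(rng, a, 0.2)
            else:  # unrelated pair
                b = _rand_protein(rng, 200)
            o_score, o_ident, o_cov = _gotoh_local(a, b)
            assert _ALIGNER.align(a, b).score == pytest.approx(o_score)
            sim = protein_align(a, b)
            if trial % 2 == 0:
                assert sim.pct_identity == pytest.approx(o_ident, abs=0.02)
                assert sim.coverage == pytest.approx(o_cov, abs=0.05)


def _frag(bc, start, end, lib="lib1", contig="c1", tags=(), strand="+"):
    return BarcodeFragmentRecord(
        bc, lib, contig, start, end, strand, 3, list(tags)
    )


B = {f"b{i}": "ACGT"[i % 4] * 19 + "ACGT"[i // 4] for i in range(1, 7)}


class TestClusterRegions:
    KEY = ("cond", "", "1")

    def test_overlap_merges(self):
        regions = cluster_regions(
            [_frag(B["b1"], 0, 3000), _frag(B["b2"], 2500, 5500)], self.KEY
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 5500)

    def test_abutting_halfopen_stays_separate(self):
        regions = cluster_regions(
            [_frag(B["b1"], 0, 3000), _frag(B["b2"], 3000, 6000)], self.KEY
        )
        assert len(regions) == 2

    def test_single_linkage_chain(self):
        regions = cluster_regions(
            [
                _frag(B["b1"], 0, 3000),
                _frag(B["b2"], 2500, 6000),
                _frag(B["b3"], 5500, 9000),
            ],
            self.KEY,
        )
        assert len(regions) == 1
        assert set(regions[0].member_barcodes) == {B["b1"], B["b2"], B["b3"]}

    def test_partitions_input(self):
        frags = [
            _frag(B["b1"], 0, 3000),
            _frag(B["b2"], 10_000, 13_000),
            _frag(B["b3"], 12_000, 15_000, lib="lib2"),
        ]
        regions = cluster_regions(frags, self.KEY)
        members = [b for r in regions for b in r.member_barcodes]
        assert sorted(members) == sorted(r.barcode for r in frags)


class TestSelectCausative:
    def test_first_key_dominates(self):
        tags, status = select_causative(
            [CandidateScore("A", 4, 0, 6.1), CandidateScore("B", 2, 3, 9.9)]
        )
        assert tags == ["A"] and status == "auto"

    def test_second_key_breaks_tie(self):
        tags, _ = select_causative(
            [CandidateScore("A", 4, 1, 6.1), CandidateScore("B", 4, 3, 5.0)]
        )
        assert tags == ["B"]

    def test_exact_tie_returns_both_for_review(self):
        tags, status = select_causative(
            [CandidateScore("A", 4, 3, 6.1), CandidateScore("B", 4, 3, 6.1)]
        )
        assert tags == ["A", "B"] and status == "needs_review"


def _toy_screen_context(rng):
    """Two libraries, one condition, two replicates.

    Region 1 (lib1): b1 [800,2000) with gA; b2 [900,2700) with gA+gB; both
    pair-significant -> overlap-confirmed, causative gA.
    Region 2 (lib2): b3 alone with gH, a ~60%-identity homolog of gA ->
    similarity-confirmed.  b4 alone with unrelated gC -> unconfirmed.
    b5 carries gB with mediocre fitness (drags gB's mean down).
    """
    pA = _rand_protein(rng, 120)
    genes = {
        "gA": GeneAnnotation("gA", "c1", 1000, 1900, "+", pA),
        "gB": GeneAnnotation("gB", "c1", 2000, 2600, "+", _rand_protein(rng, 100)),
        "gC": GeneAnnotation("gC", "c1", 5200, 6000, "+", _rand_protein(rng, 110)),
        "gH": GeneAnnotation("gH", "c2", 500, 1400, "+", _mutate_protein(rng, pA, 0.4)),
    }
    mapping = {
        B["b1"]: _frag(B["b1"], 800, 2000, tags=["gA"]),
        B["b2"]: _frag(B["b2"], 900, 2700, tags=["gA", "gB"]),
        B["b3"]: _frag(B["b3"], 300, 1500, lib="lib2", contig="c2", tags=["gH"]),
        B["b4"]: _frag(B["b4"], 5000, 8000, tags=["gC"]),
        B["b5"]: _frag(B["b5"], 1950, 4000, tags=["gB"]),
    }
    samples = [
        SampleMeta("r1", "cond"),
        SampleMeta("r2", "cond", replicate=2),
    ]
    f = {B["b1"]: (7.0, 7.4), B["b2"]: (8.0, 8.4), B["b3"]: (6.0, 6.2),
         B["b4"]: (6.5, 6.6), B["b5"]: (0.5, 0.3)}
    records = [
        FitnessRecord(bc, exp, 100, 1, fi, 0.5, fi / 0.5)
        for bc, fs in f.items()
        for exp, fi in zip(("r1", "r2"), fs)
    ]
    calls = call_significant(records, samples)
    return ScreenContext(mapping, genes, calls, records, samples)


class TestScoringAndConfirmation:
    def test_candidate_scores(self):
        ctx = _toy_screen_context(np.random.default_rng(11))
        key = ("cond", "", "1")
        (region,) = [
            r for r in cluster_regions(
                [ctx.mapping[b] for b in sorted(ctx.calls.pairs[key])
                 if ctx.mapping[b].library_id == "lib1"
                 and ctx.mapping[b].start < 3000], key)
        ]
        scores = {s.locus_tag: s for s in score_candidates(region, ctx)}
        # gA sits in 2 pair-significant inserts, each replicate counted
        assert scores["gA"].n_beneficial_inserts == 4
        assert scores["gB"].n_beneficial_inserts == 2
        # gA has one homolog (gH) in another significant region
        assert scores["gA"].n_similar_in_high_regions == 1
        assert scores["gB"].n_similar_in_high_regions == 0
        # gB's mean fitness includes the weak b5 insert
        assert scores["gB"].mean_fitness_of_inserts == pytest.approx(
            (8.2 + 0.4) / 2
        )
        tags, status = select_causative(list(scores.values()))
        assert tags == ["gA"] and status == "auto"

    def test_confirmation_modes(self):
        ctx = _toy_screen_context(np.random.default_rng(11))
        hits = {h.region.member_barcodes[0]: h for h in curate(ctx)}
        by_tags = {tuple(h.causative_tags): h for h in hits.values()}
        overlap_hit = hits[B["b1"]]
        assert overlap_hit.confirmed_by in ("overlap", "both")
        assert overlap_hit.causative_tags == ["gA"]
        similarity_hit = hits[B["b3"]]
        assert similarity_hit.confirmed_by == "similarity"
        unconfirmed = hits[B["b4"]]
        assert unconfirmed.confirmed_by == "unconfirmed"

    def test_similarity_requires_other_region(self):
        # referential integrity: the similarity confirmation of b3 cites a
        # region that exists in the same condition
        ctx = _toy_screen_context(np.random.default_rng(11))
        region3 = [h.region for h in curate(ctx)
                   if h.region.member_barcodes == [B["b3"]]][0]
        assert confirm_hit(region3, ["gH"], ctx) == "similarity"

    def test_override_replaces_causative(self):
        ctx = _toy_screen_context(np.random.default_rng(11))
        plain = curate(ctx)
        rid = [h.region.region_id for h in plain if B["b1"] in h.region.member_barcodes][0]
        hits = curate(ctx, overrides={rid: ["gB"]})
        (hit,) = [h for h in hits if h.region.region_id == rid]
        assert hit.causative_tags == ["gB"] and hit.curation_status == "auto"


class TestClusterProteinHits:
    def test_chain_and_singletons(self):
        rng = np.random.default_rng(21)
        a = _rand_protein(rng, 150)
        b = _mutate_protein(rng, a, 0.45)
        c = _mutate_protein(rng, b, 0.45)
        lone = _rand_protein(rng, 150)
        sim = SimilarityCache({"a": a, "b": b, "c": c, "lone": lone})
        assert sim.similar("a", "b") and sim.similar("b", "c")
        assert not sim.similar("a", "c")
        clusters = cluster_protein_hits(["a", "b", "c", "lone"], sim)
        assert sorted(map(tuple, clusters)) == [("a", "b", "c"), ("lone",)]

    def test_mutually_similar_form_one_cluster(self):
        rng = np.random.default_rng(22)
        a = _rand_protein(rng, 150)
        sim = SimilarityCache(
            {"a": a, "b": _mutate_protein(rng, a, 0.2), "c": _mutate_protein(rng, a, 0.25)}
        )
        assert cluster_protein_hits(["a", "b", "c"], sim) == [["a", "b", "c"]]


class TestEndToEndRecovery:
    def test_planted_gene_recovered_as_causative(self):
        truth = sim_truth(seed=31, n_genes=200, n_barcodes=600,
                          conditions=("cond1",), planted_per_condition=1,
                          delta=8.0)
        cm, samples = sim_screen(truth.true_map, truth.planted_effects,
                                 ["cond1"], seed=32, depth=1_000_000)
        records, _ = fitness_table(cm, {"lib1": truth.true_map},
                                   InclusionRules(min_total_reads=10))
        calls = call_significant(records, samples)
        key = ("cond1", "", "1")
        carriers = {
            r.barcode for r in truth.true_map
            if strain_effect(r, truth.planted_effects, "cond1") > 0
        }
        assert carriers, "generator must plant a covered gene"
        assert carriers <= calls.pairs[key]
        ctx = ScreenContext(
            mapping={r.barcode: r for r in truth.true_map},
            genes={g.locus_tag: g for g in truth.genes},
            calls=calls,
            records=records,
            samples=samples,
        )
        hits = curate(ctx)
        (planted_tag,) = {t for (t, _c) in truth.planted_effects}
        causative = {t for h in hits for t in h.causative_tags}
        assert planted_tag in causative
        carrier_hits = [h for h in hits if set(h.region.member_barcodes) & carriers]
        assert all(h.confirmed_by in ("overlap", "both") for h in carrier_hits)
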
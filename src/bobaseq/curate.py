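"""Group significant inserts into regions and pick the causative protein.

Barcodes that pass the fitness and z thresholds in both replicates are
clustered into genomic *regions* (single-linkage interval overlap within a
library and contig, per condition).  A region is *biologically consistent*
when confirmed by a second overlapping significant insert, or when its
likely causative protein has a homolog (>= 40% identity, >= 75% coverage)
inside a significant insert of a different region in the same condition.
The causative protein of a region is chosen among the proteins fully
contained in the region's best insert by lexicographic maximization of
(beneficial-insert count, similar-protein count, mean insert fitness);
residual exact ties are all reported and flagged for review, mirroring a
manual curation step.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .fitness import FitnessRecord, SignificanceCalls, replicate_mean_fitness
from .model import (
    BarcodeFragmentRecord,
    GeneAnnotation,
    SampleMeta,
    intervals_intersect,
)

ID_THRESHOLD = 0.40
COV_THRESHOLD = 0.75


@dataclass(frozen=True)
class ProteinSimilarity:
    query_tag: str
    subject_tag: str
    pct_identity: float
    coverage: float


@dataclass
class Region:
    region_id: str
    library_id: str
    contig_id: str
    start: int
    end: int
    member_barcodes: list[str]
    condition: str
    key: tuple  # (condition, concentration, day) experiment group


@dataclass
class CandidateScore:
    locus_tag: str
    n_beneficial_inserts: int
    n_similar_in_high_regions: int
    mean_fitness_of_inserts: float

    def sort_key(self):
        return (
            self.n_beneficial_inserts,
            self.n_similar_in_high_regions,
            self.mean_fitness_of_inserts,
        )


@dataclass
class CuratedHit:
    region: Region
    confirmed_by: str  # overlap | similarity | both | unconfirmed
    candidate_scores: list[CandidateScore] = field(default_factory=list)
    causative_tags: list[str] = field(default_factory=list)
    curation_status: str = "auto"  # auto | needs_review


# ---------------------------------------------------------------------------
# Protein alignment


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def protein_align(seq_a: str, seq_b: str) -> ProteinSimilarity:
    """Local BLOSUM62 alignment (gap open -11, extend -1).

    ``pct_identity`` is identities over aligned columns (gap columns
    included); ``coverage`` is the aligned span of the shorter sequence over
    its length, so a sequence against its own prefix scores coverage 1.0.
    """
    if not seq_a or not seq_b:
        raise ValueError("protein sequences must be non-empty")
    alignments = _ALIGNER.align(seq_a, seq_b)
    try:
        aln = alignments[0]
    except IndexError:  # no positive-scoring local alignment
        return ProteinSimilarity("a", "b", 0.0, 0.0)
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    if columns == 0:
        return ProteinSimilarity("a", "b", 0.0, 0.0)
    blocks_a, blocks_b = aln.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    if len(seq_a) <= len(seq_b):
        coverage = span_a / len(seq_a)
    else:
        coverage = span_b / len(seq_b)
    return ProteinSimilarity(
        "a", "b", counts.identities / columns, min(1.0, coverage)
    )


class SimilarityCache:
    """Memoized pairwise protein similarity over a tag -> sequence table."""

    def __init__(self, proteomes: dict[str, str]):
        self.proteomes = proteomes
        self._cache: dict[tuple[str, str], ProteinSimilarity] = {}

    def similar(
        self,
        tag_a: str,
        tag_b: str,
        min_identity: float = ID_THRESHOLD,
        min_coverage: float = COV_THRESHOLD,
    ) -> bool:
        sim = self.get(tag_a, tag_b)
        return sim.pct_identity >= min_identity and sim.coverage >= min_coverage

    def get(self, tag_a: str, tag_b: str) -> ProteinSimilarity:
        key = (tag_a, tag_b) if tag_a <= tag_b else (tag_b, tag_a)
        if key not in self._cache:
            a, b = self.proteomes.get(key[0], ""), self.proteomes.get(key[1], "")
            if not a or not b:
                sim = ProteinSimilarity(key[0], key[1], 0.0, 0.0)
            else:
                raw = protein_align(a, b)
                sim = ProteinSimilarity(
                    key[0], key[1], raw.pct_identity, raw.coverage
                )
            self._cache[key] = sim
        return self._cache[key]


# ---------------------------------------------------------------------------
# Region clustering


def cluster_regions(
    records: list[BarcodeFragmentRecord], key: tuple
) -> list[Region]:
    """Single-linkage overlap clustering of pair-significant inserts within
    each (library, contig); half-open abutting intervals do not join.
    Regions come back ordered by (library, contig, leftmost start)."""
    groups: dict[tuple[str, str], list[BarcodeFragmentRecord]] = defaultdict(list)
    for r in records:
        groups[(r.library_id, r.contig_id)].append(r)
    regions: list[Region] = []
    for (lib, contig) in sorted(groups):
        members = sorted(groups[(lib, contig)], key=lambda r: (r.start, r.end, r.barcode))
        cluster = [members[0]]
        cur_end = members[0].end
        for r in members[1:]:
            if r.start < cur_end:
                cluster.append(r)
                cur_end = max(cur_end, r.end)
            else:
                regions.append(_make_region(cluster, lib, contig, key))
                cluster = [r]
                cur_end = r.end
        regions.append(_make_region(cluster, lib, contig, key))
    return regions


def _make_region(cluster, lib, contig, key) -> Region:
    start = min(r.start for r in cluster)
    end = max(r.end for r in cluster)
    condition = key[0]
    rid = f"{condition}|{lib}|{contig}:{start}-{end}"
    return Region(
        region_id=rid,
        library_id=lib,
        contig_id=contig,
        start=start,
        end=end,
        member_barcodes=[r.barcode for r in cluster],
        condition=condition,
        key=key,
    )


# ---------------------------------------------------------------------------
# Candidate scoring and causative selection


@dataclass
class ScreenContext:
    """Everything curation needs about one screen.

    ``mapping`` indexes uniquely-mapped records by barcode; ``genes`` maps
    locus_tag -> annotation (tags assumed unique across libraries);
    ``calls`` carries single- and pair-replicate significance; fitness
    records supply replicate-averaged scores.
    """

    mapping: dict[str, BarcodeFragmentRecord]
    genes: dict[str, GeneAnnotation]
    calls: SignificanceCalls
    records: list[FitnessRecord]
    samples: list[SampleMeta]

    def __post_init__(self):
        self.mean_fitness = replicate_mean_fitness(self.records, self.samples)
        self.similarity = SimilarityCache(
            {t: g.protein_seq for t, g in self.genes.items() if g.protein_seq}
        )
        self._by_sample = {s.sample_id: s for s in self.samples}
        # barcode -> contained tags, precomputed once
        self.tags_of = {
            b: set(r.contained_gene_tags) for b, r in self.mapping.items()
        }

    def experiments_in_condition(self, condition: str) -> list[str]:
        return [
            e
            for key, exps in self.calls.pair_experiments.items()
            if key[0] == condition
            for e in exps
        ]

    def barcodes_with_tag(self, tag: str) -> set[str]:
        return {b for b, tags in self.tags_of.items() if tag in tags}


def score_candidates(
    region: Region, ctx: ScreenContext
) -> list[CandidateScore]:
    """Score the proteins of the region's top insert.

    The top insert is the member with the highest replicate-averaged
    fitness; candidates are the genes fully contained in it.  Scores:
    (1) significantly beneficial inserts containing the protein, replicates
    counted separately; (2) distinct similar proteins inside other
    significant regions of the same condition; (3) mean replicate-averaged
    fitness over all inserts containing the protein.
    """
    mean_f = ctx.mean_fitness.get(region.key, {})
    top = max(
        region.member_barcodes,
        key=lambda b: (mean_f.get(b, float("-inf")), b),
    )
    candidates = sorted(ctx.tags_of.get(top, ()))
    if not candidates:
        return []

    condition = region.condition
    exps = ctx.experiments_in_condition(condition)
    other_region_tags = _tags_in_other_regions(region, ctx)

    scores = []
    for tag in candidates:
        carriers = ctx.barcodes_with_tag(tag)
        n_beneficial = sum(
            1
            for e in exps
            for b in carriers
            if b in ctx.calls.single.get(e, ())
        )
        n_similar = sum(
            1 for other in sorted(other_region_tags) if ctx.similarity.similar(tag, other)
        )
        fvals = [mean_f[b] for b in carriers if b in mean_f]
        mean_fitness = sum(fvals) / len(fvals) if fvals else float("-inf")
        scores.append(CandidateScore(tag, n_beneficial, n_similar, mean_fitness))
    return scores


def _tags_in_other_regions(region: Region, ctx: ScreenContext) -> set[str]:
    """Locus tags contained in pair-significant inserts of *other* regions
    of the same condition (any library)."""
    tags: set[str] = set()
    for key, barcodes in ctx.calls.pairs.items():
        if key[0] != region.condition:
            continue
        for b in barcodes:
            r = ctx.mapping.get(b)
            if r is None:
                continue
            if (
                key == region.key
                and r.library_id == region.library_id
                and r.contig_id == region.contig_id
                and intervals_intersect(r.start, r.end, region.start, region.end)
            ):
                continue  # the region itself
            tags |= ctx.tags_of.get(b, set())
    return tags


def select_causative(
    candidate_scores: list[CandidateScore],
) -> tuple[list[str], str]:
    """Lexicographic maximization over (beneficial inserts, similar
    proteins, mean fitness); exact ties return every tied tag and flag the
    region for review."""
    if not candidate_scores:
        raise ValueError("no candidates to select from")
    best = max(s.sort_key() for s in candidate_scores)
    tags = sorted(s.locus_tag for s in candidate_scores if s.sort_key() == best)
    status = "auto" if len(tags) == 1 else "needs_review"
    return tags, status


# ---------------------------------------------------------------------------
# Confirmation and the full curation pass


def confirm_hit(
    region: Region, causative_tags: list[str], ctx: ScreenContext
) -> str:
    """overlap | similarity | both | unconfirmed."""
    overlap = len(set(region.member_barcodes)) >= 2
    similarity = False
    other_tags = _tags_in_other_regions(region, ctx)
    for tag in causative_tags:
        if any(ctx.similarity.similar(tag, other) for other in sorted(other_tags)):
            similarity = True
            break
    if overlap and similarity:
        return "both"
    if overlap:
        return "overlap"
    if similarity:
        return "similarity"
    return "unconfirmed"


def curate(
    ctx: ScreenContext,
    overrides: dict[str, list[str]] | None = None,
) -> list[CuratedHit]:
    """Full curation pass over every replicate-pair experiment group.

    Returns one :class:`CuratedHit` per region, confirmed or not; consistent
    hits are those with ``confirmed_by != 'unconfirmed'``.  ``overrides``
    (region_id -> tags) substitutes manually curated causative calls.
    """
    hits: list[CuratedHit] = []
    for key in sorted(ctx.calls.pairs):
        sig = ctx.calls.pairs[key]
        records = [
            ctx.mapping[b] for b in sorted(sig) if b in ctx.mapping
        ]
        if not records:
            continue
        for region in cluster_regions(records, key):
            scores = score_candidates(region, ctx)
            if not scores:
                hits.append(
                    CuratedHit(region, "unconfirmed", [], [], "needs_review")
                )
                continue
            tags, status = select_causative(scores)
            confirmed = confirm_hit(region, tags, ctx)
            if overrides and region.region_id in overrides:
                tags = list(overrides[region.region_id])
                status = "auto"
            hits.append(CuratedHit(region, confirmed, scores, tags, status))
    return hits


def cluster_protein_hits(
    causative_tags: list[str],
    similarity: SimilarityCache,
    min_identity: float = ID_THRESHOLD,
    min_coverage: float = COV_THRESHOLD,
) -> list[list[str]]:
    """Single-linkage clusters of causative proteins by pairwise similarity
    (identity >= 40% and coverage >= 75% joins two proteins)."""
    tags = sorted(set(causative_tags))
    parent = {t: t for t in tags}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            if similarity.similar(a, b, min_identity, min_coverage):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, list[str]] = defaultdict(list)
    for t in tags:
        clusters[find(t)].append(t)
    return [sorted(v) for _k, v in sorted(clusters.items())]
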
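"""Map long-read amplicons to a barcode -> insert table.

Each amplicon carries a 20-nt random barcode and a sheared genomic insert,
both bracketed by fixed 15-bp anchor oligos:

    ... A1 [barcode] A2 ... A3 [insert] A4 ...

The pipeline demultiplexes by terminal dual indexes, extracts cassettes
(rejecting concatemers, wrong-length barcodes and inserts with expected
error > 10), aligns inserts to the reference by k-mer seeding plus
alignment-path rescoring, resolves barcodes seen at several locations, and
annotates fully contained genes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .model import (
    BarcodeFragmentRecord,
    GeneAnnotation,
    Genome,
    gene_contained,
    revcomp,
)

BARCODE_LEN = 20
OLIGO_LEN = 15

# Match +1, mismatch -2, gap open -4, gap extend -1 (standard DNA weights;
# used to rescore and rank alignment paths).
MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1


@dataclass(frozen=True)
class OligoSet:
    """The four fixed 15-bp anchors flanking barcode and insert."""

    barcode_left: str
    barcode_right: str
    insert_left: str
    insert_right: str
    max_mismatches_per_oligo: int = 2

    def __post_init__(self):
        oligos = self.oligos()
        if any(len(o) != OLIGO_LEN for o in oligos):
            raise ValueError(f"anchor oligos must be {OLIGO_LEN} bp")
        if len(set(oligos)) != 4:
            raise ValueError("anchor oligos must be mutually distinct")

    def oligos(self) -> tuple[str, str, str, str]:
        return (
            self.barcode_left,
            self.barcode_right,
            self.insert_left,
            self.insert_right,
        )


# Synthetic default anchors (real amplicon designs supply their own four).
DEFAULT_OLIGOS = OligoSet(
    barcode_left="CTAAGGTAGCGACTG",
    barcode_right="ATCGATCCGGCTAGT",
    insert_left="GGTCTCACTGGAACC",
    insert_right="TTCAGGACGCATAGC",
)


@dataclass
class CassetteExtract:
    read_id: str
    barcode: str = ""
    insert_seq: str = ""
    insert_quals: list[int] = field(default_factory=list)
    orientation: str = "forward"  # strand of the read carrying the layout
    reject_reason: str | None = None  # no_oligos | concatemer |
    # bad_barcode_length | high_expected_error

    @property
    def accepted(self) -> bool:
        return self.reject_reason is None


@dataclass
class InsertAlignment:
    contig_id: str
    start: int
    end: int
    strand: str
    pct_coverage: float
    pct_identity: float
    score: int

    def sort_key(self):
        return (-self.score, self.contig_id, self.start, self.strand)


@dataclass
class AlignParams:
    k: int = 15
    min_coverage: float = 0.80
    min_identity: float = 0.90
    max_expected_error: float = 10.0
    band_fraction: float = 0.15  # window padding relative to insert length


@dataclass
class MapSummary:
    total_reads: int = 0
    unassigned: int = 0
    no_oligos: int = 0
    concatemer: int = 0
    bad_barcode_length: int = 0
    high_expected_error: int = 0
    unaligned: int = 0
    barcodes_seen: int = 0
    barcodes_mapped: int = 0
    multi_locus: int = 0

    @property
    def fraction_barcodes_mapped(self) -> float:
        if self.barcodes_seen == 0:
            return 0.0
        return self.barcodes_mapped / self.barcodes_seen


# ---------------------------------------------------------------------------
# Oligo search


def find_oligo(seq: str, oligo: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where a window of len(oligo) matches
    ``oligo`` with at most ``max_mismatches`` substitutions.

    Single-strand scan; callers cover the reverse strand by searching the
    reverse complement of the read.
    """
    m = len(oligo)
    n = len(seq)
    if n < m:
        return []
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j, c in enumerate(oligo.encode()):
        mism += s[j : j + n - m + 1] != c
    pos = np.nonzero(mism <= max_mismatches)[0]
    return [(int(p), int(mism[p])) for p in pos]


def expected_error(quals) -> float:
    """Sum of per-base error probabilities, Sigma 10^(-Q/10)."""
    if len(quals) == 0:
        return 0.0
    q = np.asarray(quals, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


# ---------------------------------------------------------------------------
# Cassette extraction


def _layout_hits(seq: str, oligos: OligoSet):
    tol = oligos.max_mismatches_per_oligo
    return [find_oligo(seq, o, tol) for o in oligos.oligos()]


def extract_cassette(read, oligos: OligoSet) -> CassetteExtract:
    """Pull barcode and insert out of one read.

    The strand is chosen as the one presenting the full four-anchor layout;
    any anchor occurring more than once on that strand marks a concatemer,
    and a barcode span != 20 nt is rejected.  Rejections are data, not
    errors.
    """
    read_id, seq, quals = read
    fwd = _layout_hits(seq, oligos)
    if all(h for h in fwd):
        hits, oriented_seq, oriented_quals, orientation = fwd, seq, quals, "forward"
    else:
        rc = revcomp(seq)
        rev = _layout_hits(rc, oligos)
        if all(h for h in rev):
            hits, oriented_seq, orientation = rev, rc, "reverse"
            oriented_quals = list(reversed(quals))
        else:
            return CassetteExtract(read_id, reject_reason="no_oligos")

    if any(len(h) > 1 for h in hits):
        return CassetteExtract(
            read_id, orientation=orientation, reject_reason="concatemer"
        )

    a1, a2, a3, a4 = (h[0][0] for h in hits)
    if not (a1 < a2 < a3 < a4):
        return CassetteExtract(
            read_id, orientation=orientation, reject_reason="no_oligos"
        )
    barcode = oriented_seq[a1 + OLIGO_LEN : a2]
    if len(barcode) != BARCODE_LEN:
        return CassetteExtract(
            read_id, orientation=orientation, reject_reason="bad_barcode_length"
        )
    insert = oriented_seq[a3 + OLIGO_LEN : a4]
    if not insert:
        return CassetteExtract(
            read_id, orientation=orientation, reject_reason="no_oligos"
        )
    return CassetteExtract(
        read_id,
        barcode=barcode,
        insert_seq=insert,
        insert_quals=oriented_quals[a3 + OLIGO_LEN : a4],
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# Demultiplexing by terminal dual indexes

INDEX_LEN = 16


def check_index_pairs(index_pairs: dict, max_mismatches: int = 1) -> None:
    """Reject index tables where two libraries sit within the combined
    Hamming tolerance of each other (a read could match both)."""
    pairs = list(index_pairs)
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            d = _hamming(pairs[i][0], pairs[j][0]) + _hamming(
                pairs[i][1], pairs[j][1]
            )
            if d <= 2 * max_mismatches:
                raise ValueError(
                    f"index collision between {index_pairs[pairs[i]]!r} and "
                    f"{index_pairs[pairs[j]]!r} (combined distance {d})"
                )


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def _match_indexes(seq, index_pairs, tol):
    head = seq[:INDEX_LEN]
    tail = revcomp(seq[-INDEX_LEN:])
    for (i5, i7), lib in index_pairs.items():
        if _hamming(head, i5) <= tol and _hamming(tail, i7) <= tol:
            return lib
    return None


def demultiplex(reads, index_pairs: dict, max_mismatches: int = 1):
    """Assign reads to libraries by dual 16-nt terminal indexes.

    ``index_pairs`` maps (i5, i7) -> library_id; the i5 index opens the read
    and the reverse complement of i7 closes it.  Both read orientations are
    tried.  Returns (library_id -> reads, n_unassigned).
    """
    check_index_pairs(index_pairs, max_mismatches)
    out: dict[str, list] = defaultdict(list)
    unassigned = 0
    for read in reads:
        seq = read[1]
        lib = _match_indexes(seq, index_pairs, max_mismatches)
        if lib is None:
            lib = _match_indexes(revcomp(seq), index_pairs, max_mismatches)
        if lib is None:
            unassigned += 1
        else:
            out[lib].append(read)
    return dict(out), unassigned


# ---------------------------------------------------------------------------
# Insert alignment: k-mer seed, window, alignment-path rescoring


class GenomeIndex:
    """Exact k-mer index over the forward strands of all contigs."""

    def __init__(self, genome: Genome, k: int = 15):
        if min(len(s) for s in genome.contigs.values()) < k:
            raise ValueError(f"genome contig shorter than seed k={k}")
        self.genome = genome
        self.k = k
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for cid, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    index[kmer].append((cid, i))
        self.index = dict(index)

    def seed_hits(self, query: str, step: int = 1):
        """(contig, strand, qpos, tpos) seed matches for both query strands."""
        k = self.k
        hits = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            for qpos in range(0, len(q) - k + 1, step):
                for cid, tpos in self.index.get(q[qpos : qpos + k], ()):
                    hits.append((cid, strand, qpos, tpos))
        return hits


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _score_and_identity(cigar: str):
    """(score, matches, columns, leading/trailing query-only bases)."""
    ops = list(_cigar_ops(cigar))
    # Trim terminal insertions (query bases hanging off the aligned span).
    lead = trail = 0
    if ops and ops[0][1] == "I":
        lead = ops[0][0]
        ops = ops[1:]
    if ops and ops[-1][1] == "I":
        trail = ops[-1][0]
        ops = ops[:-1]
    score = 0
    matches = 0
    columns = 0
    for n, op in ops:
        columns += n
        if op == "=":
            matches += n
            score += MATCH * n
        elif op == "X":
            score += MISMATCH * n
        elif op in ("I", "D"):
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
        else:  # pragma: no cover - edlib emits =,X,I,D only
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return score, matches, columns, lead, trail


def _candidate_windows(hits, qlen, band):
    """Cluster seed hits into candidate (contig, strand, tstart, tend)."""
    by_key = defaultdict(list)
    for cid, strand, qpos, tpos in hits:
        by_key[(cid, strand)].append((tpos - qpos, qpos, tpos))
    windows = []
    for (cid, strand), diag_hits in by_key.items():
        diag_hits.sort()
        cluster = [diag_hits[0]]
        for h in diag_hits[1:]:
            if h[0] - cluster[-1][0] <= band:
                cluster.append(h)
            else:
                windows.append((cid, strand, cluster))
                cluster = [h]
        windows.append((cid, strand, cluster))
    out = []
    for cid, strand, cluster in windows:
        diags = [c[0] for c in cluster]
        lo = min(diags) - band
        hi = max(diags) + qlen + band
        out.append((cid, strand, max(0, lo), hi, len(cluster)))
    # Strongest seed support first keeps work bounded on repetitive input.
    out.sort(key=lambda w: (-w[4], w[0], w[2]))
    return out[:8]


def align_insert(
    insert_seq: str,
    index: GenomeIndex | Genome,
    params: AlignParams | None = None,
) -> list[InsertAlignment]:
    """Align one insert to the reference.

    Seeds exact k-mers on both strands, opens a padded window around each
    co-linear seed cluster, aligns the full insert inside the window, and
    rescores the alignment path with match +1 / mismatch -2 / gap -4,-1.
    Alignments passing ``min_coverage`` and ``min_identity`` are returned
    best score first.
    """
    params = params or AlignParams()
    if isinstance(index, Genome):
        index = GenomeIndex(index, params.k)
    qlen = len(insert_seq)
    if qlen < 2 * index.k:
        return []
    band = max(16, int(params.band_fraction * qlen))
    step = max(1, index.k // 3)
    hits = index.seed_hits(insert_seq, step=step)
    results = []
    seen_spans = set()
    for cid, strand, lo, hi, _n in _candidate_windows(hits, qlen, band):
        target = index.genome.contigs[cid][int(lo) : int(hi)]
        query = insert_seq if strand == "+" else revcomp(insert_seq)
        aln = edlib.align(query, target, mode="HW", task="path")
        if aln["editDistance"] < 0 or not aln.get("cigar"):
            continue
        t0, t1 = aln["locations"][0]
        score, matches, columns, lead, trail = _score_and_identity(aln["cigar"])
        if columns == 0:
            continue
        start = int(lo) + t0
        end = int(lo) + t1 + 1
        span = (cid, strand, start, end)
        if span in seen_spans:
            continue
        seen_spans.add(span)
        coverage = (qlen - lead - trail) / qlen
        identity = matches / columns
        if coverage >= params.min_coverage and identity >= params.min_identity:
            results.append(
                InsertAlignment(cid, start, end, strand, coverage, identity, score)
            )
    results.sort(key=InsertAlignment.sort_key)
    return results


# ---------------------------------------------------------------------------
# Location resolution and gene annotation


def _consensus_interval(members: Counter) -> tuple[int, int, str, int]:
    """Per-boundary read-weighted mode over exact member locations;
    ties break toward the smaller coordinate ('+' for strand)."""
    starts: Counter = Counter()
    ends: Counter = Counter()
    strands: Counter = Counter()
    total = 0
    for (start, end, strand), n in members.items():
        starts[start] += n
        ends[end] += n
        strands[strand] += n
        total += n
    start = min(s for s, c in starts.items() if c == max(starts.values()))
    end = min(e for e, c in ends.items() if c == max(ends.values()))
    strand = "+" if strands["+"] >= strands["-"] else "-"
    if end <= start:  # degenerate mode combination; fall back to widest span
        start = min(s for s, _e, _x in members)
        end = max(e for _s, e, _x in members)
    return start, end, strand, total


def resolve_locations(
    barcode: str,
    read_locations: list[tuple[str, int, int, str]],
    library_id: str = "lib1",
) -> BarcodeFragmentRecord:
    """Collapse one barcode's per-read locations into a mapping record.

    Locations on the same contig that intersect are grouped (single
    linkage); one connected group resolves to its read-weighted consensus
    interval.  Several disconnected groups mark the barcode ``multi_locus``
    (excluded from fitness downstream), the top-read-count group becoming
    the primary row and the rest ``alt_locations``.
    """
    if not read_locations:
        raise ValueError(f"{barcode}: no read locations to resolve")
    by_contig: dict[str, list] = defaultdict(list)
    for contig, start, end, strand in read_locations:
        by_contig[contig].append((start, end, strand))

    groups = []  # (contig, Counter{(start,end,strand): reads})
    for contig in sorted(by_contig):
        locs = sorted(by_contig[contig])
        current = Counter({locs[0]: 1})
        cur_end = locs[0][1]
        for loc in locs[1:]:
            if loc[0] < cur_end:  # intersects the growing component
                current[loc] += 1
                cur_end = max(cur_end, loc[1])
            else:
                groups.append((contig, current))
                current = Counter({loc: 1})
                cur_end = loc[1]
        groups.append((contig, current))

    resolved = []
    for contig, members in groups:
        start, end, strand, reads = _consensus_interval(members)
        resolved.append((contig, start, end, strand, reads))
    resolved.sort(key=lambda g: (-g[4], g[0], g[1]))

    primary = resolved[0]
    alts = [(c, s, e, n) for c, s, e, _x, n in resolved[1:]]
    return BarcodeFragmentRecord(
        barcode=barcode,
        library_id=library_id,
        contig_id=primary[0],
        start=primary[1],
        end=primary[2],
        strand=primary[3],
        read_support=primary[4],
        multi_locus=bool(alts),
        alt_locations=alts,
    )


def annotate_genes(
    record: BarcodeFragmentRecord, genes: list[GeneAnnotation]
) -> BarcodeFragmentRecord:
    """Attach locus tags of genes fully contained in the primary interval.

    A gene counts only when completely inside the insert; orientation vs.
    the promoter is available per gene via ``record.gene_orientation``.
    """
    contained = [
        g
        for g in genes
        if g.contig_id == record.contig_id
        and gene_contained(g, record.start, record.end)
    ]
    contained.sort(key=lambda g: g.start)
    record.contained_gene_tags = [g.locus_tag for g in contained]
    return record


# ---------------------------------------------------------------------------
# Full pipeline


def build_map(
    long_reads,
    genome: Genome,
    genes: list[GeneAnnotation],
    oligos: OligoSet = DEFAULT_OLIGOS,
    params: AlignParams | None = None,
    index_pairs: dict | None = None,
    library_id: str = "lib1",
) -> tuple[list[BarcodeFragmentRecord], MapSummary]:
    """Run demultiplex -> extract -> filter -> align -> resolve -> annotate.

    With ``index_pairs`` unset all reads belong to ``library_id``.  Records
    come back sorted by (library, barcode); the summary counts rejections
    per reason.
    """
    params = params or AlignParams()
    summary = MapSummary()
    long_reads = list(long_reads)
    summary.total_reads = len(long_reads)

    if index_pairs:
        by_lib, summary.unassigned = demultiplex(long_reads, index_pairs)
    else:
        by_lib = {library_id: long_reads}

    gindex = GenomeIndex(genome, params.k)
    records: list[BarcodeFragmentRecord] = []
    for lib in sorted(by_lib):
        per_barcode: dict[str, list] = defaultdict(list)
        seen_barcodes: set[str] = set()
        for read in by_lib[lib]:
            extract = extract_cassette(read, oligos)
            if not extract.accepted:
                setattr(
                    summary,
                    extract.reject_reason,
                    getattr(summary, extract.reject_reason) + 1,
                )
                continue
            if expected_error(extract.insert_quals) > params.max_expected_error:
                summary.high_expected_error += 1
                continue
            seen_barcodes.add(extract.barcode)
            alignments = align_insert(extract.insert_seq, gindex, params)
            if not alignments:
                summary.unaligned += 1
                continue
            best = alignments[0]
            per_barcode[extract.barcode].append(
                (best.contig_id, best.start, best.end, best.strand)
            )
        summary.barcodes_seen += len(seen_barcodes)
        for barcode in sorted(per_barcode):
            record = resolve_locations(barcode, per_barcode[barcode], lib)
            annotate_genes(record, genes)
            records.append(record)
            summary.barcodes_mapped += 1
            if record.multi_locus:
                summary.multi_locus += 1
    return records, summary
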
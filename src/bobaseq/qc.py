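"""Library characterization statistics and the missing-gene analysis.

"Coverage" here is fragment depth: every uniquely-mapped fragment adds 1 to
every base it spans, and a gene counts as covered only when a fragment
contains it full-length.  Multi-locus barcodes are excluded from all
statistics, consistent with their exclusion from fitness.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .curate import SimilarityCache
from .model import BarcodeFragmentRecord, GeneAnnotation, Genome

WINDOW_BP = 20_000


@dataclass
class LibraryStats:
    n_barcodes: int
    median_fragment_bp: float
    pct_genes_covered: float
    per_gene_fragment_counts: dict[str, int]
    genes_per_fragment_hist: dict[int, int]
    strand_bias_ratio: float
    base_coverage_windows: dict[str, list[tuple[int, float]]]
    fragment_lengths: list[int] = field(default_factory=list)

    @property
    def median_per_gene_coverage(self) -> float:
        if not self.per_gene_fragment_counts:
            return 0.0
        return float(np.median(list(self.per_gene_fragment_counts.values())))


def _unique_records(records) -> list[BarcodeFragmentRecord]:
    return [r for r in records if not r.multi_locus]


def contained_genes_per_fragment(
    records: list[BarcodeFragmentRecord], genes: list[GeneAnnotation]
) -> list[list[int]]:
    """For each record, the indices of genes it fully contains."""
    by_contig: dict[str, list[tuple[int, int, int]]] = {}
    for i, g in enumerate(genes):
        by_contig.setdefault(g.contig_id, []).append((g.start, g.end, i))
    sorted_contigs = {
        c: (
            np.array([t[0] for t in sorted(v)]),
            np.array([t[1] for t in sorted(v)]),
            np.array([t[2] for t in sorted(v)]),
        )
        for c, v in ((c, v) for c, v in by_contig.items())
    }
    out: list[list[int]] = []
    for r in records:
        if r.contig_id not in sorted_contigs:
            out.append([])
            continue
        gs, ge, gi = sorted_contigs[r.contig_id]
        lo = int(np.searchsorted(gs, r.start, side="left"))
        hi = int(np.searchsorted(gs, r.end, side="left"))
        inside = ge[lo:hi] <= r.end
        out.append([int(x) for x in gi[lo:hi][inside]])
    return out


def library_stats(
    records: list[BarcodeFragmentRecord],
    genes: list[GeneAnnotation],
    genome: Genome,
    window_bp: int = WINDOW_BP,
) -> LibraryStats:
    """Fragment-level QC over a resolved mapping table.

    Returns per-gene full-containment fragment counts, the percentage of
    genes covered at least once, the genes-per-fragment histogram (0 is the
    first bin), the ratio of contained gene instances oriented opposite vs.
    same as the promoter, and mean per-base fragment depth in consecutive
    windows.
    """
    unique = _unique_records(records)
    if not unique:
        return LibraryStats(0, 0.0, 0.0, {g.locus_tag: 0 for g in genes}, {}, float("nan"), {})

    contained = contained_genes_per_fragment(unique, genes)
    per_gene = {g.locus_tag: 0 for g in genes}
    hist: Counter = Counter()
    same = opposite = 0
    for rec, idxs in zip(unique, contained):
        hist[len(idxs)] += 1
        for i in idxs:
            g = genes[i]
            per_gene[g.locus_tag] += 1
            if rec.gene_orientation(g) == "same":
                same += 1
            else:
                opposite += 1

    windows: dict[str, list[tuple[int, float]]] = {}
    for cid, seq in genome.contigs.items():
        depth_delta = np.zeros(len(seq) + 1, dtype=np.int64)
        for r in unique:
            if r.contig_id == cid:
                depth_delta[r.start] += 1
                depth_delta[min(r.end, len(seq))] -= 1
        depth = np.cumsum(depth_delta[:-1])
        windows[cid] = [
            (w, float(depth[w : w + window_bp].mean()))
            for w in range(0, len(seq), window_bp)
        ]

    lengths = [r.end - r.start for r in unique]
    n_covered = sum(1 for n in per_gene.values() if n >= 1)
    return LibraryStats(
        n_barcodes=len(unique),
        median_fragment_bp=float(np.median(lengths)),
        pct_genes_covered=100.0 * n_covered / len(genes) if genes else 0.0,
        per_gene_fragment_counts=per_gene,
        genes_per_fragment_hist=dict(sorted(hist.items())),
        strand_bias_ratio=(opposite / same) if same else float("nan"),
        base_coverage_windows=windows,
        fragment_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# Missing-gene analysis


@dataclass
class GeneFlags:
    unmapped: bool = False
    long: bool = False  # > 1.5 kb
    duplicated: bool = False  # >= 95% identity elsewhere in the same genome
    homolog_also_missing: bool = False


@dataclass
class MissingGeneSummary:
    flags: dict[str, GeneFlags]
    median_missing_bp: float
    median_mapped_bp: float


def missing_gene_analysis(
    genes_by_library: dict[str, list[GeneAnnotation]],
    records_by_library: dict[str, list[BarcodeFragmentRecord]],
    long_bp: int = 1500,
    dup_identity: float = 0.95,
    homolog_identity: float = 0.40,
    homolog_coverage: float = 0.75,
) -> MissingGeneSummary:
    """Why are some genes absent from the mapped library?

    A gene is *unmapped* when no uniquely-mapped fragment of its own library
    fully contains it.  Unmapped genes are annotated as long (> 1.5 kb),
    duplicated (a >= 95%-identity copy elsewhere in the same genome), or —
    for the remainder — sharing a homolog (>= 40% identity, >= 75%
    coverage, any library) that is itself unmapped.
    """
    proteomes: dict[str, str] = {}
    library_of: dict[str, str] = {}
    for lib, genes in genes_by_library.items():
        for g in genes:
            proteomes[g.locus_tag] = g.protein_seq
            library_of[g.locus_tag] = lib
    sim = SimilarityCache(proteomes)

    flags: dict[str, GeneFlags] = {}
    missing_lengths: list[int] = []
    mapped_lengths: list[int] = []
    unmapped_tags: set[str] = set()
    for lib, genes in genes_by_library.items():
        unique = _unique_records(records_by_library.get(lib, []))
        contained = contained_genes_per_fragment(unique, genes)
        covered = {genes[i].locus_tag for idxs in contained for i in idxs}
        for g in genes:
            f = GeneFlags(unmapped=g.locus_tag not in covered, long=g.length_bp > long_bp)
            flags[g.locus_tag] = f
            if f.unmapped:
                unmapped_tags.add(g.locus_tag)
                missing_lengths.append(g.length_bp)
            else:
                mapped_lengths.append(g.length_bp)

    # Near-identical duplicates within the same genome.
    for lib, genes in genes_by_library.items():
        tags = [g.locus_tag for g in genes if g.protein_seq]
        for i, a in enumerate(tags):
            for b in tags[i + 1 :]:
                if sim.similar(a, b, dup_identity, COV_FOR_DUP):
                    flags[a].duplicated = True
                    flags[b].duplicated = True

    # Conserved-missing: unmapped, not explained by length or duplication,
    # with an unmapped homolog anywhere.
    remaining = [
        t
        for t in sorted(unmapped_tags)
        if not flags[t].long and not flags[t].duplicated and proteomes.get(t)
    ]
    for i, a in enumerate(remaining):
        for b in remaining:
            if a != b and sim.similar(a, b, homolog_identity, homolog_coverage):
                flags[a].homolog_also_missing = True
                break

    return MissingGeneSummary(
        flags=flags,
        median_missing_bp=float(np.median(missing_lengths)) if missing_lengths else 0.0,
        median_mapped_bp=float(np.median(mapped_lengths)) if mapped_lengths else 0.0,
    )


COV_FOR_DUP = 0.75


# ---------------------------------------------------------------------------
# Plots (four library-QC panels)


def plot_library_stats(stats: LibraryStats, path) -> None:
    """Write the four QC panels (window depth, fragment lengths, cumulative
    gene coverage, genes per fragment) to one image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7))

    ax = axes[0, 0]
    for cid, win in stats.base_coverage_windows.items():
        if win:
            xs, ys = zip(*win)
            ax.plot(np.array(xs) / 1e3, ys, label=cid, lw=0.8)
    ax.set_xlabel("genome position (kb)")
    ax.set_ylabel("mean fragment depth")
    ax.set_title("fragment coverage per base (20 kb windows)")

    ax = axes[0, 1]
    if stats.fragment_lengths:
        ax.hist(stats.fragment_lengths, bins=30, color="#4878a8")
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel("fragments")
    ax.set_title("fragment lengths")

    ax = axes[1, 0]
    counts = sorted(stats.per_gene_fragment_counts.values())
    if counts:
        xs = np.arange(0, max(counts) + 1)
        cum = [100.0 * np.mean(np.array(counts) >= x) for x in xs]
        ax.step(xs, cum, where="post")
    ax.set_xlabel("fragments per gene (full containment)")
    ax.set_ylabel("% genes covered >= x")
    ax.set_title("cumulative gene coverage")

    ax = axes[1, 1]
    if stats.genes_per_fragment_hist:
        bins = sorted(stats.genes_per_fragment_hist)
        ax.bar(bins, [stats.genes_per_fragment_hist[b] for b in bins], color="#4878a8")
    ax.set_xlabel("full-length genes per fragment")
    ax.set_ylabel("fragments")
    ax.set_title("genes per fragment (0 is the first bin)")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
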
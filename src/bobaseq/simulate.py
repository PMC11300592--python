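"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates a barcoded shotgun-expression screen: a bacterial
genome of non-overlapping clean ORFs (median gene ~957 bp), a library of
~3.1-kb fragments placed uniformly (wrapping the origin of circular
contigs), long amplicon reads with substitution/indel errors and occasional
concatemers, and BarSeq screens with Dirichlet-distributed starting
abundances, planted log2 fitness effects, two replicates and two Time0
samples per day, and multinomially sampled counts.  Every stage is seeded
and regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapper import DEFAULT_OLIGOS, OligoSet
from .model import (
    BarcodeFragmentRecord,
    CountMatrix,
    GeneAnnotation,
    Genome,
    SampleMeta,
    revcomp,
    translate_cds,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass
class ErrorModel:
    """Independent per-base read error rates; quality defaults to the Phred
    value matching the total rate, so expected-error filtering sees honest
    qualities."""

    sub: float = 0.001
    ins: float = 0.0005
    dele: float = 0.0005

    @property
    def total(self) -> float:
        return self.sub + self.ins + self.dele

    @property
    def quality(self) -> int:
        if self.total <= 0:
            return 60
        return int(round(-10.0 * np.log10(self.total)))


@dataclass
class SimTruth:
    genome: Genome
    genes: list[GeneAnnotation]
    true_map: list[BarcodeFragmentRecord]
    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)


def _random_seq(rng, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def random_barcode(rng) -> str:
    return _random_seq(rng, 20)


# ---------------------------------------------------------------------------
# Genome


def sim_genome(
    n_genes: int | None = None,
    seed: int = 0,
    median_gene_bp: int = 957,
    sigma_log: float = 0.55,
    intergenic_mean: int = 130,
    target_bp: int | None = None,
    circular: bool = False,
    genome_id: str = "simgenome",
    contig_id: str = "chr",
) -> tuple[Genome, list[GeneAnnotation]]:
    """A single-contig genome tiled with non-overlapping clean ORFs.

    Gene lengths are lognormal with the requested median; each gene is
    ATG + sense codons + TAA (reverse-complemented on the '-' strand), so
    every annotation translates without internal stops.  Give either
    ``n_genes`` or ``target_bp`` (genes are added until the genome reaches
    the target length).
    """
    if (n_genes is None) == (target_bp is None):
        raise ValueError("give exactly one of n_genes or target_bp")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes: list[GeneAnnotation] = []
    pos = 0
    i = 0
    while True:
        if n_genes is not None and i >= n_genes:
            break
        if target_bp is not None and pos >= target_bp:
            break
        gap = int(rng.exponential(intergenic_mean)) + 10
        parts.append(_random_seq(rng, gap))
        pos += gap
        length = int(rng.lognormal(np.log(median_gene_bp), sigma_log))
        length = max(150, length - length % 3)
        n_codons = length // 3 - 2
        idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
        orf = "ATG" + "".join(_SENSE_CODONS[j] for j in idx) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        placed = orf if strand == "+" else revcomp(orf)
        parts.append(placed)
        tag = f"{genome_id}_{i + 1:05d}"
        genes.append(
            GeneAnnotation(
                locus_tag=tag,
                contig_id=contig_id,
                start=pos,
                end=pos + length,
                strand=strand,
                protein_seq=translate_cds(orf, "+"),
            )
        )
        pos += length
        i += 1
    parts.append(_random_seq(rng, int(rng.exponential(intergenic_mean)) + 10))
    seq = "".join(parts)
    genome = Genome(genome_id, {contig_id: seq}, {contig_id: circular})
    return genome, genes


# ---------------------------------------------------------------------------
# Library


class _GeneLocator:
    """Sorted-array containment lookup, wrap-aware for circular contigs."""

    def __init__(self, genes: list[GeneAnnotation], contig_len: int):
        ordered = sorted(genes, key=lambda g: g.start)
        self.tags = [g.locus_tag for g in ordered]
        self.starts = np.array([g.start for g in ordered], dtype=np.int64)
        self.ends = np.array([g.end for g in ordered], dtype=np.int64)
        self.contig_len = contig_len

    def _contained_idx(self, f_start: int, f_end: int):
        lo = int(np.searchsorted(self.starts, f_start, side="left"))
        hi = int(np.searchsorted(self.starts, f_end, side="left"))
        inside = np.nonzero(self.ends[lo:hi] <= f_end)[0]
        return [lo + int(i) for i in inside]

    def contained(self, f_start: int, f_end: int) -> list[str]:
        """Locus tags fully inside [f_start, f_end); f_end may extend past
        the contig end (origin wrap)."""
        idx = self._contained_idx(f_start, f_end)
        if f_end > self.contig_len:
            idx += self._contained_idx(
                f_start - self.contig_len, f_end - self.contig_len
            )
        return [self.tags[i] for i in sorted(set(idx))]


def sim_library(
    genome: Genome,
    genes: list[GeneAnnotation],
    n_barcodes: int,
    seed: int = 0,
    frag_mean: float = 3100.0,
    frag_sd: float = 450.0,
    frag_min: int = 1000,
    frag_max: int = 6000,
    library_id: str = "lib1",
) -> list[BarcodeFragmentRecord]:
    """Uniformly placed sheared fragments with collision-free 20-nt barcodes.

    Fragment starts are uniform over the contig (wrapping the origin when
    the contig is circular; clamped to fit otherwise); lengths are normal
    around ~3.1 kb, truncated to the size-selection window.  Orientation vs.
    the vector promoter is Bernoulli(1/2).  ``contained_gene_tags`` carries
    the planted truth.
    """
    rng = np.random.default_rng(seed)
    (contig_id, seq), = genome.contigs.items()
    G = len(seq)
    circular = genome.circular[contig_id]
    if frag_sd > 0:
        lengths = rng.normal(frag_mean, frag_sd, size=n_barcodes)
    else:
        lengths = np.full(n_barcodes, frag_mean)
    lengths = np.clip(np.round(lengths), frag_min, min(frag_max, G - 1)).astype(int)
    if circular:
        starts = rng.integers(0, G, size=n_barcodes)
    else:
        starts = np.array(
            [rng.integers(0, G - L + 1) for L in lengths], dtype=int
        )
    strands = rng.random(n_barcodes) < 0.5

    # draw all barcodes at once, redrawing any collisions
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n_barcodes:
        block = rng.choice(_BASES, size=(n_barcodes - len(barcodes), 20))
        for row in block:
            bc = row.tobytes().decode()
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)

    locator = _GeneLocator(genes, G)
    records = []
    for i in range(n_barcodes):
        start = int(starts[i])
        end = start + int(lengths[i])
        records.append(
            BarcodeFragmentRecord(
                barcode=barcodes[i],
                library_id=library_id,
                contig_id=contig_id,
                start=start,
                end=end,
                strand="+" if strands[i] else "-",
                read_support=1,
                contained_gene_tags=locator.contained(start, end),
            )
        )
    return records


def fragment_sequence(record: BarcodeFragmentRecord, genome: Genome) -> str:
    """The cloned insert in promoter orientation (wrap-aware)."""
    seq = genome.contigs[record.contig_id]
    if record.end <= len(seq):
        insert = seq[record.start : record.end]
    else:  # circular wrap
        insert = seq[record.start :] + seq[: record.end - len(seq)]
    return insert if record.strand == "+" else revcomp(insert)


# ---------------------------------------------------------------------------
# Long reads


def _mutate(rng, seq: str, model: ErrorModel) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    r = rng.random(n)
    sub_idx = np.nonzero(r < model.sub)[0]
    if sub_idx.size:
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=sub_idx.size)
        base_idx = np.searchsorted(_BASES, arr[sub_idx])
        arr[sub_idx] = _BASES[(base_idx + shift) % 4]
    r2 = rng.random(n)
    del_idx = np.nonzero(r2 < model.dele)[0]
    if del_idx.size:
        arr = np.delete(arr, del_idx)
    r3 = rng.random(arr.size)
    ins_idx = np.nonzero(r3 < model.ins)[0]
    if ins_idx.size:
        arr = np.insert(arr, ins_idx, rng.choice(_BASES, size=ins_idx.size))
    return arr.tobytes().decode()


def sim_longreads(
    true_map: list[BarcodeFragmentRecord],
    genome: Genome,
    oligos: OligoSet = DEFAULT_OLIGOS,
    seed: int = 0,
    depth: float = 10.0,
    error_model: ErrorModel | None = None,
    concatemer_rate: float = 0.0,
    index_pair: tuple[str, str] | None = None,
) -> list[tuple[str, str, list[int]]]:
    """Amplicon reads for every cassette in the truth table.

    Each cassette (pad, A1, barcode, A2, spacer, A3, insert, A4, pad) is
    emitted ~Poisson(depth) times with stochastic errors; a
    ``concatemer_rate`` fraction of reads carries the cassette twice; half
    of the reads come out reverse-complemented.  Per-base qualities match
    the planted error rate.
    """
    model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    q = model.quality
    a1, a2, a3, a4 = oligos.oligos()
    reads = []
    for rec in true_map:
        insert = fragment_sequence(rec, genome)
        cassette_core = (
            a1 + rec.barcode + a2 + _random_seq(rng, 10) + a3 + insert + a4
        )
        n_reads = rng.poisson(depth)
        for j in range(n_reads):
            cassette = _random_seq(rng, int(rng.integers(5, 16))) + cassette_core
            if concatemer_rate and rng.random() < concatemer_rate:
                cassette = cassette + _random_seq(rng, 8) + cassette_core
            cassette = cassette + _random_seq(rng, int(rng.integers(5, 16)))
            seq = _mutate(rng, cassette, model)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            if index_pair is not None:
                seq = index_pair[0] + seq + revcomp(index_pair[1])
            reads.append((f"{rec.barcode}_{j}", seq, [q] * len(seq)))
    return reads


# ---------------------------------------------------------------------------
# Fitness screens


def strain_effect(
    record: BarcodeFragmentRecord,
    planted_effects: dict[tuple[str, str], float],
    condition: str,
) -> float:
    """Gain-of-function semantics: a strain's log2 effect is the max planted
    effect over the genes its fragment fully contains (0 with none)."""
    deltas = [
        planted_effects.get((tag, condition), 0.0)
        for tag in record.contained_gene_tags
    ]
    return max(deltas, default=0.0)


def sim_screen(
    true_map: list[BarcodeFragmentRecord],
    planted_effects: dict[tuple[str, str], float],
    conditions: list[str],
    seed: int = 0,
    depth: int = 3_000_000,
    n_replicates: int = 2,
    n_time0: int = 2,
    day: str = "1",
    dirichlet_alpha: float = 1.0,
) -> tuple[CountMatrix, list[SampleMeta]]:
    """Multinomial BarSeq counts with planted effects.

    Time0 relative abundances are Dirichlet(alpha); in each condition a
    strain's abundance is multiplied by 2^delta and renormalized, both
    replicates sharing the selected composition (growth is treated as
    deterministic; only sequencing is resampled).
    """
    rng = np.random.default_rng(seed)
    barcodes = [r.barcode for r in true_map]
    p0 = rng.dirichlet(np.full(len(barcodes), dirichlet_alpha))

    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    for t in range(n_time0):
        samples.append(
            SampleMeta(
                sample_id=f"T0_d{day}_{t + 1}",
                condition="Time0",
                replicate=t + 1,
                day=day,
                is_time0=True,
            )
        )
        columns.append(rng.multinomial(depth, p0))
    for cond in conditions:
        deltas = np.array(
            [strain_effect(r, planted_effects, cond) for r in true_map]
        )
        p = p0 * np.exp2(deltas)
        p = p / p.sum()
        for rep in range(n_replicates):
            samples.append(
                SampleMeta(
                    sample_id=f"{cond}_d{day}_r{rep + 1}",
                    condition=cond,
                    replicate=rep + 1,
                    day=day,
                    is_time0=False,
                )
            )
            columns.append(rng.multinomial(depth, p))
    counts = np.stack(columns, axis=1)
    return CountMatrix(barcodes, samples, counts), samples


# ---------------------------------------------------------------------------
# Convenience: a full ground-truthed screen in one call


def sim_truth(
    seed: int = 0,
    n_genes: int = 60,
    n_barcodes: int = 400,
    conditions: tuple[str, ...] = ("cond1",),
    planted_per_condition: int = 1,
    delta: float = 6.0,
) -> SimTruth:
    """Genome + library + planted effects, choosing as planted genes the
    ones with at least two covering fragments (so effects are confirmable by
    overlap)."""
    genome, genes = sim_genome(n_genes=n_genes, seed=seed)
    true_map = sim_library(genome, genes, n_barcodes, seed=seed + 1)
    coverage: dict[str, int] = {g.locus_tag: 0 for g in genes}
    for r in true_map:
        for t in r.contained_gene_tags:
            coverage[t] += 1
    well_covered = [t for t, n in sorted(coverage.items()) if n >= 2]
    rng = np.random.default_rng(seed + 2)
    planted: dict[tuple[str, str], float] = {}
    for cond in conditions:
        picks = rng.choice(
            len(well_covered), size=min(planted_per_condition, len(well_covered)), replace=False
        )
        for p in picks:
            planted[(well_covered[int(p)], cond)] = delta
    return SimTruth(
        genome=genome,
        genes=genes,
        true_map=true_map,
        planted_effects=planted,
        seeds={"genome": seed, "library": seed + 1, "effects": seed + 2},
    )
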
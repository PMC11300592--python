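"""Domain types shared across the pipeline.

Coordinate convention: all genomic intervals are 0-based, half-open, on the
forward strand of the contig.  GFF input (1-based, inclusive) is converted at
the I/O boundary.  Barcodes are exactly 20 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")
BARCODE_LEN = 20

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_seq(seq: str) -> str:
    """Uppercase a nucleotide string and map non-ACGTN characters to N."""
    s = seq.upper()
    if set(s) <= VALID_BASES:
        return s
    return "".join(c if c in VALID_BASES else "N" for c in s)


def translate_cds(nt: str, strand: str = "+") -> str:
    """Translate a CDS using the bacterial code (NCBI table 11).

    The annotated start codon is forced to M (bacterial convention covers
    GTG/TTG starts); ambiguous codons translate to X; a trailing stop codon
    is dropped.  ``strand`` '-' reverse-complements first.
    """
    if strand == "-":
        nt = revcomp(nt)
    nt = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if aa:
        aa = "M" + aa[1:]
    return aa


class FormatError(ValueError):
    """Raised for malformed input files (names the offending record)."""


@dataclass
class Genome:
    """A reference assembly: contig id -> uppercase ACGTN sequence."""

    genome_id: str
    contigs: dict[str, str]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"empty sequence for contig {cid!r}")
            if not set(seq) <= VALID_BASES:
                raise FormatError(f"non-ACGTN characters in contig {cid!r}")
            self.circular.setdefault(cid, False)

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class GeneAnnotation:
    """A protein-coding gene (CDS), the unit fragments are scored against."""

    locus_tag: str
    contig_id: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str  # '+' or '-'
    protein_seq: str = ""
    internal_stop: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.locus_tag}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.locus_tag}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class BarcodeFragmentRecord:
    """One barcode's resolved genomic insert — a mapping-table row.

    ``strand`` is the insert's cloned orientation: '+' means the forward
    genomic strand of the interval runs downstream of the vector promoter,
    so a '+'-strand gene inside a '+' record is oriented *same* as the
    promoter.  ``alt_locations`` holds (contig, start, end, read_support)
    tuples for barcodes whose reads map to distant genomic locations; such
    records carry ``multi_locus=True`` and are excluded from fitness.
    """

    barcode: str
    library_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+'/'-': insert orientation vs. the vector promoter
    read_support: int = 1
    contained_gene_tags: list[str] = field(default_factory=list)
    multi_locus: bool = False
    alt_locations: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.barcode) != BARCODE_LEN:
            raise ValueError(
                f"barcode length must be {BARCODE_LEN}, got {len(self.barcode)}"
                f" ({self.barcode!r})"
            )
        if self.end - self.start <= 0:
            raise ValueError(f"{self.barcode}: empty insert interval")
        if self.read_support < 1:
            raise ValueError(f"{self.barcode}: read_support must be >= 1")
        if self.multi_locus and not self.alt_locations:
            raise ValueError(f"{self.barcode}: multi_locus without alt_locations")

    def gene_orientation(self, gene: GeneAnnotation) -> str:
        """'same' if the gene is transcribed in the promoter direction."""
        return "same" if gene.strand == self.strand else "opposite"


@dataclass
class SampleMeta:
    sample_id: str
    condition: str
    concentration: str = ""
    replicate: int = 1
    day: str = "1"
    is_time0: bool = False
    layout: str = "bs4"
    index: str = ""


@dataclass
class CountMatrix:
    """Barcode x sample read counts with sample metadata.

    ``counts`` is a dense non-negative integer array of shape
    (len(barcodes), len(samples)).
    """

    barcodes: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.barcodes), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        self._barcode_index = {b: i for i, b in enumerate(self.barcodes)}
        self._sample_index = {s.sample_id: j for j, s in enumerate(self.samples)}

    def sample(self, sample_id: str) -> SampleMeta:
        return self.samples[self._sample_index[sample_id]]

    def column(self, sample_id: str):
        return self.counts[:, self._sample_index[sample_id]]

    def get(self, barcode: str, sample_id: str) -> int:
        i = self._barcode_index.get(barcode)
        if i is None:
            return 0
        return int(self.counts[i, self._sample_index[sample_id]])


def intervals_intersect(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True iff the half-open intervals [a_start,a_end) and [b_start,b_end)
    share at least one base.  Abutting intervals do not intersect."""
    return a_start < b_end and b_start < a_end


def gene_contained(gene: GeneAnnotation, start: int, end: int) -> bool:
    """Full containment: only complete genes count (partial genes at insert
    boundaries are not recorded)."""
    return gene.start >= start and gene.end <= end
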
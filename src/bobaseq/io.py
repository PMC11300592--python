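"""Readers and writers for the standard formats the pipeline touches.

FASTA / FASTQ (Phred+33) / GFF3 CDS features / TSV mapping tables, count
matrices and sample sheets.  All readers and writers are mutual inverses on
valid data.  Plain and gzip-compressed text are both accepted (by ``.gz``
suffix).
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np

from .model import (
    BarcodeFragmentRecord,
    CountMatrix,
    FormatError,
    GeneAnnotation,
    Genome,
    SampleMeta,
    clean_seq,
    translate_cds,
)

PHRED_OFFSET = 33


def _open_text(path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, genome_id: str | None = None, circular: bool = False) -> Genome:
    """Read a FASTA assembly into a :class:`Genome`.

    Lowercase is normalized to uppercase; characters outside ACGTN become N.
    Duplicate headers or an empty file raise :class:`FormatError`.
    """
    contigs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    contigs[name] = clean_seq("".join(parts))
                name = line[1:].split()[0]
                if name in contigs:
                    raise FormatError(f"duplicate contig id {name!r} in {path}")
                if not name:
                    raise FormatError(f"empty FASTA header in {path}")
                parts = []
            else:
                if name is None:
                    raise FormatError(f"sequence before first header in {path}")
                parts.append(line)
    if name is not None:
        if name in contigs:
            raise FormatError(f"duplicate contig id {name!r} in {path}")
        contigs[name] = clean_seq("".join(parts))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    gid = genome_id if genome_id is not None else Path(path).stem
    return Genome(gid, contigs, {c: circular for c in contigs})


def write_fasta(genome: Genome, path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    """Read 4-line FASTQ records as (read_id, seq, Phred integer qualities)."""
    return list(iter_fastq(path))


def iter_fastq(path) -> Iterator[tuple[str, str, list[int]]]:
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"expected '@' header, got {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            if not plus.startswith("+") or not qual:
                raise FormatError(f"incomplete FASTQ record for {read_id!r}")
            if len(seq) != len(qual):
                raise FormatError(
                    f"seq/quality length mismatch for read {read_id!r}"
                )
            yield read_id, clean_seq(seq), [ord(c) - PHRED_OFFSET for c in qual]


def write_fastq(records: Iterable[tuple[str, str, list[int]]], path) -> None:
    with _open_text(path, "wt") as fh:
        for read_id, seq, quals in records:
            qstr = "".join(chr(min(q, 93) + PHRED_OFFSET) for q in quals)
            fh.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# GFF3 CDS features


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def read_gff_genes(path, genome: Genome) -> list[GeneAnnotation]:
    """Parse CDS features from a GFF3 file into 0-based half-open genes.

    Protein sequences are translated from ``genome`` with the bacterial code
    (table 11), reverse-complemented for '-' strand CDS.  Features missing a
    ``locus_tag`` attribute get an auto-assigned ``contig:start-end`` tag
    with a warning; a CDS outside its contig raises.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            contig, _src, ftype, start1, end1, _score, strand, _frame, attrs = fields
            if ftype != "CDS":
                continue
            if contig not in genome.contigs:
                raise FormatError(
                    f"{path}:{lineno}: CDS on unknown contig {contig!r}"
                )
            start = int(start1) - 1  # GFF is 1-based inclusive
            end = int(end1)
            clen = len(genome.contigs[contig])
            if start < 0 or end > clen or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: CDS {start1}..{end1} outside contig "
                    f"{contig!r} (length {clen})"
                )
            tag = _gff_attributes(attrs).get("locus_tag")
            if tag is None:
                tag = f"{contig}:{start}-{end}"
                warnings.warn(f"CDS without locus_tag; auto-assigned {tag}")
            if tag in seen:
                raise FormatError(f"{path}:{lineno}: duplicate locus_tag {tag!r}")
            seen.add(tag)
            nt = genome.contigs[contig][start:end]
            protein = translate_cds(nt, strand)
            genes.append(
                GeneAnnotation(
                    locus_tag=tag,
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    protein_seq=protein.replace("*", ""),
                    internal_stop="*" in protein,
                )
            )
    return genes


def write_gff_genes(genes: Iterable[GeneAnnotation], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "bobaseq",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.locus_tag};locus_tag={g.locus_tag}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Mapping table (TSV)

MAPPING_COLUMNS = [
    "barcode",
    "library",
    "contig",
    "start",
    "end",
    "strand_vs_promoter",
    "read_support",
    "genes",
    "multi_locus",
    "alt_locations",
]


def _encode_alts(alts: list[tuple[str, int, int, int]]) -> str:
    return ";".join(f"{c}:{s}-{e}:{n}" for c, s, e, n in alts) or "-"


def _decode_alts(text: str) -> list[tuple[str, int, int, int]]:
    if text in ("-", ""):
        return []
    out = []
    for item in text.split(";"):
        loc, n = item.rsplit(":", 1)
        contig, span = loc.rsplit(":", 1)
        s, e = span.split("-")
        out.append((contig, int(s), int(e), int(n)))
    return out


def write_mapping_table(records: Iterable[BarcodeFragmentRecord], path) -> None:
    """Serialize records as TSV, one primary row per barcode with alternate
    locations encoded inline (``contig:start-end:reads`` joined by ';')."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(MAPPING_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.barcode,
                        r.library_id,
                        r.contig_id,
                        str(r.start),
                        str(r.end),
                        r.strand,
                        str(r.read_support),
                        ",".join(r.contained_gene_tags) or "-",
                        "1" if r.multi_locus else "0",
                        _encode_alts(r.alt_locations),
                    ]
                )
                + "\n"
            )


def read_mapping_table(path) -> list[BarcodeFragmentRecord]:
    records = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MAPPING_COLUMNS:
            raise FormatError(f"unexpected mapping-table header in {path}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(MAPPING_COLUMNS):
                raise FormatError(f"{path}:{lineno}: malformed mapping row")
            try:
                records.append(
                    BarcodeFragmentRecord(
                        barcode=fields[0],
                        library_id=fields[1],
                        contig_id=fields[2],
                        start=int(fields[3]),
                        end=int(fields[4]),
                        strand=fields[5],
                        read_support=int(fields[6]),
                        contained_gene_tags=(
                            [] if fields[7] == "-" else fields[7].split(",")
                        ),
                        multi_locus=fields[8] == "1",
                        alt_locations=_decode_alts(fields[9]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Count matrix (long-format TSV) and sample sheet

SAMPLE_COLUMNS = [
    "sample_id",
    "condition",
    "concentration",
    "replicate",
    "day",
    "is_time0",
    "layout",
    "index",
]


def write_sample_sheet(samples: Iterable[SampleMeta], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(SAMPLE_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                "\t".join(
                    [
                        s.sample_id,
                        s.condition,
                        s.concentration or "-",
                        str(s.replicate),
                        s.day,
                        "1" if s.is_time0 else "0",
                        s.layout,
                        s.index or "-",
                    ]
                )
                + "\n"
            )


def read_sample_sheet(path) -> list[SampleMeta]:
    samples = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SAMPLE_COLUMNS:
            raise FormatError(f"unexpected sample-sheet header in {path}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(SAMPLE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: malformed sample row")
            samples.append(
                SampleMeta(
                    sample_id=f[0],
                    condition=f[1],
                    concentration="" if f[2] == "-" else f[2],
                    replicate=int(f[3]),
                    day=f[4],
                    is_time0=f[5] == "1",
                    layout=f[6],
                    index="" if f[7] == "-" else f[7],
                )
            )
    return samples


def write_count_matrix(cm: CountMatrix, path, sheet_path=None) -> None:
    """Long-format TSV (barcode, sample, count); zero counts are written so
    all-zero columns survive the round trip."""
    with _open_text(path, "wt") as fh:
        fh.write("barcode\tsample\tcount\n")
        for j, s in enumerate(cm.samples):
            col = cm.counts[:, j]
            for i, b in enumerate(cm.barcodes):
                fh.write(f"{b}\t{s.sample_id}\t{int(col[i])}\n")
    if sheet_path is not None:
        write_sample_sheet(cm.samples, sheet_path)


def read_count_matrix(path, samples: list[SampleMeta]) -> CountMatrix:
    sample_index = {s.sample_id: j for j, s in enumerate(samples)}
    barcodes: list[str] = []
    barcode_index: dict[str, int] = {}
    triplets: list[tuple[int, int, int]] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["barcode", "sample", "count"]:
            raise FormatError(f"unexpected count-matrix header in {path}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 3:
                raise FormatError(f"{path}:{lineno}: malformed count row")
            b, sid, n = f
            if sid not in sample_index:
                raise FormatError(f"{path}:{lineno}: unknown sample {sid!r}")
            if b not in barcode_index:
                barcode_index[b] = len(barcodes)
                barcodes.append(b)
            triplets.append((barcode_index[b], sample_index[sid], int(n)))
    counts = np.zeros((len(barcodes), len(samples)), dtype=np.int64)
    for i, j, n in triplets:
        counts[i, j] += n
    return CountMatrix(barcodes, samples, counts)
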
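"""BarSeq short reads -> barcode counts, plus barcode-diversity estimation.

A BarSeq read carries an inline sample index, a fixed pre-barcode anchor,
the 20-nt barcode, and a post-barcode anchor.  Two primer generations are
supported: the older design with 6-bp inline indexes on both sides and the
newer one with an 8-bp P5 / 10-bp P7 index; only the P5-side inline index is
checked here, the P7 index being handled by instrument demultiplexing.

Counting uses ``min_quality=0`` (every read with an intact layout counts);
diversity estimation uses ``min_quality=30``, bounding the per-barcode error
rate at 0.001/base x 20 nt = 2%, then removes off-by-1 neighbors of more
abundant barcodes and applies the Chao1 estimator with the singleton count
discounted by an assumed residual error rate.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .model import BarcodeFragmentRecord, CountMatrix, SampleMeta

BARCODE_LEN = 20

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class BarseqLayout:
    name: str  # bs3 | bs4
    pre_barcode_anchor: str
    post_barcode_anchor: str
    inline_index_length: int
    barcode_length: int = BARCODE_LEN
    anchor_mismatches: int = 1

    def __post_init__(self):
        if not self.pre_barcode_anchor or not self.post_barcode_anchor:
            raise ValueError("anchors must be non-empty")
        if self.barcode_length != BARCODE_LEN:
            raise ValueError(f"barcode_length must be {BARCODE_LEN}")


# Anchor sequences bracketing the barcode in the common BarSeq primer
# designs; any primer set can be described by constructing a layout.
LAYOUT_BS3 = BarseqLayout("bs3", "CAGCGTACG", "AGAGACC", inline_index_length=6)
LAYOUT_BS4 = BarseqLayout("bs4", "CAGCGTACG", "AGAGACC", inline_index_length=8)

LAYOUTS = {"bs3": LAYOUT_BS3, "bs4": LAYOUT_BS4}


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_barcode(
    read,
    layout: BarseqLayout,
    min_quality: int = 0,
    expected_index: str | None = None,
):
    """Return the 20-nt barcode from one short read, or (None, reason).

    The pre-barcode anchor must sit directly after the inline index, the
    post-barcode anchor directly after the barcode (each within the layout's
    mismatch tolerance).  Acceptance additionally requires every barcode
    base quality >= ``min_quality`` and, when ``expected_index`` is given,
    an exact inline-index match.
    """
    _rid, seq, quals = read
    ilen = layout.inline_index_length
    pre = layout.pre_barcode_anchor
    post = layout.post_barcode_anchor
    b0 = ilen + len(pre)
    b1 = b0 + layout.barcode_length
    if len(seq) < b1 + len(post):
        return None, "too_short"
    if _mismatches(seq[ilen:b0], pre) > layout.anchor_mismatches:
        return None, "no_pre_anchor"
    if _mismatches(seq[b1 : b1 + len(post)], post) > layout.anchor_mismatches:
        return None, "no_post_anchor"
    if expected_index is not None and seq[:ilen] != expected_index:
        return None, "index_mismatch"
    barcode = seq[b0:b1]
    if "N" in barcode:
        return None, "ambiguous_base"
    if min_quality > 0 and min(quals[b0:b1]) < min_quality:
        return None, "low_quality"
    return barcode, None


def tally(
    sample_reads: dict[str, list],
    layout: BarseqLayout,
    sample_sheet: list[SampleMeta],
    min_quality: int = 0,
) -> tuple[CountMatrix, dict[str, dict[str, int]]]:
    """Count barcodes per sample.

    ``sample_reads`` maps sample_id -> reads; every sample must appear in
    the sheet (the reverse is allowed: listed samples with zero reads keep
    an all-zero column, so Time0 columns always exist).  Returns the count
    matrix and per-sample rejection tallies; reads are conserved:
    accepted + rejected == input reads for every sample.
    """
    sheet_ids = {s.sample_id for s in sample_sheet}
    unknown = set(sample_reads) - sheet_ids
    if unknown:
        raise ValueError(f"samples not in sheet: {sorted(unknown)}")
    per_sample_counts: dict[str, Counter] = {}
    rejections: dict[str, dict[str, int]] = {}
    for meta in sample_sheet:
        counts: Counter = Counter()
        rej: Counter = Counter()
        for read in sample_reads.get(meta.sample_id, ()):
            barcode, reason = extract_barcode(
                read, layout, min_quality, expected_index=meta.index or None
            )
            if barcode is None:
                rej[reason] += 1
            else:
                counts[barcode] += 1
        per_sample_counts[meta.sample_id] = counts
        rejections[meta.sample_id] = dict(rej)
    barcodes = sorted(set().union(*per_sample_counts.values()))
    mat = np.zeros((len(barcodes), len(sample_sheet)), dtype=np.int64)
    bindex = {b: i for i, b in enumerate(barcodes)}
    for j, meta in enumerate(sample_sheet):
        for b, n in per_sample_counts[meta.sample_id].items():
            mat[bindex[b], j] = n
    return CountMatrix(barcodes, list(sample_sheet), mat), rejections


# ---------------------------------------------------------------------------
# Off-by-1 collapse


def _neighbors(barcode: str):
    for i, base in enumerate(barcode):
        for alt in _ALPHABET:
            if alt != base:
                yield barcode[:i] + alt + barcode[i + 1 :]


def collapse_offby1(counts: dict[str, int]) -> dict[str, int]:
    """Eliminate barcodes that are off-by-1 errors of a more abundant one.

    A barcode is removed iff some barcode at Hamming distance exactly 1 has
    a strictly higher count in the *original* table (decisions are computed
    first, then applied, so removal order cannot cascade).  Removed counts
    are discarded, not merged.  Idempotent.
    """
    doomed = set()
    for barcode, n in counts.items():
        for nb in _neighbors(barcode):
            if counts.get(nb, 0) > n:
                doomed.add(barcode)
                break
    return {b: n for b, n in counts.items() if b not in doomed}


# ---------------------------------------------------------------------------
# Chao1 diversity


@dataclass
class DiversityEstimate:
    s_obs: int
    f1: int
    f2: int
    assumed_error_rates: list[float]
    estimates: list[float] = field(default_factory=list)


def chao1(
    counts: dict[str, int],
    assumed_error_rates: tuple[float, ...] = (0.0, 0.01, 0.02),
) -> DiversityEstimate:
    """Chao1 richness with error-discounted singletons.

    For each assumed residual error rate e the singleton count becomes
    f1' = f1 (1 - e) and the estimate S_obs + f1'^2 / (2 f2); with no
    doubletons the bias-corrected form S_obs + f1'(f1'-1)/2 is used.
    Counts are expected to be off-by-1 collapsed already.
    """
    s_obs = len(counts)
    f1 = sum(1 for n in counts.values() if n == 1)
    f2 = sum(1 for n in counts.values() if n == 2)
    est = DiversityEstimate(s_obs, f1, f2, list(assumed_error_rates))
    for e in assumed_error_rates:
        f1p = f1 * (1.0 - e)
        if s_obs == 0:
            est.estimates.append(0.0)
        elif f2 > 0:
            est.estimates.append(s_obs + f1p * f1p / (2.0 * f2))
        else:
            est.estimates.append(s_obs + max(0.0, f1p * (f1p - 1.0)) / 2.0)
    return est


def barcode_error_bound(q: int = 30, length: int = BARCODE_LEN) -> float:
    """Upper bound on the per-barcode error rate when every base has
    quality >= q: length x 10^(-q/10) (Q30 over 20 nt gives 2%)."""
    return length * 10.0 ** (-q / 10.0)


def fraction_mapped(
    count_matrix: CountMatrix, mapping_table: list[BarcodeFragmentRecord]
) -> float:
    """Fraction of barcodes detected by BarSeq (count > 0 anywhere) that
    appear in the long-read mapping table."""
    detected = {
        b
        for b, row in zip(count_matrix.barcodes, count_matrix.counts.sum(axis=1))
        if row > 0
    }
    if not detected:
        return 0.0
    mapped = {r.barcode for r in mapping_table}
    return len(detected & mapped) / len(detected)
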
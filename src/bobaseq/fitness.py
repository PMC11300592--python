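"""Per-strain fitness scores, Poisson standard errors, and significance calls.

For a barcode with n reads in a selective sample and n0 reads summed across
the paired Time0 samples, with N and N0 the corresponding totals over all
considered barcodes, the fitness is the pseudocounted log2 change in
relative abundance

    f = log2((n + psi)/N) - log2((n0 + 1/psi)/N0),    psi = sqrt(N/N0)

so that f = 0 whenever n = n0 = 0, and psi = 1 at equal totals.  The
standard error under Poisson counting noise is

    sigma = sqrt(1/(n + psi) + 1/(n0 + 1/psi)) / ln 2

and z = f / sigma.  A barcode is called significant in one experiment when
f >= f_min and z >= z_min (defaults +5 and 4, one-sided: this is a
gain-of-function assay), and pair-significant when that holds in both
replicates of a condition run on the same day.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from scipy.special import erfc

from .model import BarcodeFragmentRecord, CountMatrix, SampleMeta

LN2 = math.log(2.0)

F_MIN_DEFAULT = 5.0
Z_MIN_DEFAULT = 4.0


@dataclass
class ExperimentTotals:
    experiment_id: str
    N: int
    N0: int

    def __post_init__(self):
        if self.N <= 0 or self.N0 <= 0:
            raise ValueError(
                f"{self.experiment_id}: totals must be positive (N={self.N}, "
                f"N0={self.N0})"
            )

    @property
    def psi(self) -> float:
        return math.sqrt(self.N / self.N0)


@dataclass
class FitnessRecord:
    barcode: str
    experiment_id: str
    n: int
    n0: int
    fitness: float
    sigma: float
    z: float
    significant: bool = False


@dataclass
class InclusionRules:
    """Which barcodes enter the fitness computation.

    ``min_total_reads`` applies to the sum over all experimental and Time0
    samples after off-by-1 collapse; 10 is the pooled-screen default, 2 the
    bare detection floor.  ``donor_barcodes`` restricts to barcodes present
    in the conjugation donor when ``require_in_donor`` is set.
    """

    require_unique_mapping: bool = True
    require_in_donor: bool = False
    min_total_reads: int = 10
    donor_barcodes: frozenset[str] = frozenset()


def psi(N: float, N0: float) -> float:
    """The pseudocount sqrt(N/N0); exactly 1 when N equals N0."""
    if N <= 0 or N0 <= 0:
        raise ValueError("totals must be positive")
    return math.sqrt(N / N0)


def strain_fitness(n: int, n0: int, N: int, N0: int) -> tuple[float, float, float]:
    """(fitness, sigma, z) for one barcode in one experiment."""
    if n < 0 or n0 < 0:
        raise ValueError("counts must be non-negative")
    p = psi(N, N0)
    f = math.log2((n + p) / N) - math.log2((n0 + 1.0 / p) / N0)
    sigma = math.sqrt(1.0 / (n + p) + 1.0 / (n0 + 1.0 / p)) / LN2
    return f, sigma, f / sigma


def select_barcodes(
    count_matrix: CountMatrix,
    mapping_tables: dict[str, list[BarcodeFragmentRecord]] | list,
    rules: InclusionRules | None = None,
) -> set[str]:
    """The considered barcode set.

    Excludes barcodes that mapped to several genomic locations
    (``multi_locus``), barcodes mapped in more than one library, barcodes
    absent from the donor pool (when required), and barcodes whose total
    reads over every sample fall below ``min_total_reads``.
    """
    rules = rules or InclusionRules()
    if isinstance(mapping_tables, list):
        mapping_tables = {"lib": mapping_tables}
    libs_per_barcode: dict[str, set[str]] = defaultdict(set)
    multi_locus: set[str] = set()
    for lib, records in mapping_tables.items():
        for r in records:
            libs_per_barcode[r.barcode].add(lib)
            if r.multi_locus:
                multi_locus.add(r.barcode)

    totals = dict(zip(count_matrix.barcodes, count_matrix.counts.sum(axis=1)))
    selected = set()
    for barcode, libs in libs_per_barcode.items():
        if rules.require_unique_mapping and (barcode in multi_locus or len(libs) > 1):
            continue
        if rules.require_in_donor and barcode not in rules.donor_barcodes:
            continue
        if totals.get(barcode, 0) < rules.min_total_reads:
            continue
        selected.add(barcode)
    return selected


def time0_samples_for(sample: SampleMeta, samples: list[SampleMeta]) -> list[SampleMeta]:
    """The Time0 samples paired with an experimental sample (same day)."""
    return [s for s in samples if s.is_time0 and s.day == sample.day]


def fitness_table(
    count_matrix: CountMatrix,
    mapping_tables,
    rules: InclusionRules | None = None,
) -> tuple[list[FitnessRecord], dict[str, ExperimentTotals]]:
    """Fitness records for every considered barcode in every experiment.

    Each non-Time0 sample is one experiment; its n0 sums the same-day Time0
    samples.  N and N0 are totals over the considered barcode set only, so
    excluded barcodes contribute nothing to the denominators.
    """
    rules = rules or InclusionRules()
    considered = select_barcodes(count_matrix, mapping_tables, rules)
    barcodes = [b for b in count_matrix.barcodes if b in considered]
    idx = [count_matrix._barcode_index[b] for b in barcodes]

    records: list[FitnessRecord] = []
    totals: dict[str, ExperimentTotals] = {}
    for sample in count_matrix.samples:
        if sample.is_time0:
            continue
        t0 = time0_samples_for(sample, count_matrix.samples)
        if not t0:
            raise ValueError(
                f"experiment {sample.sample_id!r} has no Time0 sample on day "
                f"{sample.day!r}"
            )
        col = count_matrix.column(sample.sample_id)[idx]
        col0 = sum(count_matrix.column(s.sample_id) for s in t0)[idx]
        N = int(col.sum())
        N0 = int(col0.sum())
        et = ExperimentTotals(sample.sample_id, N, N0)
        totals[sample.sample_id] = et
        for b, n, n0 in zip(barcodes, col, col0):
            f, sigma, z = strain_fitness(int(n), int(n0), N, N0)
            records.append(
                FitnessRecord(
                    barcode=b,
                    experiment_id=sample.sample_id,
                    n=int(n),
                    n0=int(n0),
                    fitness=f,
                    sigma=sigma,
                    z=z,
                )
            )
    return records, totals


def pair_key(sample: SampleMeta) -> tuple[str, str, str]:
    """Replicates share a condition, concentration, and screen day."""
    return (sample.condition, sample.concentration, sample.day)


@dataclass
class SignificanceCalls:
    """Single-replicate and replicate-pair significance.

    ``single`` maps experiment_id -> significant barcodes; ``pairs`` maps
    (condition, concentration, day) -> barcodes significant in *both* (all)
    replicates of that group.
    """

    f_min: float
    z_min: float
    single: dict[str, set[str]] = field(default_factory=dict)
    pairs: dict[tuple, set[str]] = field(default_factory=dict)
    pair_experiments: dict[tuple, list[str]] = field(default_factory=dict)

    def significant_in_any_replicate(self, key: tuple) -> set[str]:
        out: set[str] = set()
        for exp in self.pair_experiments.get(key, ()):
            out |= self.single.get(exp, set())
        return out


def call_significant(
    records: list[FitnessRecord],
    samples: list[SampleMeta],
    f_min: float = F_MIN_DEFAULT,
    z_min: float = Z_MIN_DEFAULT,
) -> SignificanceCalls:
    """Flag records with f >= f_min and z >= z_min, then intersect across
    replicate pairs.  Unpaired experiments keep single-replicate flags only
    (with a warning)."""
    calls = SignificanceCalls(f_min=f_min, z_min=z_min)
    by_sample = {s.sample_id: s for s in samples}
    for r in records:
        r.significant = r.fitness >= f_min and r.z >= z_min
        if r.significant:
            calls.single.setdefault(r.experiment_id, set()).add(r.barcode)
        else:
            calls.single.setdefault(r.experiment_id, set())

    groups: dict[tuple, list[str]] = defaultdict(list)
    for exp_id in calls.single:
        groups[pair_key(by_sample[exp_id])].append(exp_id)
    for key, exps in sorted(groups.items()):
        exps.sort()
        calls.pair_experiments[key] = exps
        if len(exps) < 2:
            warnings.warn(
                f"experiment group {key} has a single replicate; "
                "no pair-significance calls made"
            )
            calls.pairs[key] = set()
            continue
        sig = set.intersection(*(calls.single[e] for e in exps))
        calls.pairs[key] = sig
    return calls


def replicate_mean_fitness(
    records: list[FitnessRecord], samples: list[SampleMeta]
) -> dict[tuple, dict[str, float]]:
    """Replicate-averaged fitness per (condition, concentration, day)."""
    by_sample = {s.sample_id: s for s in samples}
    acc: dict[tuple, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for r in records:
        acc[pair_key(by_sample[r.experiment_id])][r.barcode].append(r.fitness)
    return {
        key: {b: sum(v) / len(v) for b, v in per_bc.items()}
        for key, per_bc in acc.items()
    }


def expected_null_exceedances(n_barcodes: int, z_min: float) -> float:
    """Expected number of standard-normal z scores >= z_min among
    ``n_barcodes`` independent null barcodes: n x (1 - Phi(z_min)),
    computed through the complementary error function for precision in the
    far tail."""
    if n_barcodes <= 0:
        raise ValueError("n_barcodes must be positive")
    tail = 0.5 * erfc(z_min / math.sqrt(2.0))
    return float(n_barcodes * tail)
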
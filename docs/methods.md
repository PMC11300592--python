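# Methods

## The screen being modeled

A barcoded shotgun-overexpression library is a pool of plasmids, each
carrying one randomly sheared genomic fragment (~3 kb, size-selected)
downstream of an inducible promoter and one random 20-nt barcode. Two
sequencing assays describe the pool: long-read amplicons spanning
barcode and insert establish *which fragment each barcode tags*, and short
BarSeq reads of the barcode locus alone count *how abundant each strain is*
in a sample. Fitness is inferred by comparing a strain's relative abundance
after selective growth against the inoculum (Time0). Because the assay is
gain-of-function, only high positive fitness is called.

## Long-read mapping

Amplicons are laid out `...A1 [barcode] A2 ... A3 [insert] A4...` with four
fixed 15-bp anchors. Extraction chooses the read strand presenting all four
anchors (each matched with ≤ 2 substitutions; no indels, which keeps the
matcher equivalent to a plain Hamming scan and testable against one).
Filters, in order:

- **concatemer** — any anchor found more than once on the chosen strand;
- **barcode length** — the span between A1 and A2 must be exactly 20 nt;
- **expected error** — inserts with `Σ 10^(-Q/10) > 10` are dropped
  (default `max_expected_error = 10`, configurable).

Inserts are aligned by exact k-mer seeding (default `k = 15`, both strands)
into windows padded by `0.15 ×` insert length, followed by a
full-query alignment inside the window whose path is rescored with match
+1, mismatch −2, gap open −4, gap extend −1. Alignments must reach
`pct_coverage ≥ 0.80` and `pct_identity ≥ 0.90` (both configurable; the
thresholds are deliberately permissive for long-read error while rejecting
spurious hits, and the aligner is validated against full Smith–Waterman on
≤ 50-kb genomes: same interval within the band, identity within 0.5
percentage points).

Per barcode, per-read best locations are grouped by interval intersection
on the same contig (single linkage; any overlap joins, abutting half-open
intervals do not). One group resolves to a consensus interval — the
read-weighted mode of each boundary, ties to the smaller coordinate, which
makes mapping invariant to read order. Several disconnected groups mark the
barcode `multi_locus`: the top-read-count group is kept as the primary row,
all others as `alt_locations`, and the record is excluded from fitness.
Genes are attached only when *fully contained* in the insert
(`gene.start ≥ start and gene.end ≤ end`); partial genes at the boundaries
are not recorded since only complete ORFs can be functionally expressed.
A gene is oriented *same* as the promoter when its strand equals the
insert's cloned orientation.

## BarSeq counting and diversity

A BarSeq read is `[inline index][pre-anchor][20-nt barcode][post-anchor]`.
Counting mode accepts any read with an intact layout (`min_quality = 0`);
diversity estimation demands quality ≥ 30 at every barcode base, bounding
the per-barcode error rate at `20 × 10^-3 = 2%`. Barcodes at Hamming
distance exactly 1 from a strictly more abundant barcode are *eliminated*
(not merged — merging would inflate the parent), with removal decisions
computed against the original abundances so the operation is idempotent.
Only substitution neighbors are considered: barcode length is enforced
upstream, so indel neighbors cannot arise. The neighbor search enumerates
the 60 one-substitution variants per barcode against a hash table, which
scales linearly and is verified against the all-pairs comparison in tests.

Chao1 richness uses singletons `f1` and doubletons `f2`:
`S = S_obs + f1'^2/(2 f2)` with `f1' = f1 (1 − e)` for assumed residual
error rates `e ∈ {0, 1%, 2%}`; at `f2 = 0` the standard bias-corrected form
`S_obs + f1'(f1'−1)/2` applies (the classical estimator is undefined
there). The estimate is ≥ `S_obs` and non-increasing in `e` by
construction.

## Fitness statistic

Considered barcodes must map to a single location in a single library, be
present in the conjugation donor pool when a donor list is supplied, and
have ≥ `min_total_reads` reads summed over all experimental and Time0
samples (default 10 for pooled screens; 2 is the bare detection floor).
Totals `N`, `N0` are computed over the final considered set in one pass, so
excluded barcodes contribute nothing to the denominators.

With `ψ = sqrt(N/N0)`,

```
f = log2((n + ψ)/N) − log2((n0 + 1/ψ)/N0)
σ = sqrt(1/(n + ψ) + 1/(n0 + 1/ψ)) / ln 2          (Poisson counting noise)
z = f/σ
```

The pseudocount pairing `ψ` against `1/ψ` gives three exact identities the
tests pin down: `f(0,0) = 0` for any totals, `ψ = 1` at `N = N0`, and
antisymmetry `f(n, n0) = −f(n0, n)` at equal totals. `Φ` for the expected
null exceedances `n (1 − Φ(z_min))` is computed through `erfc`, which keeps
full precision at `z = 4`.

Each non-Time0 sample is one experiment; `n0` sums the Time0 samples
collected on the same day, and replicates share a
(condition, concentration, day) key. Significance (`f ≥ 5`, `z ≥ 4`) is
one-sided — benefit only — and pair-significance requires both replicates.
The `+5` floor reflects control Time0-vs-Time0 comparisons in screens of
~3 × 10^5 barcodes, where null fitness stays within about ±4.

## Curation

Pair-significant inserts are clustered into regions per
(condition, library, contig) by single-linkage interval overlap — the
minimal parameter-free definition of "same region of the genome". For each
region, the insert with the highest replicate-averaged fitness nominates
candidate proteins (genes it fully contains). Candidate scores:

1. number of significantly beneficial inserts containing the protein, each
   replicate counted separately (scoped to the region's condition);
2. number of distinct similar proteins (≥40% identity and ≥75% coverage)
   inside *other* pair-significant regions of the same condition;
3. mean replicate-averaged fitness over all inserts containing the protein.

The causative protein maximizes these lexicographically; exact residual
ties return every tied tag and flag the region `needs_review`, and an
overrides table can substitute a manual call — mirroring the visual
curation step such screens end with rather than automating it. A region is
confirmed by *overlap* (≥ 2 member inserts) or by *similarity* (its
causative protein has a qualifying homolog in a significant insert of a
different region, same condition, any library); unconfirmed singletons are
retained in the output but excluded from the consistent-hit report.

Protein similarity is local BLOSUM62 alignment (gap open −11, extend −1);
identity is identities over aligned columns (gaps included) and coverage is
the aligned span over the *shorter* sequence — symmetric, and the common
choice for homolog screens where a domain-sized match against a longer
multi-domain protein should still count. Causative proteins across all
conditions are grouped into protein clusters by single linkage at the same
thresholds.

## Library QC

"Coverage" is fragment depth: each uniquely mapped fragment adds 1 to every
base it spans (20-kb window means are reported), while a gene counts as
covered only when fully contained — matching the genes-per-fragment
histogram convention (0 is the first bin). Fragment lengths are
alignment-derived interval lengths. The strand-bias ratio divides contained
gene instances oriented opposite the promoter by those oriented the same
way; ligation-built libraries sit near 1, while PCR-based assembly can push
it toward 1.4–1.9. The missing-gene analysis classifies unmapped genes as
long (> 1.5 kb), duplicated (≥ 95%-identity copy in the same genome), or —
after removing those two classes — conserved-missing (an unmapped homolog
at ≥ 40% identity / 75% coverage in any library), the signature of genes
toxic to the cloning host.

## Synthetic data

The generator is first-class, seeded code; identical seeds are
byte-identical. Its defaults are the screen conditions the package is
designed around:

- genomes of non-overlapping clean ORFs, lognormal gene lengths with median
  957 bp (σ_log = 0.55, floor 150 bp), exponential intergenic gaps (mean
  ~130 bp plus a 10-bp floor) — typical gut-bacterial gene geometry;
- fragment lengths normal around 3.1 kb (sd 450 bp) truncated to the 1–6 kb
  size-selection window, uniform starts (wrapping circular contigs),
  collision-free random barcodes, Bernoulli(1/2) promoter orientation;
- long reads at ~Poisson(10) depth per cassette with independent per-base
  substitution/insertion/deletion errors (defaults 0.1%/0.05%/0.05%,
  CCS-like; qualities honest to the planted total rate), optional
  concatemers, half the reads reverse-complemented;
- screens with Dirichlet(1.0) starting abundances, two replicates and two
  Time0 samples per day, multinomial counts at 3 × 10^6 reads per sample. A
  strain's effect is the *maximum* planted Δ over its fully contained genes
  (gain-of-function semantics, not additive); condition abundances are
  `p0 · 2^Δ` renormalized, with growth treated as deterministic and only
  sequencing resampled.

What the generator does **not** emulate: realistic long-read error
profiles (homopolymer bias, chimeric PCR artifacts beyond simple
concatemers), growth stochasticity and jackpot takeovers (both replicates
share one selected composition), cloning bias (GC, toxicity), or barcode
cross-contamination. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to every
artifact of real screens.

Because condition abundances are renormalized, a planted effect Δ is
recovered as `Δ − log2 Z` with `Z = Σ_b p0_b 2^(Δ_b)` — the arithmetic of
competitive growth. Unit tests check recovery against this exact
expectation at any library size; the screen-scale recovery checks use a
6.5-Mbp genome, where the carrier mass of a single planted gene makes
`log2 Z ≈ 0.03`, well inside one standard error, so Δ = 6 is recovered
within 3σ directly.

## Numerical and design notes

- Intervals are 0-based half-open on the forward strand throughout; GFF
  1-based inclusive coordinates are converted at the I/O boundary.
  Translation uses the bacterial code (table 11) with the start codon
  forced to M; ambiguous bases become N and translate to X; internal stops
  are flagged rather than fatal.
- Insert alignment ranks by path score; exact ties break by
  (contig, start, strand). Consensus boundaries tie toward the smaller
  coordinate. Two top location groups with equal read counts and no overlap
  stay `multi_locus` — no arbitrary winner.
- Problem sizes in the test suite (50-kb to 6.5-Mb genomes, 10^2–10^5
  barcodes, up to 3 × 10^6 reads per sample, three seeds for stochastic
  claims) were chosen as the smallest sizes at which the statistical
  assertions have comfortable margins under the stated model.
- Degenerate inputs: empty read sets yield empty tables and zeroed
  summaries; an empty quality vector has expected error 0; `chao1({})`
  returns zeros; experiments lacking a same-day Time0 raise; a strand-bias
  ratio with no promoter-same genes is NaN.
- Known limitations: the mapper does not split concatemers into usable
  cassettes or polish insert consensi; negative-tail (deleterious) calling
  is out of scope; region definitions are purely interval-based, so two
  causative genes inside one overlap component share a region until manual
  review separates them.
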
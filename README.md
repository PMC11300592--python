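# bobaseq

Analysis toolkit for **barcoded shotgun-overexpression screens** in
bacteria: libraries in which randomly sheared ~3-kb genomic fragments are
cloned downstream of an inducible promoter on a replicative vector, each
plasmid tagged with a random 20-nt DNA barcode. Pooled libraries are grown
competitively under selective conditions (single carbon sources,
antibiotics, bile salts, ...) and strain abundances are tracked cheaply by
sequencing the barcode locus alone (BarSeq). The package is aimed at
microbial functional-genomics groups running gain-of-function screens in
hosts such as *Bacteroides*, where poorly annotated genomes make
genotype-to-phenotype mapping the bottleneck.

It covers the full computational workflow:

- **Long-read mapping** — demultiplex amplicons, extract the barcode and
  insert between four fixed 15-bp anchor oligos, reject concatemers,
  wrong-length barcodes and inserts with expected error
  `EE = Σ 10^(-Q/10) > 10`, align inserts to the reference (k-mer
  seed-and-extend), resolve barcodes seen at several genomic locations, and
  emit a barcode → insert mapping table with fully contained genes.
- **BarSeq counting** — per-sample barcode tallies (two primer layouts),
  off-by-1 error collapse against more abundant barcodes, and Chao1 barcode
  diversity `S_obs + f1'^2 / (2 f2)` with singletons `f1' = f1(1-e)`
  discounted for an assumed residual error rate `e ∈ [0, 2%]`.
- **Fitness statistics** — for a barcode with `n` reads in a condition and
  `n0` reads across the paired Time0 samples (totals `N`, `N0` over the
  considered barcodes):

  ```
  f = log2((n + ψ)/N) − log2((n0 + 1/ψ)/N0),      ψ = sqrt(N/N0)
  σ = sqrt(1/(n + ψ) + 1/(n0 + 1/ψ)) / ln 2,      z = f/σ
  ```

  so `f = 0` when `n = n0 = 0` and `ψ = 1` at equal totals. A strain is
  *significant* at `f ≥ 5` and `z ≥ 4`, and *pair-significant* when that
  holds in both same-day replicates.
- **Hit curation** — pair-significant inserts are clustered into genomic
  regions (single-linkage interval overlap); a region is *biologically
  consistent* when confirmed by a second overlapping significant insert or
  by a protein homolog (≥40% identity, ≥75% coverage, BLOSUM62 local
  alignment) in another significant region of the same condition. The
  causative protein is picked by lexicographic maximization of
  (beneficial-insert count, similar-protein count, mean insert fitness).
- **Library QC** — per-gene full-containment coverage, genes-per-fragment
  histogram, fragment-depth in 20-kb windows, promoter strand bias, and a
  missing-gene analysis (long genes, near-identical duplicates, conserved
  missing homologs).
- **Synthetic data** — a seeded generator for genomes of clean ORFs,
  uniform fragment libraries, noisy long reads, and multinomial BarSeq
  screens with planted log2 effects; it provides ground truth for every
  stage and backs the test suite.

## Worked example

`examples/` holds one short script per capability. Scoring a simulated
screen with one gene planted at +6 log2 units
(`python examples/03_fitness_screen.py`) prints:

```
experiment totals: N=1000000, N0=1999998, psi=0.707
pair-significant barcodes (f>=5 and z>=4 in both replicates): 10
strains whose fragment contains the planted gene simgenome_00176: 10; of these, significant: 10
  ACCCTTAC.. cond1_d1_r1: n=7612 n0=227 f=6.06 sigma=0.097 z=62.5
  ...
expected false positives at z>=4 among 599 barcodes: 0.019
```

All ten strains whose fragment contains the planted gene — and no others —
clear both thresholds in both replicates, and the normal-tail expectation
`n × (1 − Φ(4))` says essentially no null barcode should. Curating the same
screen (`python examples/04_curate_hits.py`) groups those strains into one
region and selects the planted gene over its neighbor by the
beneficial-insert count (20 vs. 10, replicates counted separately):

```
region chr:218955-223774 (10 inserts) confirmed_by=overlap causative=simgenome_00176 [auto]
    simgenome_00175: beneficial_inserts=10 similar_in_high_regions=0 mean_f=3.70
    simgenome_00176: beneficial_inserts=20 similar_in_high_regions=0 mean_f=5.99
```

A thin CLI mirrors the library (`bobaseq simulate|map|count|diversity|
fitness|curate|qc`), reading and writing plain FASTA/GFF3/FASTQ/TSV.

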
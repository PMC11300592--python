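"""Characterize a shotgun-expression library: the four standard QC panels.

For a simulated 2,000-fragment library: fragment-depth along the genome in
20-kb windows, the fragment-length distribution, the per-gene
full-containment coverage, the genes-per-fragment histogram, and the strand
bias of contained genes relative to the vector promoter.
"""

import numpy as np

from bobaseq.qc import library_stats
from bobaseq.simulate import sim_genome, sim_library

genome, genes = sim_genome(target_bp=200_000, seed=5)
library = sim_library(genome, genes, 2000, seed=6)

stats = library_stats(library, genes, genome)
print(f"barcodes (uniquely mapped): {stats.n_barcodes}")
print(f"median fragment length: {stats.median_fragment_bp:.0f} bp")
print(f"genes fully covered >=1x: {stats.pct_genes_covered:.1f}%")
print(f"median fragments per gene: {stats.median_per_gene_coverage:.0f}")
print(f"strand bias (opposite/same vs promoter): {stats.strand_bias_ratio:.2f}")
print(f"genes per fragment: {stats.genes_per_fragment_hist}")
depths = [d for _w, d in stats.base_coverage_windows['chr']]
print(f"mean fragment depth per 20-kb window: "
      f"{np.mean(depths):.1f} (min {min(depths):.1f}, max {max(depths):.1f})")
# An unbiased ligation library shows a strand ratio near 1 and window
# depths fluctuating around n_fragments x fragment_length / genome_length.
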
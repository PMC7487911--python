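"""Region calling and gene annotation on a hand-sized q-value profile.

Ten SNPs on one chromosome include a run of three with q < 0.05; the region
seeds there, extends over flanking SNPs with q <= 0.1, and the genes
overlapping it are ranked by distance from the most significant SNP
(rank 1 = closest).
"""

import numpy as np
import pandas as pd

from dcmscan.genio import GeneSet
from dcmscan.regions import annotate_regions, call_regions, summarize_regions

pos = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10]) * 100_000
q = np.array([0.9, 0.4, 0.08, 0.01, 0.004, 0.03, 0.09, 0.5, 0.02, 0.7])

regions = call_regions(pos, q, chrom="1", breed="demo")
for r in regions:
    print(f"region {r.region_id}: 1:{r.start}-{r.end}, "
          f"{r.n_sig_snps} SNPs with q<0.05, peak at {r.peak_pos} (q={r.peak_q})")

genes = GeneSet(pd.DataFrame(
    [("GENE_A", "1", 480_000, 520_000, "protein_coding"),
     ("GENE_B", "1", 640_000, 700_000, "protein_coding"),
     ("GENE_C", "1", 900_000, 950_000, "lncRNA")],
    columns=GeneSet.COLUMNS,
)).protein_coding()

for h in annotate_regions(regions, genes):
    print(f"  {h.gene_id}: {h.distance_bp} bp from peak SNP, rank {h.rank}")

print("\nsummary:")
print(summarize_regions(regions).to_string(index=False))
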
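"""TSS metagene profiles: methylation density in 50-bp bins over TSS +/- 2 kb.

Rows are genes (strand-oriented, bin 0 most upstream), values are
(methylated calls in bin) x 1e6 / (sample-wide calls).  Averaging rows by
expression quartile shows the methylation well around the TSS; subtracting
the control matrix from the injured one shows where injury moved
methylation.
"""

import numpy as np
import pandas as pd

from regenmeth import (
    SimConfig,
    average_profile,
    delta_matrix,
    generate_dataset,
    merge_cpg_strands,
    profile_matrix,
)
from regenmeth.meth_io import MethylCallTable

dataset = generate_dataset(SimConfig(n_genes=40, chrom_length=120_000, seed=11))


def pooled(condition):
    frames = [
        merge_cpg_strands(t.subset_context("CpG")).df
        for t in dataset.samples
        if t.condition == condition
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        .groupby(["chrom", "pos", "strand", "context", "trinucleotide"], as_index=False)
        .sum()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return MethylCallTable(condition, condition, df)


control = profile_matrix(pooled("regenerative_control"), dataset.genes)
injured = profile_matrix(pooled("regenerative_injured"), dataset.genes)
print(f"matrix: {len(control.gene_ids)} genes x {control.n_bins} bins "
      f"(bin {control.tss_bin()} starts at the TSS)")

curves, sizes = average_profile(control, dataset.truth.set_index("gene_id")["quartile"])
lo, hi = control.tss_bin() - 14, control.tss_bin() + 14  # central +/- 700 bp
print("\nmean density in the central well (TSS +/- 700 bp), control tissue:")
for q in ("Q1", "Q2", "Q3", "Q4"):
    print(f"  {q} (n={sizes[q]}): {np.nanmean(curves[q][lo:hi]):8.2f}")
print("The most expressed genes (Q1) have the deepest well - the classic "
      "inverse relation between TSS methylation and expression.")

delta = delta_matrix(injured, control)
affected = dataset.truth.query("effect_sign == 1")["gene_id"]
rows = [delta.gene_ids.index(g) for g in affected]
island = slice(delta.tss_bin() - 5, delta.tss_bin() + 5)  # +/- 250 bp
print(f"\ninjured - control density over the central island, "
      f"hyper-affected genes: {np.nanmean(delta.values[rows][:, island]):.2f}")
print("A positive delta recovers the planted injury-induced promoter "
      "hypermethylation.")
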
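"""Genome-wide %5mC per context, compared across conditions.

Each biological replicate contributes one genome-wide percent-methylated
value per sequence context (CpG / CHG / CHH); conditions are compared with a
one-way ANOVA and, when the omnibus test is significant, Fisher LSD
pairwise post-hocs on the pooled error term.
"""

import pandas as pd

from regenmeth import SimConfig, generate_dataset
from regenmeth.global_stats import compare_conditions, context_fractions

dataset = generate_dataset(SimConfig(n_genes=40, chrom_length=120_000, seed=11))

fractions = pd.concat(
    [context_fractions(t) for t in dataset.samples], ignore_index=True
)
means = fractions.pivot_table(
    index="condition", columns="context", values="percent_methylated"
)
print("mean % methylation per condition (3 replicates each):")
print(means.round(2).to_string())

print("\nper-context ANOVA across the four conditions:")
for context, res in compare_conditions(fractions).items():
    print(f"  {context}: F({res.df_between},{res.df_within}) = {res.F:.2f}, "
          f"p = {res.p:.3g}")
    for a, b, t, p in res.pairwise[:3]:
        print(f"      LSD {a} vs {b}: t = {t:.2f}, p = {p:.3g}")

print("\nNon-CpG (CHG/CHH) methylation separates tissues several-fold and "
      "responds to injury in opposite directions, as the design plants; "
      "CpG differences are confined to promoters and barely move the "
      "genome-wide figure.")
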
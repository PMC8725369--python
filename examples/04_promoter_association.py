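"""Intersect DMRs with promoters and test the methylation-expression link.

Promoters are 750 bp upstream to 250 bp downstream of the TSS, strand-aware.
Genes are classified by the direction of their best overlapping DMR and by
differential expression, and the 2x2 table is tested with Pearson's
chi-squared (df = 1, no continuity correction).
"""

from regenmeth import (
    FdrConfig,
    SimConfig,
    call_dmrs,
    classify_expression,
    contingency_chi2,
    filter_dmrs,
    generate_dataset,
    intersect_dmrs_promoters,
    merge_cpg_strands,
    tally_directions,
)
from regenmeth.exceptions import RegenmethError
from regenmeth.promoter_assoc import add_promoters

# couple expression to methylation so the association is visible, and keep
# enough genes of both effect signs to populate the whole 2x2 table
config = SimConfig(n_genes=200, chrom_length=500_000, seed=11,
                   hyper_fraction=0.7, affected_fraction=0.4, dmr_de_coupling=0.9)
dataset = generate_dataset(config)
merged = [merge_cpg_strands(t.subset_context("CpG")) for t in dataset.samples]

dmrs = filter_dmrs(
    call_dmrs(
        merged,
        dataset.sample_ids("regenerative_injured"),
        dataset.sample_ids("regenerative_control"),
    ),
    FdrConfig(),
).retained

genes = add_promoters(dataset.genes).merge(
    dataset.expression.rename(columns={"fdr": "de_fdr"}), on="gene_id"
)
genes = classify_expression(genes)
genes = intersect_dmrs_promoters(dmrs, genes)

n_hyper, n_hypo, frac = tally_directions(genes)
print(f"promoter-DMR genes: {n_hyper} hyper + {n_hypo} hypo "
      f"-> fraction hyper = {frac:.2f}")
print(f"(generator planted hyper with probability {config.hyper_fraction})")

try:
    res = contingency_chi2(genes)
    print(f"\n2x2 table (rows hyper/hypo, cols up/down):\n{res.table}")
    print(f"chi2(1, N = {res.N}) = {res.chi2:.2f}, p = {res.p:.3g}, "
          f"OR = {res.odds_ratio:.2f}")
    print("\nA large chi2 means DMR direction and expression direction are "
          "associated; with dmr_de_coupling = 0 the same analysis gives a "
          "null (uniform p) result.")
except RegenmethError as exc:
    print(f"\nassociation untestable on this draw: {exc}")
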
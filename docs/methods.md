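# Methods

This note documents the models, parameter choices and numerical conventions
behind `regenmeth`, in the order data flow through the pipeline.

## Coordinate and format conventions

All in-memory coordinates are 0-based half-open; the Bismark dialects on
disk stay 1-based and are converted only at the file boundary. This keeps
interval arithmetic (promoter overlap, region splitting, binning) free of
off-by-one ambiguity, with lossless round trips.

CpG dinucleotides are palindromic, so their two strand records are merged
into one record at the + strand cytosine before any CpG analysis, conserving
counts exactly; a − strand CpG without a + partner is kept as a singleton
and logged. CHG/CHH contexts are not palindromic and are never merged —
strand-specific non-CpG methylation is the community convention.

Binned tracks and profile matrices use the depth-normalized density
`(counts in bin) × 10⁶ / (sample-wide call total)`. The normalization total
is computed genome-wide per sample (not per matrix); this makes densities
invariant under uniform count scaling and comparable across samples of
different depth. A per-matrix alternative would rescale all rows of one
sample by a common factor and is available by renormalizing the output.
Log2 ratio tracks add a pseudocount ψ (default 1.0 density unit) to both
operands; antisymmetry under operand swap holds exactly at ψ = 0.

## The synthetic study

The generator emulates the statistical structure of a WGBS comparison of
regenerative vs non-regenerative nervous tissue at toy scale. Defaults are
the study conditions the analysis targets:

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes × chrom_length` | 2 × 500 kb | toy genome; large enough for ~2200 testable regions, small enough for minute-scale runs |
| `n_genes` | 400 | genes laid out at even spacing so promoters/wells never overlap |
| `coverage_mean` | 15 reads/site | Poisson per-site coverage |
| `n_replicates` | 3 per condition | biological replicates |
| `conditions` | {regenerative, nonregenerative} × {control, injured} | 12 samples |
| `cpg_background_meth` | 0.85 | CpG methylation far from promoters |
| `well_halfwidth` | 700 bp | low-methylation well around each TSS |
| `island_halfwidth` | 250 bp | denser-CpG island band inside the well, carrying a +0.1 methylation bump (capped at background) |
| `well_floor_by_quartile` | 0.05/0.15/0.30/0.50 | well depth tied to expression quartile, Q1 (most expressed) deepest |
| `noncpg_baseline_by_tissue` | 0.010 / 0.028 | CHG/CHH methylation, a 2.8-fold tissue difference |
| `noncpg_injury_multiplier` | ×2.8 regenerative, ×0.5 nonregenerative | opposite non-CpG injury responses |
| `promoter_effect_logit` | 2.0 | planted promoter effect, log-odds scale |
| `hyper_fraction` | 0.94 | share of affected promoters whose effect is positive (regenerative tissue) |
| `affected_fraction` | 0.3 | share of genes with a promoter effect |
| `replicate_dispersion` φ | 0.01 | beta-binomial across-replicate dispersion |

The CpG surface is background methylation with a smooth cosine-tapered dip
to the quartile floor at the TSS; any smooth monotone dip would serve, and
the taper is an internal function that can be swapped. The injury effect is
applied on the logit scale inside the promoter window — symmetric for
hyper/hypo and automatically bounded. A gene's effect sign is drawn once
(positive with probability `hyper_fraction`); the non-regenerative tissue
applies the negated sign, mirroring the opposing injury responses of the
two tissue types.

Counts: per-site coverage is Poisson, the replicate-level methylation
proportion is Beta with mean equal to the surface value and variance
`φ·p(1−p)` (so the counts are beta-binomial with inflation `1+(n−1)φ`),
and methylated calls are binomial. Coverage dispersion and replicate
variance are conventions — the study design they emulate states only mean
coverage and replicate count. CpG dinucleotide counts are split binomially
between strands (methylated calls hypergeometrically), so re-merging the
strands recovers the drawn counts exactly.

Expression: FPKMs are log-normal; quartiles follow the descending-FPKM
ranking. A `de_fraction` of genes is differentially expressed with
log2 fold-changes `±N(1.5, 0.5)` and small FDRs. `dmr_de_coupling` is the
probability that an affected gene is *forced* DE with direction matching
its methylation effect; 0 (the default) leaves methylation and expression
independent, which is the regime in which the 2×2 association must be null.
Both regimes are needed because tissue-level comparisons show a strong
methylation–expression association while regenerative-injury comparisons
do not.

What the generator does **not** emulate: read-level data (no FASTQs, no
bisulfite-conversion failure), genome sequence composition, duplicated
(homeologous) chromosomes, correlated dispersion between neighbouring
sites, or isoform-level TSS ambiguity. Passing tests therefore demonstrate
the statistical machinery on data matching the model's assumptions, not
robustness to alignment artifacts or annotation error.

## DMR calling

Sites with coverage ≥ 3 in every sample are clustered: maximal runs with
inter-site gaps ≤ 100 bp, at least 3 sites, split greedily left-to-right at
500 bp. These numeric defaults mirror the documented defaults of the
standard CpG-clustering tool; all are exposed in `ClusterParams`. Region
boundaries depend only on positions and the coverage mask, never on
methylation values. Ties in splitting are resolved left-to-right for
determinism.

The Wald test uses pooled-count group proportions, with 0.5/0.5
pseudo-counts added to a group's sums only when the proportion would hit
0 or 1 (keeps `W` finite; standard practice). Dispersion estimation is the
one genuinely open design point with three replicates:

- the per-region method-of-moments estimate (mode `"region"`) is floored at
  zero and is so noisy at r = 3 that most regions floor out, which makes
  the test anti-conservative (measured type-I ≈ 0.076 at p < 0.05);
- the default mode `"pooled"` instead estimates one genome-wide variance
  inflation factor per group, `κ = Σ d² / Σ p̂(1−p̂)·mean(1/n)` over regions
  (d² the bias-corrected mean squared deviation of replicate proportions
  from the pooled proportion), and sets `Var(p̂) = κ ×` binomial variance.
  κ may fall below 1: a region mixing sites of very different methylation
  levels (e.g. spanning the TSS well) has true binomial variance *below*
  what the pooled p̂(1−p̂) implies, and a zero-floored dispersion cannot
  express that. Measured on null simulations at the study design, pooled
  mode gives type-I error 0.050 and uniform p-values both on homogeneous
  regions and on the full synthetic genome, and recovers the planted
  dispersion (κ̂ ≈ 1.46 vs theoretical 1 + (n−1)φ ≈ 1.44 at φ = 0.01,
  n ≈ 45).

`force_phi=0` reduces the test exactly to the unpooled two-proportion
z-test, which is the oracle used in the test suite. Non-CpG contexts are
never run through the caller; the DMR analysis is CpG-only.

## Empirical FDR

π₀ is `#{p > λ}/((1−λ)·m)` at λ = 0.3, clipped to [0, 1] (the raw estimator
can exceed 1 by chance). q-values are the Storey step-down transform,
bounded by π₀ and monotone in p by construction. The final list is the
p < 0.05 subset with q ≤ `q_max`; the cutoff defaults to 0.05 and is
logged per comparison together with λ and π₀, because the "optimal FDR" of
the two-stage protocol is a per-comparison choice that must stay auditable.
On mixture simulations at the study design the realized false-discovery
proportion averages within 0.01 of the nominal q cutoff.

## Promoter association

Promoter = [TSS−750, TSS+250) on the + strand and its exact mirror
[TSS−249, TSS+751) on the − strand; both are 1000 bp, clipped (with a
warning) only at chromosome edges. Overlap is ≥ 1 bp under half-open
semantics. A gene overlapped by DMRs of both directions takes the direction
of the smallest-p DMR — a deterministic rule for a case the protocol leaves
open. Expression classes: up/down require DE FDR below threshold (default
0.05) *and* a nonzero log2 fold-change; log2fc exactly 0 is `ns` because
its direction is undefined. Quartiles split the descending-FPKM ranking
into four near-equal blocks, remainders to the earlier quartiles, ties
broken by gene id.

The 2×2 test is Pearson's Χ² without continuity correction (the analysis
operates at hundreds-to-thousands of genes, where the correction only
biases); a `continuity=True` switch exists for sensitivity checks. The
odds ratio adds 0.5 to every cell only when some cell is zero (Haldane).
Tables with a zero margin raise a degenerate-table error rather than
returning a meaningless statistic.

## TSS profiles

Matrices are genes × 80 bins (50 bp over TSS ± 2 kb), rows in transcript
orientation: bin 0 is the most upstream bin and the TSS base sits at the
start of bin 40 (the first downstream bin) — an anchoring convention that
must simply be fixed and documented. Strand handling is exact: reflecting a
gene's coordinates about its TSS and flipping its strand reproduces the
identical row. Bins falling off a chromosome end are missing (NaN) and are
excluded from group averages rather than zero-filled, avoiding edge bias.
Heatmap export orders rows by descending row sum (intensity), the reading
of "clustered from highest to lowest" adopted here; the unsorted matrix is
always available.

## Pipeline

Comparisons are ordered pairs — `diff`, `W` and Δ profiles are always
first-minus-second — so hyper/hypo directly mean "more/less methylated in
the first condition". The run report embeds the config echo, the seed,
per-stage summaries and a sha256 manifest of every file written; identical
config + seed reproduces identical bytes. A stage that cannot run on the
data at hand (e.g. a degenerate association table when effects are almost
all one-directional) contributes an explicit skip record instead of
failing the run.

## Problem sizes

Default problem sizes (400 genes over 1 Mb, ~2200 testable regions, 12
samples; 100-replicate calibration loops at m = 2000 run at the region
level rather than regenerating genomes) were chosen so the full test suite
and the acceptance script each complete in about a minute on one CPU while
keeping every tally large enough for the stated statistical tolerances.

## Known limitations

- The Wald test's normal reference is asymptotic; regions with very few
  calls lean on the pseudo-count stabilization.
- The pooled κ assumes dispersion is exchangeable across the genome; a
  genome with strongly locus-dependent replicate variance would want the
  per-region or blended modes.
- One TSS per gene; no isoform or alternative-promoter handling.
- π₀ estimation at a single λ = 0.3 (no smoothed λ path, no local FDR).
- bedGraph/TSV outputs only; no BAM input or bigWig output.
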
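# regenmeth

Differential DNA-methylation analysis for whole-genome bisulfite sequencing
(WGBS) of regenerative versus non-regenerative central nervous system
tissue — from per-cytosine methylation counts to promoter-level conclusions
about how injury rewires the methylome.

## Who this is for

Amphibian CNS regions differ sharply in their ability to regenerate axons
(e.g. tadpole hindbrain and optic tissue regenerate; post-metamorphic
hindbrain does not), and injury drives opposite methylation responses in the
two kinds of tissue: promoter **hyper**methylation where regeneration
succeeds, **hypo**methylation where it fails. `regenmeth` implements the
count-level statistical pipeline needed to quantify that picture from
Bismark-style methylation call tables, and ships a ground-truth-annotated
synthetic data generator so every stage can be validated end to end without
multi-gigabyte sequencing archives.

## The statistics at the core

- **DMR calling.** CpG sites covered in every sample are clustered into
  candidate regions (inter-site gap ≤ 100 bp, ≥ 3 sites, ≤ 500 bp). Region
  counts are modeled beta-binomially: replicate *i* of group *g* contributes
  counts with proportion variance `p_g(1−p_g)(1+(n_i−1)φ_g)/n_i`. The test
  statistic is a Wald ratio

  `W = (p̂₁ − p̂₂) / sqrt(Var(p̂₁) + Var(p̂₂))`, `p = 2(1 − Φ(|W|))`,

  with the dispersion pooled genome-wide by default (a variance inflation
  factor `κ` per group) so the test stays calibrated with only three
  replicates. Every region is reported, whatever its effect size.
- **Empirical FDR.** The null proportion is read off the flat tail of the
  p-value distribution, `π₀ = #{p > λ}/((1−λ)m)` with λ = 0.3; Storey
  q-values `q₍ⱼ₎ = min_{k≥j} π₀ m p₍ₖ₎/k` then filter the p < 0.05 subset at
  q ≤ 0.05.
- **Promoter association.** Promoters are strand-aware windows from 750 bp
  upstream to 250 bp downstream of the TSS. Genes are classified by the
  direction of their best overlapping DMR and by differential expression,
  and the hyper/hypo × up/down table is tested with Pearson's Χ² (df = 1,
  no continuity correction).
- **TSS metagene profiles.** Methylation density in 50-bp bins over
  TSS ± 2 kb, normalized as `(methylated calls in bin) × 10⁶ / (sample-wide
  calls)`, averaged by expression quartile or DMR direction, with
  injured-minus-control Δ matrices.
- **Global context statistics.** Genome-wide %5mC per context (CpG/CHG/CHH)
  per replicate, compared across conditions by one-way ANOVA with Fisher
  LSD post-hocs.

## Worked example

```bash
python examples/06_full_pipeline.py
```

runs the whole analysis on a synthetic study (400 genes, four conditions ×
3 replicates at ~15× coverage, 30% of genes given a promoter effect that is
hypermethylating 94% of the time under regenerative injury) and prints:

```
regions tested: 2204, pi0 = 0.840, retained = 289 (272 hyper / 17 hypo)
promoter-DMR genes: fraction hyper = 0.949 (planted: 0.94)
well depth by quartile: {"Q1": 22.5, "Q2": 28.0, "Q3": 34.6, "Q4": 44.7}
```

Reading: 2204 candidate regions were Wald-tested; the p > 0.3 tail puts the
null proportion at 0.84; 289 regions survive the empirical FDR filter, and
among genes whose promoter carries one, 94.9% are hypermethylated —
recovering the planted 94%. The quartile numbers are mean methylation
density in the central well (TSS ± 700 bp): the most expressed quartile
(Q1) has the deepest well, the classic inverse relation between TSS
methylation and expression.

The other examples each demonstrate one capability: dataset generation
(`01`), global context statistics (`02`), DMR calling + FDR (`03`), the
2×2 methylation–expression association (`04`), and metagene profiles
(`05`). The same stages are available from the shell:

```bash
regenmeth run-all --config my_run.yaml --out runs/demo --seed 7
```

## Layout

- `src/regenmeth/` — the library: `simulate` (generator), `meth_io`
  (formats and tracks), `global_stats`, `dmr_caller`, `empirical_fdr`,
  `promoter_assoc`, `tss_profiles`, `pipeline` and the `cli` layer.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model assumptions, parameter meanings and numerical
  choices.
- `tests/` — the pytest suite, including acceptance-level checks.
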
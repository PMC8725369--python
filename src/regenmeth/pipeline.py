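"""End-to-end orchestration: simulate -> global stats -> DMRs -> FDR ->
promoter annotation -> TSS profiles -> association.

A single structured config (YAML file or plain dict) drives the run.  Every
stage writes its tabular output under the run directory and contributes a
section to the machine-readable run report (``report.json``); stages that
cannot run on the data at hand (e.g. a degenerate contingency table) leave
an explicit skip record instead.  Identical config + seed reproduces an
identical report and identical files.

Minimal config::

    seed: 7
    outdir: runs/demo
    simulation: {n_genes: 400}
    comparison:
      group_a: regenerative_injured
      group_b: regenerative_control
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import global_stats, meth_io, promoter_assoc, tss_profiles
from .dmr_caller import ClusterParams, call_dmrs, write_dmr_table
from .empirical_fdr import FdrConfig, filter_dmrs
from .exceptions import DegenerateTableError, RegenmethError, ValidationError
from .simulate import SimConfig, SimDataset, generate_dataset, read_gene_bed, write_dataset

logger = logging.getLogger(__name__)


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError("pipeline config must be a mapping")
    return config


def _load_inputs(cfg: dict, outdir: Path):
    """Either generate a synthetic dataset or load files named in the config."""
    if "simulation" in cfg:
        sim_kwargs = dict(cfg["simulation"])
        sim_kwargs.setdefault("seed", cfg.get("seed", 0))
        simconfig = SimConfig(**sim_kwargs)
        dataset = generate_dataset(simconfig)
        write_dataset(dataset, outdir / "data")
        genes = dataset.genes
        expression = dataset.expression
        samples = dataset.samples
        truth = dataset.truth
    elif "inputs" in cfg:
        inp = cfg["inputs"]
        samples = [
            meth_io.read_cytosine_report(s["path"], s.get("sample_id"), s.get("condition", ""))
            for s in inp["samples"]
        ]
        genes = read_gene_bed(inp["genes_bed"])
        expression = pd.read_csv(inp["expression_tsv"], sep="\t").rename(
            columns={"fpkm_A": "fpkm_a", "fpkm_B": "fpkm_b"}
        )
        truth = None
        dataset = None
    else:
        raise ValidationError("config needs either a 'simulation' or an 'inputs' block")
    return samples, genes, expression, truth


def _resolve_group(samples, spec) -> list[str]:
    """A group is a condition name or an explicit list of sample ids."""
    ids = {t.sample_id for t in samples}
    if isinstance(spec, str):
        group = [t.sample_id for t in samples if t.condition == spec]
        if not group:
            raise ValidationError(f"no samples with condition {spec!r}")
        return group
    group = list(spec)
    unknown = set(group) - ids
    if unknown:
        raise ValidationError(f"unknown sample ids {sorted(unknown)}")
    return group


def _pool_condition(tables) -> meth_io.MethylCallTable:
    """Sum replicate counts into one pooled table (post strand-merge)."""
    df = pd.concat([t.df for t in tables], ignore_index=True)
    pooled = (
        df.groupby(["chrom", "pos", "strand", "context", "trinucleotide"], as_index=False)[
            ["meth", "unmeth"]
        ]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return meth_io.MethylCallTable(tables[0].condition + "_pooled", tables[0].condition, pooled)


def run_pipeline(config: str | Path | dict, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis and return the run report (also serialized).

    Stage order: simulate/load, global stats (context fractions + per-context
    ANOVA/LSD), CpG strand merge, DMR calling, empirical FDR filtering,
    promoter annotation and quartiles, TSS profile matrices and deltas, and
    the methylation-expression 2x2 association.
    """
    cfg = load_config(config)
    if "simulation" not in cfg and "inputs" not in cfg:
        raise ValidationError("config needs either a 'simulation' or an 'inputs' block")
    outdir = Path(outdir or cfg.get("outdir", "regenmeth_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.get("seed", 0), "config": _echo(cfg), "stages": {}}

    samples, genes, expression, truth = _load_inputs(cfg, outdir)

    # ---- global statistics -------------------------------------------------
    fractions = pd.concat([global_stats.context_fractions(t) for t in samples],
                          ignore_index=True)
    fractions.to_csv(outdir / "context_fractions.tsv", sep="\t", index=False)
    anovas = global_stats.compare_conditions(fractions, alpha=cfg.get("anova_alpha", 0.05))
    report["stages"]["global_stats"] = {
        "fractions": fractions.to_dict(orient="records"),
        "anova": {
            ctx: {
                "F": r.F, "df_between": r.df_between, "df_within": r.df_within,
                "p": r.p, "mse": r.mse, "group_means": r.group_means,
                "pairwise": [
                    {"a": a, "b": b, "t": t, "p": p} for a, b, t, p in r.pairwise
                ],
            }
            for ctx, r in anovas.items()
        },
    }

    # ---- DMR calling -------------------------------------------------------
    comparison = cfg.get("comparison")
    if comparison is None:
        report["stages"]["dmr"] = {"skipped": "no comparison block in config"}
        _write_report(report, outdir)
        return report

    merged = [meth_io.merge_cpg_strands(t.subset_context("CpG")) for t in samples]
    group_a = _resolve_group(samples, comparison["group_a"])
    group_b = _resolve_group(samples, comparison["group_b"])
    params = ClusterParams(**cfg.get("cluster", {}))
    dmrs = call_dmrs(merged, group_a, group_b, params,
                     dispersion=cfg.get("dispersion", "pooled"))
    write_dmr_table(dmrs, outdir / "dmrs_all.tsv")

    fdr_cfg = FdrConfig(**cfg.get("fdr", {}))
    fdr = filter_dmrs(dmrs, fdr_cfg)
    write_dmr_table(fdr.retained, outdir / "dmrs_retained.tsv")
    logger.info(
        "comparison %s vs %s: lambda=%.2f pi0=%.3f q_max=%.3g m=%d retained=%d",
        comparison["group_a"], comparison["group_b"],
        fdr_cfg.lambda_, fdr.pi0, fdr_cfg.q_max, fdr.m, fdr.n_retained,
    )
    report["stages"]["dmr"] = {
        "group_a": group_a, "group_b": group_b,
        "m": fdr.m, "pi0": fdr.pi0,
        "lambda": fdr_cfg.lambda_, "p_max": fdr_cfg.p_max, "q_max": fdr_cfg.q_max,
        "n_retained": fdr.n_retained,
        "n_hyper": int((fdr.retained["direction"] == "hyper").sum()),
        "n_hypo": int((fdr.retained["direction"] == "hypo").sum()),
    }

    # ---- promoter annotation ----------------------------------------------
    gtab = promoter_assoc.add_promoters(genes)
    gtab = gtab.merge(
        expression.rename(columns={"fdr": "de_fdr"})[["gene_id", "fpkm_a", "log2fc", "de_fdr"]],
        on="gene_id", how="left",
    ).rename(columns={"fpkm_a": "fpkm"})
    if gtab["fpkm"].notna().all() and len(gtab) >= 4:
        gtab = promoter_assoc.quartile_partition(gtab)
    gtab = promoter_assoc.classify_expression(gtab, cfg.get("de_fdr_threshold", 0.05))
    gtab = promoter_assoc.intersect_dmrs_promoters(fdr.retained, gtab)
    gtab.to_csv(outdir / "gene_annotation.tsv", sep="\t", index=False)
    promoter_assoc.write_promoter_bed(gtab, outdir / "promoters.bed")

    try:
        n_hyper, n_hypo, frac = promoter_assoc.tally_directions(gtab)
        tally = {"n_hyper": n_hyper, "n_hypo": n_hypo, "fraction_hyper": frac}
    except RegenmethError as exc:
        tally = {"skipped": str(exc)}
    report["stages"]["promoter_tally"] = tally

    # ---- TSS profiles ------------------------------------------------------
    prof_cfg = cfg.get("profiles", {})
    bin_size = prof_cfg.get("bin_size", 50)
    flank = prof_cfg.get("flank", 2000)
    cond_a = [t for t in merged if t.sample_id in group_a]
    cond_b = [t for t in merged if t.sample_id in group_b]
    mat_a = tss_profiles.profile_matrix(_pool_condition(cond_a), gtab,
                                        bin_size=bin_size, flank=flank)
    mat_b = tss_profiles.profile_matrix(_pool_condition(cond_b), gtab,
                                        bin_size=bin_size, flank=flank)
    delta = tss_profiles.delta_matrix(mat_a, mat_b)
    tss_profiles.write_matrix_tsv(mat_a, outdir / "profile_group_a.tsv")
    tss_profiles.write_matrix_tsv(mat_b, outdir / "profile_group_b.tsv")
    tss_profiles.write_matrix_tsv(delta, outdir / "profile_delta.tsv")

    profile_summary: dict = {"bin_size": bin_size, "flank": flank}
    if "quartile" in gtab.columns:
        grouping = gtab.set_index("gene_id")["quartile"]
        curves, sizes = tss_profiles.average_profile(mat_b, grouping)
        tss_bin = mat_b.tss_bin()
        halfwin = max(1, 700 // bin_size)
        profile_summary["well_mean_by_quartile"] = {
            q: float(np.nanmean(c[tss_bin - halfwin:tss_bin + halfwin]))
            for q, c in curves.items()
        }
        profile_summary["group_sizes"] = sizes
    dgroup = gtab.set_index("gene_id")["dmr_class"]
    dcurves, dsizes = tss_profiles.average_profile(delta, dgroup)
    island_bins = max(1, 250 // bin_size)
    tss_bin = delta.tss_bin()
    profile_summary["delta_island_mean_by_dmr_class"] = {
        k: float(np.nanmean(c[tss_bin - island_bins:tss_bin + island_bins]))
        for k, c in dcurves.items()
    }
    report["stages"]["profiles"] = profile_summary

    # ---- association -------------------------------------------------------
    try:
        cont = promoter_assoc.contingency_chi2(gtab, continuity=cfg.get("continuity", False))
        report["stages"]["association"] = {
            "table": cont.table.tolist(), "N": cont.N,
            "chi2": cont.chi2, "df": cont.df, "p": cont.p, "odds_ratio": cont.odds_ratio,
        }
    except RegenmethError as exc:
        report["stages"]["association"] = {"skipped": str(exc)}

    if truth is not None:
        truth.to_csv(outdir / "truth_echo.tsv", sep="\t", index=False)

    _write_report(report, outdir)
    return report


def _echo(cfg: dict) -> dict:
    return json.loads(json.dumps(cfg, default=str))


def _write_report(report: dict, outdir: Path) -> None:
    manifest = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "report.json":
            manifest[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    report["file_manifest"] = manifest
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
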
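"""Seeded synthetic bisulfite datasets with known ground truth.

The generator emulates the statistical structure of a whole-genome bisulfite
study of regenerative versus non-regenerative nervous tissue, at toy scale:

* a small genome (2 chromosomes x 500 kb by default) with gene models whose
  promoters never overlap, CpG sites laid down densely (a CpG island) within
  ``island_halfwidth`` of each TSS and sparsely elsewhere, plus strand-
  specific CHG/CHH sites;
* a CpG methylation *surface*: heavily methylated background (default 0.85)
  with a smooth cosine-tapered well of reduced methylation within
  ``well_halfwidth`` of each TSS whose floor depends on the gene's
  expression quartile (deepest for the most expressed genes), carrying a
  small bump of re-methylation over the central island;
* condition effects: genes drawn as "affected" receive a promoter-window
  methylation shift on the log-odds scale in injured samples — positive
  (hypermethylation) with probability ``hyper_fraction`` in the regenerative
  tissue and the opposite sign in the non-regenerative tissue, mirroring the
  opposing injury responses of the two tissue types; non-CpG methylation has
  tissue-specific baselines (a few-fold apart) scaled by per-tissue injury
  multipliers;
* counts: per-site coverage is Poisson with mean ``coverage_mean`` (15 by
  default, three replicates per condition), replicate-level methylation
  proportions are Beta-distributed around the surface value with dispersion
  ``replicate_dispersion``, and methylated counts are Binomial — i.e. the
  beta-binomial model the downstream Wald test assumes;
* a coupled expression table (FPKM, log2 fold-change, FDR) with a tunable
  fraction of DE genes and an optional coupling that forces affected genes
  to be differentially expressed in the direction of their methylation
  effect (coupling 0 = independence).

Everything is driven by one :class:`SimConfig` and one integer seed;
identical config + seed reproduces identical bytes on disk.  The ground
truth (per-gene effect sign, DE direction, quartile) is kept alongside the
data for parameter-recovery tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContextError, SizingError, ValidationError
from .meth_io import CALL_COLUMNS, MethylCallTable, write_cytosine_report
from .promoter_assoc import promoter_window, quartile_partition

logger = logging.getLogger(__name__)

TISSUES = ("regenerative", "nonregenerative")
INJURIES = ("control", "injured")


def condition_name(tissue: str, injury: str) -> str:
    return f"{tissue}_{injury}"

DEFAULT_CONDITIONS = tuple(condition_name(t, i) for t in TISSUES for i in INJURIES)


def split_condition(condition: str) -> tuple[str, str]:
    tissue, injury = condition.rsplit("_", 1)
    if tissue not in TISSUES or injury not in INJURIES:
        raise ValidationError(f"unknown condition {condition!r}")
    return tissue, injury


@dataclass
class SimConfig:
    """Study-design and effect-size parameters for the generator.

    Defaults are the study conditions the analysis targets: 15x mean
    coverage, three replicates per condition, a ~0.85 CpG methylation
    background with a +/-700 bp TSS well containing a +/-250 bp island band,
    quartile-dependent well floors (Q1 = most expressed = deepest), non-CpG
    baselines a 2.8-fold apart between tissues, and injury multipliers that
    raise non-CpG methylation in regenerative tissue and lower it in
    non-regenerative tissue.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 400
    coverage_mean: float = 15.0
    n_replicates: int = 3
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    cpg_background_meth: float = 0.85
    well_halfwidth: int = 700
    island_halfwidth: int = 250
    well_floor_by_quartile: tuple[float, float, float, float] = (0.05, 0.15, 0.30, 0.50)
    noncpg_baseline_by_tissue: dict = field(
        default_factory=lambda: {"regenerative": 0.010, "nonregenerative": 0.028}
    )
    noncpg_injury_multiplier: dict = field(
        default_factory=lambda: {"regenerative": 2.8, "nonregenerative": 0.5}
    )
    promoter_effect_logit: float = 2.0
    hyper_fraction: float = 0.94
    affected_fraction: float = 0.3
    de_fraction: float = 0.3
    de_log2fc_mean: float = 1.5
    de_log2fc_sd: float = 0.5
    dmr_de_coupling: float = 0.0
    replicate_dispersion: float = 0.01
    cpg_island_density: float = 0.10   # CpG sites per bp within the island band
    cpg_background_density: float = 0.02
    noncpg_density: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.cpg_background_meth, self.hyper_fraction, self.affected_fraction,
            self.de_fraction, self.dmr_de_coupling, self.replicate_dispersion,
            *self.well_floor_by_quartile,
            *self.noncpg_baseline_by_tissue.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        floors = list(self.well_floor_by_quartile)
        if sorted(floors) != floors:
            raise ValidationError("well_floor_by_quartile must be non-decreasing Q1..Q4")
        if self.coverage_mean <= 0:
            raise ValidationError("coverage_mean must be positive")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.island_halfwidth > self.well_halfwidth:
            raise ValidationError("island_halfwidth must not exceed well_halfwidth")
        for c in self.conditions:
            split_condition(c)


# ---------------------------------------------------------------------------
# genome construction


def build_genome(config: SimConfig, rng: np.random.Generator):
    """Gene models and cytosine site map for a toy genome.

    Genes are laid out at regular spacing (no promoter or well overlap is
    possible by construction), strands drawn Bernoulli(0.5).  CpG sites are
    sampled with elevated density within ``island_halfwidth`` of a TSS and
    background density elsewhere; non-CpG (CHG/CHH) sites are sampled
    uniformly on random strands.  Returns (genes, sites) DataFrames; CpG
    sites are dinucleotide records on the + strand (downstream writers emit
    both strand reports).
    """
    config.validate()
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genes_per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    genes_per_chrom[: config.n_genes % config.n_chromosomes] += 1

    margin = 2 * config.well_halfwidth + 1000
    gene_rows = []
    gid = 0
    for chrom, n in zip(chroms, genes_per_chrom):
        if n == 0:
            continue
        spacing = config.chrom_length // (n + 1)
        if spacing < margin:
            raise SizingError(
                f"{chrom}: {n} genes do not fit in {config.chrom_length} bp "
                f"(need spacing >= {margin})"
            )
        for k in range(n):
            tss = (k + 1) * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"gene{gid:04d}", chrom, strand, tss))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "tss"])

    h_bases = np.array(list("ACT"))
    site_frames = []
    for chrom in chroms:
        dens = np.full(config.chrom_length, config.cpg_background_density)
        for tss in genes.loc[genes["chrom"] == chrom, "tss"]:
            lo = max(0, tss - config.island_halfwidth)
            hi = min(config.chrom_length, tss + config.island_halfwidth + 1)
            dens[lo:hi] = config.cpg_island_density
        # CpG dinucleotides occupy two bases, so candidate positions are the
        # even offsets thinned at twice the per-bp density: overlap-free by
        # construction with the requested expected density per bp
        candidates = np.arange(0, config.chrom_length - 1, 2)
        cpg_pos = candidates[
            rng.random(len(candidates)) < np.minimum(1.0, 2.0 * dens[candidates])
        ]
        n_cpg = len(cpg_pos)
        cpg = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": cpg_pos,
                "strand": "+",
                "context": "CpG",
                "trinucleotide": np.char.add("CG", rng.choice(list("ACGT"), n_cpg)),
            }
        )
        ncg_pos = np.flatnonzero(rng.random(config.chrom_length) < config.noncpg_density)
        ncg_pos = np.setdiff1d(ncg_pos, np.union1d(cpg_pos, cpg_pos + 1))
        n_ncg = len(ncg_pos)
        is_chg = rng.random(n_ncg) < 0.5
        h1 = rng.choice(h_bases, n_ncg)
        h2 = rng.choice(h_bases, n_ncg)
        tri = np.where(is_chg, np.char.add(np.char.add("C", h1), "G"),
                       np.char.add(np.char.add("C", h1), h2))
        ncg = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": ncg_pos,
                "strand": np.where(rng.random(n_ncg) < 0.5, "+", "-"),
                "context": np.where(is_chg, "CHG", "CHH"),
                "trinucleotide": tri,
            }
        )
        site_frames.append(pd.concat([cpg, ncg], ignore_index=True))
    sites = pd.concat(site_frames, ignore_index=True) if site_frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "context", "trinucleotide"]
    )
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return genes, sites


# ---------------------------------------------------------------------------
# the methylation surface


def _cosine_well(dist: np.ndarray, floor: np.ndarray, config: SimConfig) -> np.ndarray:
    """Smooth dip from the background to ``floor`` at the TSS."""
    bg = config.cpg_background_meth
    t = np.clip(dist / config.well_halfwidth, 0.0, 1.0)
    return floor + (bg - floor) * (1 - np.cos(np.pi * t)) / 2


def methylation_surface(
    gene: dict | pd.Series | None,
    site_pos: int,
    context: str,
    condition: str,
    config: SimConfig,
    quartile: str | None = None,
    effect_sign: int = 0,
) -> float:
    """True methylation probability of one site under one condition.

    ``gene`` supplies chrom/strand/tss (None for a site far from any gene);
    ``quartile`` ('Q1'..'Q4') selects the well floor; ``effect_sign`` is the
    gene's promoter effect (+1 hyper, -1 hypo, 0 none) already resolved for
    the tissue in question and applied only in injured conditions, on the
    log-odds scale inside the promoter window.
    """
    tissue, injury = split_condition(condition)
    if context in ("CHG", "CHH"):
        base = config.noncpg_baseline_by_tissue[tissue]
        if injury == "injured":
            base = base * config.noncpg_injury_multiplier[tissue]
        return float(np.clip(base, 0.001, 0.999))
    if context != "CpG":
        raise ContextError(f"unknown context {context!r}")

    bg = config.cpg_background_meth
    if gene is None:
        return float(np.clip(bg, 0.001, 0.999))
    tss = int(gene["tss"])
    dist = abs(site_pos - tss)
    if dist >= config.well_halfwidth:
        p = bg
    else:
        qidx = int((quartile or "Q4")[1]) - 1
        floor = config.well_floor_by_quartile[qidx]
        p = float(_cosine_well(np.array([dist]), np.array([floor]), config)[0])
        if dist <= config.island_halfwidth:
            p = min(p + 0.1, bg)
    if effect_sign != 0 and injury == "injured":
        ps, pe = promoter_window(tss, gene["strand"])
        if ps <= site_pos < pe:
            logit = np.log(p / (1 - p)) + effect_sign * config.promoter_effect_logit
            p = 1 / (1 + np.exp(-logit))
    return float(np.clip(p, 0.001, 0.999))


def _surface_vector(
    sites: pd.DataFrame, genes: pd.DataFrame, truth: pd.DataFrame,
    condition: str, config: SimConfig,
) -> np.ndarray:
    """Vectorized methylation surface over the whole site map."""
    tissue, injury = split_condition(condition)
    p = np.empty(len(sites))

    ctx = sites["context"].to_numpy()
    noncpg = ctx != "CpG"
    base = config.noncpg_baseline_by_tissue[tissue]
    if injury == "injured":
        base *= config.noncpg_injury_multiplier[tissue]
    p[noncpg] = base

    cpg_mask = ~noncpg
    p[cpg_mask] = config.cpg_background_meth
    pos_all = sites["pos"].to_numpy()

    tinfo = truth.set_index("gene_id")
    for _, gene in genes.iterrows():
        tss = int(gene["tss"])
        row = tinfo.loc[gene["gene_id"]]
        qidx = int(row["quartile"][1]) - 1
        floor = config.well_floor_by_quartile[qidx]
        sign = int(row["effect_sign"])
        if tissue == "nonregenerative":
            sign = -sign

        near = (
            cpg_mask
            & (sites["chrom"].to_numpy() == gene["chrom"])
            & (np.abs(pos_all - tss) < config.well_halfwidth)
        )
        if not near.any():
            continue
        dist = np.abs(pos_all[near] - tss)
        floors = np.full(dist.shape, floor)
        vals = _cosine_well(dist, floors, config)
        island = dist <= config.island_halfwidth
        vals[island] = np.minimum(vals[island] + 0.1, config.cpg_background_meth)
        if sign != 0 and injury == "injured":
            ps, pe = promoter_window(tss, gene["strand"])
            prom = (pos_all[near] >= ps) & (pos_all[near] < pe)
            logit = np.log(vals[prom] / (1 - vals[prom])) + sign * config.promoter_effect_logit
            vals[prom] = 1 / (1 + np.exp(-logit))
        p[near] = vals
    return np.clip(p, 0.001, 0.999)


# ---------------------------------------------------------------------------
# count sampling


def sample_counts(
    prob: float | np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Beta-binomial replicate counts at one or more sites.

    For each of ``n_replicates`` replicates: total ~ Poisson(coverage_mean);
    the replicate-level proportion is Beta with mean ``prob`` and dispersion
    phi = ``replicate_dispersion`` (phi = 0 collapses to the binomial);
    methylated count ~ Binomial(total, proportion).  Returns (meth, total)
    arrays of shape (n_sites, n_replicates).
    """
    prob = np.atleast_1d(np.asarray(prob, dtype=float))
    n = prob.size
    r = config.n_replicates
    total = rng.poisson(config.coverage_mean, size=(n, r))
    phi = config.replicate_dispersion
    if phi > 0:
        # Beta(a, b) with a+b = (1-phi)/phi has Var = phi * mu(1-mu)
        s = (1.0 - phi) / phi
        a = np.clip(prob * s, 1e-12, None)
        b = np.clip((1.0 - prob) * s, 1e-12, None)
        props = rng.beta(a[:, None], b[:, None], size=(n, r))
    else:
        props = np.broadcast_to(prob[:, None], (n, r))
    meth = rng.binomial(total, props)
    return meth, total


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SimDataset:
    """A complete generated study: genes, truth, expression, samples."""

    config: SimConfig
    genes: pd.DataFrame
    truth: pd.DataFrame
    expression: pd.DataFrame
    samples: list[MethylCallTable]

    def sample_ids(self, condition: str | None = None) -> list[str]:
        return [
            t.sample_id for t in self.samples
            if condition is None or t.condition == condition
        ]


def _draw_truth(genes: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene ground truth and the matching expression table.

    Expression levels are log-normal FPKMs; quartiles follow the descending
    FPKM ranking.  ``effect_sign`` is the promoter methylation effect in the
    regenerative tissue (+1 with probability hyper_fraction among affected
    genes); the non-regenerative tissue applies the negated sign.  DE status
    is drawn independently at ``de_fraction``; with probability
    ``dmr_de_coupling`` an affected gene is instead forced DE with direction
    matching its methylation effect, so coupling 0 means independence.
    """
    n = len(genes)
    fpkm = np.exp(rng.normal(1.0, 1.5, size=n))
    gtab = genes.copy()
    gtab["fpkm"] = fpkm
    gtab = quartile_partition(gtab)

    affected = rng.random(n) < config.affected_fraction
    sign = np.where(rng.random(n) < config.hyper_fraction, 1, -1)
    effect_sign = np.where(affected, sign, 0)

    de = rng.random(n) < config.de_fraction
    de_dir = np.where(rng.random(n) < 0.5, 1, -1)
    coupled = affected & (rng.random(n) < config.dmr_de_coupling)
    de = de | coupled
    de_dir = np.where(coupled, effect_sign, de_dir)

    log2fc = np.where(
        de,
        de_dir * np.abs(rng.normal(config.de_log2fc_mean, config.de_log2fc_sd, size=n)),
        rng.normal(0.0, 0.1, size=n),
    )
    de_fdr = np.where(de, rng.uniform(1e-6, 0.04, size=n), rng.uniform(0.1, 1.0, size=n))

    truth = pd.DataFrame(
        {
            "gene_id": gtab["gene_id"],
            "effect_sign": effect_sign,
            "de_direction": np.where(de, np.where(de_dir > 0, "up", "down"), "none"),
            "quartile": gtab["quartile"],
        }
    )
    ratio = 2.0 ** log2fc
    expression = pd.DataFrame(
        {
            "gene_id": gtab["gene_id"],
            "fpkm_a": fpkm * np.sqrt(ratio),
            "fpkm_b": fpkm / np.sqrt(ratio),
            "log2fc": log2fc,
            "fdr": de_fdr,
        }
    )
    return truth, expression


def _split_cpg_strands(
    cpg: pd.DataFrame, meth: np.ndarray, total: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Distribute dinucleotide counts over the two strand records.

    Read totals split Binomial(total, 1/2) between strands and methylated
    calls hypergeometrically, so re-merging the strands recovers the
    dinucleotide counts exactly.
    """
    t_plus = rng.binomial(total, 0.5)
    m_plus = rng.hypergeometric(
        np.maximum(meth, 0), np.maximum(total - meth, 0), t_plus
    )
    t_minus = total - t_plus
    m_minus = meth - m_plus
    comp = np.char.add("CG", cpg["trinucleotide"].str[2].to_numpy().astype("U1"))
    plus = pd.DataFrame(
        {
            "chrom": cpg["chrom"], "pos": cpg["pos"], "strand": "+",
            "context": "CpG", "trinucleotide": cpg["trinucleotide"],
            "meth": m_plus, "unmeth": t_plus - m_plus,
        }
    )
    minus = pd.DataFrame(
        {
            "chrom": cpg["chrom"], "pos": cpg["pos"] + 1, "strand": "-",
            "context": "CpG", "trinucleotide": comp,
            "meth": m_minus, "unmeth": t_minus - m_minus,
        }
    )
    return pd.concat([plus, minus], ignore_index=True)


def generate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Generate the full study: genome, truth, expression and all samples."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, sites = build_genome(config, rng)
    if genes.empty:
        truth = pd.DataFrame(columns=["gene_id", "effect_sign", "de_direction", "quartile"])
        expression = pd.DataFrame(columns=["gene_id", "fpkm_a", "fpkm_b", "log2fc", "fdr"])
    else:
        truth, expression = _draw_truth(genes, config, rng)

    cpg = sites[sites["context"] == "CpG"].reset_index(drop=True)
    ncg = sites[sites["context"] != "CpG"].reset_index(drop=True)

    samples: list[MethylCallTable] = []
    for condition in config.conditions:
        probs = _surface_vector(sites, genes, truth, condition, config) if len(sites) else np.empty(0)
        p_cpg = probs[(sites["context"] == "CpG").to_numpy()]
        p_ncg = probs[(sites["context"] != "CpG").to_numpy()]
        meth_c, tot_c = sample_counts(p_cpg, config, rng) if len(cpg) else (
            np.zeros((0, config.n_replicates), dtype=int),) * 2
        meth_n, tot_n = sample_counts(p_ncg, config, rng) if len(ncg) else (
            np.zeros((0, config.n_replicates), dtype=int),) * 2
        for rep in range(config.n_replicates):
            frames = []
            if len(cpg):
                frames.append(_split_cpg_strands(cpg, meth_c[:, rep], tot_c[:, rep], rng))
            if len(ncg):
                nd = ncg.copy()
                nd["meth"] = meth_n[:, rep]
                nd["unmeth"] = tot_n[:, rep] - meth_n[:, rep]
                frames.append(nd[CALL_COLUMNS])
            df = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=CALL_COLUMNS)
            )
            df = df.astype({"pos": np.int64, "meth": np.int64, "unmeth": np.int64})
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
            samples.append(MethylCallTable(f"{condition}_rep{rep + 1}", condition, df))
    return SimDataset(config, genes, truth, expression, samples)


def write_dataset(dataset: SimDataset, out_dir: str | Path) -> dict:
    """Write the dataset in its on-disk formats and return the manifest.

    Emits per-sample cytosine reports, BED6 gene models, the expression TSV,
    the truth TSV and ``manifest.json`` (seed, config echo, per-file sha256).
    Files round-trip losslessly through the meth_io readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}

    for table in dataset.samples:
        path = out_dir / f"{table.sample_id}.CpG_report.txt"
        write_cytosine_report(table, path)
        files[path.name] = _sha256(path)

    bed = pd.DataFrame(
        {
            "chrom": dataset.genes["chrom"],
            "start": dataset.genes["tss"],
            "end": dataset.genes["tss"] + 1,
            "name": dataset.genes["gene_id"],
            "score": 0,
            "strand": dataset.genes["strand"],
        }
    )
    # BED6 anchors each gene at its TSS base; strand column orients the promoter
    bed_path = out_dir / "genes.bed"
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    files[bed_path.name] = _sha256(bed_path)

    expr_path = out_dir / "expression.tsv"
    dataset.expression.rename(
        columns={"fpkm_a": "fpkm_A", "fpkm_b": "fpkm_B"}
    ).to_csv(expr_path, sep="\t", index=False, float_format="%.6g")
    files[expr_path.name] = _sha256(expr_path)

    truth_path = out_dir / "truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t", index=False)
    files[truth_path.name] = _sha256(truth_path)

    manifest = {
        "seed": dataset.config.seed,
        "config": _jsonable(asdict(dataset.config)),
        "files": files,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 gene models back into the genes table layout."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    return pd.DataFrame(
        {"gene_id": df["gene_id"], "chrom": df["chrom"], "strand": df["strand"],
         "tss": df["start"]}
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
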
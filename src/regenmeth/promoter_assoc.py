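"""Promoter windows, DMR-promoter intersection and methylation-expression
association.

Promoters are strand-aware 1-kb windows spanning 750 bp upstream to 250 bp
downstream of the TSS.  Genes are cross-classified by the direction of their
best overlapping promoter DMR (hyper/hypo) and by differential expression
(up/down at an FDR threshold), and the resulting 2x2 table is tested with a
Pearson chi-squared (df = 1), by default without continuity correction.

Gene tables are plain DataFrames with at least ``gene_id, chrom, strand,
tss`` and optionally ``fpkm, log2fc, de_fdr``; the operations here add the
derived columns (promoter bounds, quartile, expr_class, dmr_class, dmr_p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateTableError, ValidationError

logger = logging.getLogger(__name__)

UPSTREAM = 750
DOWNSTREAM = 250


def promoter_window(tss: int, strand: str) -> tuple[int, int]:
    """Strand-aware promoter interval (0-based half-open) around a TSS.

    On the + strand the window is [tss-750, tss+250); on the - strand its
    mirror image [tss-249, tss+751).  Both are 1000 bp.  Windows extending
    past the chromosome start are clipped at 0 with a warning.
    """
    if strand == "+":
        start, end = tss - UPSTREAM, tss + DOWNSTREAM
    elif strand == "-":
        start, end = tss - (DOWNSTREAM - 1), tss + UPSTREAM + 1
    else:
        raise ValidationError(f"gene has no usable strand: {strand!r}")
    if start < 0:
        logger.warning("promoter window clipped at chromosome start (tss=%d)", tss)
        start = 0
    return start, end


def add_promoters(genes: pd.DataFrame) -> pd.DataFrame:
    """Add promoter_start/promoter_end columns to a gene table."""
    out = genes.copy()
    windows = [promoter_window(int(t), s) for t, s in zip(out["tss"], out["strand"])]
    out["promoter_start"] = [w[0] for w in windows]
    out["promoter_end"] = [w[1] for w in windows]
    return out


def intersect_dmrs_promoters(dmrs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene the direction of its best overlapping promoter DMR.

    A gene is assigned when at least one retained DMR overlaps its promoter
    by >= 1 bp (half-open interval semantics).  If several DMRs overlap, the
    one with the smallest p decides the direction.  Genes without overlap get
    dmr_class 'none' and dmr_p NaN.
    """
    genes = genes if "promoter_start" in genes.columns else add_promoters(genes)
    out = genes.copy()
    out["dmr_class"] = "none"
    out["dmr_p"] = np.nan
    if dmrs.empty:
        return out
    for chrom, gsub in out.groupby("chrom"):
        dsub = dmrs[dmrs["chrom"] == chrom]
        if dsub.empty:
            continue
        d_start = dsub["start"].to_numpy()
        d_end = dsub["end"].to_numpy()
        d_p = dsub["p"].to_numpy()
        d_dir = dsub["direction"].to_numpy()
        for i in gsub.index:
            ps, pe = out.at[i, "promoter_start"], out.at[i, "promoter_end"]
            hit = (d_start < pe) & (d_end > ps)
            if hit.any():
                best = np.flatnonzero(hit)[np.argmin(d_p[hit])]
                out.at[i, "dmr_class"] = d_dir[best]
                out.at[i, "dmr_p"] = d_p[best]
    return out


def tally_directions(genes: pd.DataFrame) -> tuple[int, int, float]:
    """(n_hyper, n_hypo, fraction_hyper) over genes with a promoter DMR."""
    if "dmr_class" not in genes.columns:
        raise ValidationError("dmr_class not filled; run intersect_dmrs_promoters")
    n_hyper = int((genes["dmr_class"] == "hyper").sum())
    n_hypo = int((genes["dmr_class"] == "hypo").sum())
    if n_hyper + n_hypo == 0:
        raise ValidationError("no genes carry a classified promoter DMR")
    return n_hyper, n_hypo, n_hyper / (n_hyper + n_hypo)


def classify_expression(genes: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Classify genes as up/down/ns from log2fc and DE FDR.

    up: de_fdr < threshold and log2fc > 0; down: de_fdr < threshold and
    log2fc < 0; everything else (including log2fc exactly 0, where direction
    is undefined) is ns.  Genes missing DE statistics are classed ns with a
    warning.
    """
    out = genes.copy()
    if "log2fc" not in out.columns or "de_fdr" not in out.columns:
        logger.warning("DE statistics missing; all genes classed ns")
        out["expr_class"] = "ns"
        return out
    lfc = out["log2fc"].to_numpy(dtype=float)
    fdr = out["de_fdr"].to_numpy(dtype=float)
    missing = np.isnan(lfc) | np.isnan(fdr)
    if missing.any():
        logger.warning("%d gene(s) missing DE stats classed ns", int(missing.sum()))
    sig = ~missing & (fdr < fdr_threshold)
    out["expr_class"] = np.where(
        sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns")
    )
    return out


def quartile_partition(genes: pd.DataFrame) -> pd.DataFrame:
    """Assign expression quartiles Q1 (highest FPKM) .. Q4 (lowest).

    Genes are ranked by fpkm descending (ties broken by gene_id for
    determinism) and split into four blocks of near-equal size, remainders
    going to the earlier quartiles.
    """
    if len(genes) < 4:
        raise ValidationError("quartile partition needs at least 4 genes")
    if genes["fpkm"].isna().any():
        raise ValidationError("fpkm missing for some genes")
    out = genes.copy()
    order = out.sort_values(["fpkm", "gene_id"], ascending=[False, True], kind="mergesort").index
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    labels = np.repeat([f"Q{i + 1}" for i in range(4)], sizes)
    out.loc[order, "quartile"] = labels
    return out


@dataclass
class ContingencyResult:
    """2x2 association of promoter-DMR direction with expression direction.

    ``table`` rows are (hyper, hypo), columns (up, down)."""

    table: np.ndarray
    N: int
    chi2: float
    df: int
    p: float
    odds_ratio: float


def contingency_chi2(
    genes: pd.DataFrame | None = None,
    table=None,
    continuity: bool = False,
) -> ContingencyResult:
    """Pearson chi-squared on the hyper/hypo x up/down gene table.

    Either pass a classified gene table (rows with dmr_class in
    {hyper, hypo} AND expr_class in {up, down} are cross-tabulated; ns genes
    are excluded) or a raw 2x2 ``table``.  No continuity correction by
    default; the odds ratio gets 0.5 added to every cell iff any cell is 0.
    """
    if table is None:
        if genes is None:
            raise ValidationError("pass either a gene table or a 2x2 table")
        sub = genes[
            genes["dmr_class"].isin(["hyper", "hypo"])
            & genes["expr_class"].isin(["up", "down"])
        ]
        table = np.array(
            [
                [
                    int(((sub["dmr_class"] == m) & (sub["expr_class"] == e)).sum())
                    for e in ("up", "down")
                ]
                for m in ("hyper", "hypo")
            ]
        )
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError("contingency table must be 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin; chi-squared undefined")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=continuity)
    a, b, c, d = table.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return ContingencyResult(
        table=table.astype(int),
        N=int(table.sum()),
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        odds_ratio=float((a * d) / (b * c)),
    )


def write_promoter_bed(genes: pd.DataFrame, path) -> None:
    """Write promoter windows as BED6."""
    genes = genes if "promoter_start" in genes.columns else add_promoters(genes)
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["promoter_start"],
            "end": genes["promoter_end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
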
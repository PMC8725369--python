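"""Strand-oriented binned methylation/read density matrices around the TSS.

Every gene contributes one row of ``2*flank/bin_size`` bins spanning
TSS +/- flank (defaults: 2 kb flank, 50 bp bins, 80 columns).  Bins are laid
out 5'->3' in transcript orientation: bin 0 is the most upstream bin and the
TSS base sits at the start of bin ``flank/bin_size`` (the first downstream
bin), so rows from + and - strand genes are directly comparable.  Cell
values use the sample-depth normalization
``(counts in bin) x 1e6 / (sample-wide total calls)``; bins that fall off
the chromosome end are missing (NaN) and excluded from averages.

Group averages (by expression quartile, by promoter-DMR direction, or any
custom labelling) and cellwise difference matrices reproduce the metagene
curves and the injury-minus-control delta profiles used to read promoter
methylation changes.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, NormalizationError, ValidationError
from .meth_io import MethylCallTable

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Genes x bins density matrix in transcript orientation."""

    gene_ids: list[str]
    values: np.ndarray = field(repr=False)  # (n_genes, n_bins), NaN = missing
    bin_size: int = 50
    flank: int = 2000
    mode: str = "meth"
    sample_id: str = ""

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def tss_bin(self) -> int:
        """Index of the first downstream bin (the bin whose start is the TSS)."""
        return self.flank // self.bin_size


def profile_matrix(
    table: MethylCallTable,
    genes: pd.DataFrame,
    mode: str = "meth",
    bin_size: int = 50,
    flank: int = 2000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> ProfileMatrix:
    """Build the TSS-centred density matrix for one sample.

    ``genes`` needs gene_id, chrom, strand, tss.  In ``meth`` mode counts are
    methylated calls; in ``reads`` mode per-site call totals stand in for
    read counts.  The normalization denominator is the sample-wide total.
    """
    if flank % bin_size != 0:
        raise ValidationError("flank must be a multiple of bin_size")
    df = table.df
    if mode == "meth":
        norm = float(df["meth"].sum() + df["unmeth"].sum())
        site_weight = lambda sub: sub["meth"].to_numpy(dtype=float)  # noqa: E731
    elif mode == "reads":
        norm = float(df["meth"].sum() + df["unmeth"].sum())
        site_weight = lambda sub: (sub["meth"] + sub["unmeth"]).to_numpy(dtype=float)  # noqa: E731
    else:
        raise ValidationError(f"unknown profile mode {mode!r}")
    if norm <= 0:
        raise NormalizationError("zero normalization total for profile matrix")

    n_bins = 2 * flank // bin_size
    values = np.zeros((len(genes), n_bins))
    by_chrom = {
        chrom: (sub["pos"].to_numpy(), site_weight(sub))
        for chrom, sub in df.groupby("chrom")
    }
    # positions within each chrom are sorted (table invariant), enabling searchsorted
    for row, (_, gene) in enumerate(genes.iterrows()):
        chrom, tss, strand = gene["chrom"], int(gene["tss"]), gene["strand"]
        pos, w = by_chrom.get(chrom, (np.empty(0, dtype=int), np.empty(0)))
        if strand == "-":
            lo, hi = tss - flank + 1, tss + flank + 1  # offsets tss - pos in [-flank, flank)
        else:
            lo, hi = tss - flank, tss + flank
        i0, i1 = np.searchsorted(pos, [lo, hi])
        window_pos, window_w = pos[i0:i1], w[i0:i1]
        off = (tss - window_pos) if strand == "-" else (window_pos - tss)
        bins = (off + flank) // bin_size
        values[row, :] = np.bincount(bins, weights=window_w, minlength=n_bins)[:n_bins]
        # mark bins whose genomic span leaves the chromosome as missing
        clip_left = max(0, -lo)
        clip_right = 0
        if chrom_lengths is not None and hi > chrom_lengths.get(chrom, hi):
            clip_right = hi - chrom_lengths[chrom]
        if clip_left or clip_right:
            n_lo = -(-clip_left // bin_size)  # ceil
            n_hi = -(-clip_right // bin_size)
            if strand == "-":
                n_lo, n_hi = n_hi, n_lo
            if n_lo:
                values[row, :n_lo] = np.nan
            if n_hi:
                values[row, n_bins - n_hi:] = np.nan
            logger.debug("gene %s window clipped (%d/%d bins)", gene["gene_id"], n_lo, n_hi)
    values *= 1e6 / norm
    return ProfileMatrix(
        gene_ids=list(genes["gene_id"]),
        values=values,
        bin_size=bin_size,
        flank=flank,
        mode=mode,
        sample_id=table.sample_id,
    )


def average_profile(
    matrix: ProfileMatrix, grouping: Mapping[str, str] | pd.Series
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Per-group mean curve over matrix rows; missing bins excluded.

    ``grouping`` maps gene_id -> group label and must cover every row.
    Returns (curves, group sizes); empty groups are simply absent.
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    labels = []
    for g in matrix.gene_ids:
        if g not in grouping:
            raise ValidationError(f"grouping does not cover gene {g}")
        labels.append(grouping[g])
    labels = np.asarray(labels)
    curves: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for label in sorted(set(labels.tolist())):
        rows = matrix.values[labels == label]
        with np.errstate(invalid="ignore"):
            curves[label] = np.nanmean(rows, axis=0)
        sizes[label] = int((labels == label).sum())
    return curves, sizes


def delta_matrix(a: ProfileMatrix, b: ProfileMatrix) -> ProfileMatrix:
    """Cellwise a - b of two normalized density matrices."""
    if a.gene_ids != b.gene_ids or a.values.shape != b.values.shape or a.mode != b.mode:
        raise AlignmentError("profile matrices not aligned (genes/bins/mode differ)")
    return ProfileMatrix(
        gene_ids=list(a.gene_ids),
        values=a.values - b.values,
        bin_size=a.bin_size,
        flank=a.flank,
        mode=a.mode,
        sample_id=f"{a.sample_id}-{b.sample_id}",
    )


def sort_rows(matrix: ProfileMatrix) -> ProfileMatrix:
    """Rows reordered by descending row sum (heatmap intensity order)."""
    with np.errstate(invalid="ignore"):
        sums = np.nansum(matrix.values, axis=1)
    order = np.argsort(-sums, kind="mergesort")
    return ProfileMatrix(
        gene_ids=[matrix.gene_ids[i] for i in order],
        values=matrix.values[order],
        bin_size=matrix.bin_size,
        flank=matrix.flank,
        mode=matrix.mode,
        sample_id=matrix.sample_id,
    )


def write_matrix_tsv(matrix: ProfileMatrix, path: str | Path) -> Path:
    path = Path(path)
    cols = [f"bin_{i}" for i in range(matrix.n_bins)]
    pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=cols).to_csv(
        path, sep="\t", index_label="gene_id", float_format="%.6g"
    )
    return path


def write_deeptools_matrix(
    matrix: ProfileMatrix, genes: pd.DataFrame, path: str | Path
) -> Path:
    """Write a deepTools-compatible gzipped matrix (JSON header + TSV body)."""
    path = Path(path)
    header = {
        "upstream": [matrix.flank],
        "downstream": [matrix.flank],
        "body": [0],
        "bin size": [matrix.bin_size],
        "ref point": ["TSS"],
        "sample_labels": [matrix.sample_id],
        "group_labels": ["genes"],
        "sample_boundaries": [0, matrix.n_bins],
        "group_boundaries": [0, len(matrix.gene_ids)],
    }
    gidx = genes.set_index("gene_id")
    with gzip.open(path, "wt") as fh:
        fh.write("@" + json.dumps(header) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            g = gidx.loc[gid]
            start, end = int(g["tss"]), int(g["tss"]) + 1
            vals = "\t".join("nan" if np.isnan(v) else f"{v:.6g}" for v in row)
            fh.write(f"{g['chrom']}\t{start}\t{end}\t{gid}\t0\t{g['strand']}\t{vals}\n")
    return path
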
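"""Methylation call-table I/O and binned genome tracks.

This module is the boundary between on-disk bisulfite formats and the
in-memory representation the rest of the package works with.

On disk we speak two Bismark dialects:

* **cytosine report** — one row per cytosine: ``chrom  pos(1-based)  strand
  count_methylated  count_unmethylated  context  trinucleotide``;
* **coverage** — one row per covered cytosine: ``chrom  start(1-based)
  end(1-based)  percent_methylated  count_methylated  count_unmethylated``
  (no strand or context columns).

In memory everything is 0-based half-open: a :class:`MethylCallTable` wraps a
pandas DataFrame with columns ``chrom, pos, strand, context, trinucleotide,
meth, unmeth`` sorted by (chrom, pos).  Conversion happens only at the file
boundary, so interval arithmetic downstream is unambiguous.

Binned density tracks follow the normalization
``(counts in bin) x 1e6 / (total calls in sample)`` so tracks from samples
sequenced to different depths are comparable, and log2-ratio tracks compare
two such tracks bin by bin with a pseudocount.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ContextError,
    FormatError,
    NormalizationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "trinucleotide", "meth", "unmeth"]

_CONTEXTS = ("CpG", "CHG", "CHH")


def classify_context(trinucleotide: str) -> str:
    """Classify a cytosine trinucleotide into CpG, CHG or CHH.

    The trinucleotide reads 5'->3' on the strand carrying the cytosine, so the
    first base must be C.  CpG if the second base is G; otherwise CHG if the
    third base is G; otherwise CHH (H = A, C or T).

    Raises
    ------
    ContextError
        If the first base is not C or any base is outside {A, C, G, T}.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or any(b not in "ACGT" for b in tri):
        raise ContextError(f"invalid trinucleotide {trinucleotide!r}")
    if tri[0] != "C":
        raise ContextError(f"trinucleotide {trinucleotide!r} does not start with C")
    if tri[1] == "G":
        return "CpG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


@dataclass
class MethylCallTable:
    """Per-sample cytosine methylation calls.

    Attributes
    ----------
    sample_id:
        Free-text sample identifier.
    condition:
        Condition descriptor (opaque to this module; the simulator uses
        ``tissue_injury`` strings).
    df:
        DataFrame with columns :data:`CALL_COLUMNS`; ``pos`` is 0-based,
        rows sorted by (chrom, pos).
    """

    sample_id: str
    condition: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"call table missing columns {missing}")
        if (self.df["meth"] < 0).any() or (self.df["unmeth"] < 0).any():
            raise ValidationError("negative methylation counts")

    @property
    def total_calls(self) -> int:
        """Genome-wide number of methylation calls (meth + unmeth)."""
        return int(self.df["meth"].sum() + self.df["unmeth"].sum())

    def subset_context(self, context: str) -> "MethylCallTable":
        if context not in _CONTEXTS:
            raise ContextError(f"unknown context {context!r}")
        return replace(self, df=self.df[self.df["context"] == context].reset_index(drop=True))

    def sorted(self) -> "MethylCallTable":
        df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return replace(self, df=df)


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.astype({"pos": np.int64, "meth": np.int64, "unmeth": np.int64})
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def read_cytosine_report(
    path: str | Path, sample_id: str | None = None, condition: str = ""
) -> MethylCallTable:
    """Read a Bismark-style cytosine report into a :class:`MethylCallTable`.

    Positions are converted from the 1-based on-disk convention to 0-based.
    Lines with the wrong column count raise :class:`FormatError` naming the
    line; negative counts raise :class:`ValidationError`.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 TAB-separated columns, got {len(fields)}"
                )
            chrom, pos, strand, meth, unmeth, context, tri = fields
            try:
                pos_i, meth_i, unmeth_i = int(pos), int(meth), int(unmeth)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed integer field") from exc
            if meth_i < 0 or unmeth_i < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            rows.append((chrom, pos_i - 1, strand, context, tri, meth_i, unmeth_i))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=CALL_COLUMNS)
    return MethylCallTable(sample_id or path.stem, condition, _finalize(df))


def write_cytosine_report(table: MethylCallTable, path: str | Path) -> Path:
    """Write a call table in cytosine-report dialect (1-based positions)."""
    path = Path(path)
    out = table.df[CALL_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out = out[["chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide"]]
    out.to_csv(path, sep="\t", header=False, index=False)
    return path


def read_coverage(
    path: str | Path,
    sample_id: str | None = None,
    condition: str = "",
    context: str = "CpG",
) -> MethylCallTable:
    """Read a Bismark coverage file.

    The coverage dialect carries no strand or context columns; records get
    strand ``.`` and the supplied ``context`` (CpG by default, which is what
    Bismark's coverage output contains), with an empty trinucleotide.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 TAB-separated columns, got {len(fields)}"
                )
            chrom, start, _end, _pct, meth, unmeth = fields
            try:
                pos_i, meth_i, unmeth_i = int(start), int(meth), int(unmeth)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed integer field") from exc
            if meth_i < 0 or unmeth_i < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            rows.append((chrom, pos_i - 1, ".", context, "", meth_i, unmeth_i))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=CALL_COLUMNS)
    return MethylCallTable(sample_id or path.stem, condition, _finalize(df))


def write_coverage(table: MethylCallTable, path: str | Path) -> Path:
    """Write a call table in Bismark coverage dialect (1-based, inclusive)."""
    path = Path(path)
    df = table.df
    total = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * df["meth"] / total, 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"] + 1,
            "end": df["pos"] + 1,
            "pct": pct,
            "meth": df["meth"],
            "unmeth": df["unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
    return path


def merge_cpg_strands(table: MethylCallTable) -> MethylCallTable:
    """Collapse CpG dinucleotides to a single record on the + strand.

    A CpG is palindromic: the cytosine on the - strand sits one base
    downstream (pos+1) of its + strand partner.  Counts from the two strands
    are summed and reported at the + strand position.  CHG/CHH records are
    non-palindromic and pass through untouched.  A - strand CpG with no +
    partner is kept as a singleton at its own position (and logged), so
    genome-wide counts are conserved exactly.
    """
    df = table.df
    cpg = df[df["context"] == "CpG"]
    rest = df[df["context"] != "CpG"]
    if cpg.empty:
        return table.sorted()

    plus = cpg[cpg["strand"] != "-"].copy()
    minus = cpg[cpg["strand"] == "-"].copy()
    if minus.empty:
        return table.sorted()

    # partner a - strand C at pos with the + strand C at pos-1
    minus["partner_pos"] = minus["pos"] - 1
    merged = plus.merge(
        minus[["chrom", "partner_pos", "meth", "unmeth"]],
        left_on=["chrom", "pos"],
        right_on=["chrom", "partner_pos"],
        how="left",
        suffixes=("", "_minus"),
    )
    merged["meth"] = merged["meth"] + merged["meth_minus"].fillna(0).astype(np.int64)
    merged["unmeth"] = merged["unmeth"] + merged["unmeth_minus"].fillna(0).astype(np.int64)
    merged["strand"] = "+"
    merged = merged[CALL_COLUMNS]

    paired = minus.merge(
        plus[["chrom", "pos"]],
        left_on=["chrom", "partner_pos"],
        right_on=["chrom", "pos"],
        how="left",
        suffixes=("", "_plus"),
        indicator=True,
    )
    orphans = paired[paired["_merge"] == "left_only"]
    if not orphans.empty:
        logger.info(
            "merge_cpg_strands: %d - strand CpG(s) without a + partner kept as singletons",
            len(orphans),
        )
    orphans = orphans[CALL_COLUMNS]

    out = pd.concat([merged, orphans, rest], ignore_index=True)
    return replace(table, df=_finalize(out))


@dataclass
class TrackConfig:
    """Parameters shared by track operations.

    ``bin_size`` is the genomic bin width in bp; ``pseudocount`` is the
    density-unit offset added to both operands of a log2 ratio to keep it
    finite in empty bins.
    """

    bin_size: int = 50
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")


@dataclass
class BinnedTrack:
    """Fixed-width binned signal along one chromosome."""

    chrom: str
    bin_size: int
    values: np.ndarray
    normalization_total: float

    def __len__(self) -> int:
        return len(self.values)


def density_track(
    table: MethylCallTable,
    config: TrackConfig | None = None,
    mode: str = "meth",
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, BinnedTrack]:
    """Binned signal density per chromosome.

    In ``meth`` mode the bin value is (sum of methylated counts in the bin)
    x 1e6 / (sample-wide total calls); in ``reads`` mode methylated counts
    are replaced by per-site read (call) totals and the denominator by the
    sample-wide read total.  The normalization total is computed genome-wide
    per sample, so doubling all counts leaves the track unchanged.
    """
    config = config or TrackConfig()
    df = table.df
    if mode == "meth":
        counts = df["meth"].to_numpy(dtype=np.float64)
        norm = float(df["meth"].sum() + df["unmeth"].sum())
    elif mode == "reads":
        counts = (df["meth"] + df["unmeth"]).to_numpy(dtype=np.float64)
        norm = float(counts.sum())
    else:
        raise ValidationError(f"unknown track mode {mode!r}")
    if norm <= 0:
        raise NormalizationError("zero normalization total for density track")

    tracks: dict[str, BinnedTrack] = {}
    chroms = (
        list(chrom_lengths) if chrom_lengths is not None else sorted(df["chrom"].unique())
    )
    for chrom in chroms:
        sub = df["chrom"] == chrom
        pos = df.loc[sub, "pos"].to_numpy()
        if chrom_lengths is not None:
            length = chrom_lengths[chrom]
        else:
            length = int(pos.max()) + 1 if len(pos) else config.bin_size
        nbins = math.ceil(length / config.bin_size)
        values = np.bincount(
            pos // config.bin_size, weights=counts[sub.to_numpy()], minlength=nbins
        )[:nbins]
        tracks[chrom] = BinnedTrack(chrom, config.bin_size, values * 1e6 / norm, norm)
    return tracks


def log2_ratio_track(a: BinnedTrack, b: BinnedTrack, config: TrackConfig | None = None) -> BinnedTrack:
    """Per-bin log2((a + psi)/(b + psi)) of two aligned density tracks."""
    config = config or TrackConfig()
    if a.chrom != b.chrom or a.bin_size != b.bin_size or len(a) != len(b):
        raise AlignmentError(
            f"tracks not aligned: {a.chrom}/{b.chrom}, bin {a.bin_size}/{b.bin_size}, "
            f"len {len(a)}/{len(b)}"
        )
    psi = config.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2((a.values + psi) / (b.values + psi))
    return BinnedTrack(a.chrom, a.bin_size, values, float("nan"))


def write_bedgraph(tracks: Iterable[BinnedTrack] | BinnedTrack, path: str | Path) -> Path:
    """Write one or more binned tracks as bedGraph (0-based half-open)."""
    if isinstance(tracks, BinnedTrack):
        tracks = [tracks]
    path = Path(path)
    with open(path, "w") as fh:
        for track in tracks:
            starts = np.arange(len(track)) * track.bin_size
            for s, v in zip(starts, track.values):
                fh.write(f"{track.chrom}\t{s}\t{s + track.bin_size}\t{v:.6g}\n")
    return path
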
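"""CpG-site clustering into candidate regions and beta-binomial Wald DMR tests.

The caller works in two stages.  First, CpG sites covered in every sample are
clustered into candidate regions: maximal runs of retained sites whose
inter-site gaps do not exceed ``max_gap``, dropped if they hold fewer than
``min_sites`` sites and split greedily left-to-right when they exceed
``max_region_len``.  Per-sample methylated/total counts are summed over a
region's member sites.

Second, each region is tested between two replicate groups with a Wald test
under a beta-binomial count model: group proportions are pooled-count
estimates, per-group dispersion phi is a method-of-moments estimate from the
replicate-level proportions (floored at zero; by default pooled genome-wide,
see :func:`wald_test_counts`), the variance of each group proportion carries
the beta-binomial inflation factor (1 + (n-1)phi), and
W = (p1 - p2) / sqrt(Var1 + Var2) is referred to the standard normal.  All
regions are reported regardless of the size of the difference, so the
downstream empirical-FDR stage sees the full p-value distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .meth_io import MethylCallTable

logger = logging.getLogger(__name__)

DMR_COLUMNS = [
    "chrom", "start", "end", "n_sites",
    "p1", "p2", "diff", "phi1", "phi2", "W", "p", "direction",
]


@dataclass
class ClusterParams:
    """Site-clustering parameters.

    max_gap:
        Largest allowed distance (bp) between adjacent retained sites inside
        one region.
    min_sites:
        Minimum CpG sites per reported region.
    max_region_len:
        Regions longer than this are split greedily left-to-right.
    min_site_coverage:
        A site must have at least this many calls in every sample to be
        retained.
    """

    max_gap: int = 100
    min_sites: int = 3
    max_region_len: int = 500
    min_site_coverage: int = 3

    def __post_init__(self) -> None:
        if min(self.max_gap, self.min_sites, self.max_region_len, self.min_site_coverage) <= 0:
            raise ValidationError("all clustering parameters must be positive")
        if self.max_region_len < self.max_gap:
            raise ValidationError("max_region_len must be >= max_gap")


@dataclass
class RegionCountMatrix:
    """Clustered regions with per-sample summed counts.

    ``regions`` has columns chrom, start, end (0-based half-open), n_sites;
    ``meth`` and ``total`` are (n_regions x n_samples) arrays aligned with
    ``sample_ids``.
    """

    regions: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    sample_ids: list[str]

    def __len__(self) -> int:
        return len(self.regions)


def _check_merged(df: pd.DataFrame) -> None:
    """Reject CpG tables that still carry both strands of a dinucleotide."""
    minus = df[df["strand"] == "-"]
    if minus.empty:
        return
    plus = df[df["strand"] != "-"]
    hit = minus.merge(
        plus[["chrom", "pos"]].assign(pos=lambda d: d["pos"] + 1),
        on=["chrom", "pos"],
        how="inner",
    )
    if not hit.empty:
        raise ValidationError(
            "CpG table appears unmerged: - strand records adjacent to + strand "
            "partners; run merge_cpg_strands first"
        )


def cluster_sites(
    tables: Sequence[MethylCallTable], params: ClusterParams | None = None
) -> RegionCountMatrix:
    """Cluster commonly covered CpG sites into candidate regions.

    Tables must be CpG-context and strand-merged.  The site universe is the
    intersection of (chrom, pos) across samples; a site is retained when its
    coverage is >= ``min_site_coverage`` in every sample.  Region boundaries
    depend only on positions and the coverage mask, never on methylation
    levels.
    """
    params = params or ClusterParams()
    if not tables:
        raise ValidationError("no samples supplied")
    sample_ids = [t.sample_id for t in tables]

    frames = []
    for t in tables:
        df = t.df[t.df["context"] == "CpG"]
        _check_merged(df)
        frames.append(
            df.set_index(["chrom", "pos"])[["meth", "unmeth"]].rename(
                columns={"meth": f"m_{t.sample_id}", "unmeth": f"u_{t.sample_id}"}
            )
        )
    wide = pd.concat(frames, axis=1, join="inner").sort_index()
    if wide.empty:
        return RegionCountMatrix(
            pd.DataFrame(columns=["chrom", "start", "end", "n_sites"]),
            np.zeros((0, len(tables)), dtype=np.int64),
            np.zeros((0, len(tables)), dtype=np.int64),
            sample_ids,
        )

    meth = wide[[f"m_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    unmeth = wide[[f"u_{s}" for s in sample_ids]].to_numpy(dtype=np.int64)
    total = meth + unmeth
    keep = (total >= params.min_site_coverage).all(axis=1)

    idx = wide.index[keep]
    meth, total = meth[keep], total[keep]
    chroms = idx.get_level_values(0).to_numpy()
    pos = idx.get_level_values(1).to_numpy()

    rows, meth_rows, total_rows = [], [], []
    start_i = 0
    n = len(pos)
    for i in range(1, n + 1):
        boundary = (
            i == n
            or chroms[i] != chroms[i - 1]
            or pos[i] - pos[i - 1] > params.max_gap
            or pos[i] - pos[start_i] + 1 > params.max_region_len
        )
        if boundary:
            count = i - start_i
            if count >= params.min_sites:
                rows.append(
                    (chroms[start_i], int(pos[start_i]), int(pos[i - 1]) + 1, count)
                )
                meth_rows.append(meth[start_i:i].sum(axis=0))
                total_rows.append(total[start_i:i].sum(axis=0))
            start_i = i

    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites"])
    return RegionCountMatrix(
        regions,
        np.asarray(meth_rows, dtype=np.int64).reshape(len(rows), len(sample_ids)),
        np.asarray(total_rows, dtype=np.int64).reshape(len(rows), len(sample_ids)),
        sample_ids,
    )


def _moment_pieces(meth: np.ndarray, total: np.ndarray):
    """Per-region moment components for dispersion estimation.

    For one group with counts (m x r): pooled proportion p (with 0.5/0.5
    pseudo-counts when it would hit 0 or 1), the bias-corrected mean squared
    deviation of replicate proportions from p, and the expectation pieces
    E[d2] = pq*mean_inv + phi*pq*mean_frac the MoM estimator inverts.
    Replicates with zero coverage are excluded.
    """
    Sm = meth.sum(axis=1).astype(float)
    St = total.sum(axis=1).astype(float)
    if (St <= 0).any():
        raise ValidationError("group with zero total coverage in a region")
    p = Sm / St
    # 0.5/0.5 pseudo-counts keep boundary proportions off 0/1 so W stays finite
    boundary = (p <= 0) | (p >= 1)
    p = np.where(boundary, (Sm + 0.5) / (St + 1.0), p)

    with np.errstate(invalid="ignore", divide="ignore"):
        covered = total > 0
        ncov = covered.sum(axis=1)
        prop = np.where(covered, meth / np.maximum(total, 1), np.nan)
        d2 = np.nansum((prop - p[:, None]) ** 2, axis=1) / np.maximum(ncov, 1)
        # estimating p from the same replicates deflates the spread ~ (1-1/r)
        d2 = d2 * ncov / np.maximum(ncov - 1, 1)
        mean_inv = np.nansum(np.where(covered, 1.0 / np.maximum(total, 1), np.nan), axis=1)
        mean_inv /= np.maximum(ncov, 1)
        mean_frac = np.nansum(
            np.where(covered, (total - 1) / np.maximum(total, 1), np.nan), axis=1
        )
        mean_frac /= np.maximum(ncov, 1)
    return p, d2, mean_inv, mean_frac, ncov


def _phi_region(p, d2, mean_inv, mean_frac, ncov) -> np.ndarray:
    """Per-region method-of-moments dispersion, floored at 0."""
    pq = p * (1 - p)
    phi = np.where(
        (pq > 0) & (mean_frac > 0) & (ncov > 1),
        (d2 / np.maximum(pq, 1e-300) - mean_inv) / np.maximum(mean_frac, 1e-300),
        0.0,
    )
    return np.clip(phi, 0.0, 1.0)


def _phi_pooled(p, d2, mean_inv, mean_frac, ncov) -> float:
    """Genome-wide pooled MoM dispersion (ratio of summed moments).

    Summing numerator and denominator over regions before dividing makes the
    estimator stable where the noisy per-region estimate is mostly floored
    at zero.
    """
    pq = p * (1 - p)
    use = (ncov > 1) & (pq > 0)
    if not use.any():
        return 0.0
    num = (d2[use] - pq[use] * mean_inv[use]).sum()
    den = (pq[use] * mean_frac[use]).sum()
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))


def _kappa_pooled(p, d2, mean_inv, ncov) -> float:
    """Genome-wide variance inflation factor for the group proportion.

    kappa is the ratio of the observed across-replicate variance of region
    proportions to the binomial variance implied by the pooled proportion,
    pooled over all regions: Var(p_hat) = kappa x (binomial variance).
    Unlike a zero-floored dispersion it may fall below 1, which happens when
    a region mixes sites of very different methylation levels (the pooled
    p(1-p) then overstates the true binomial variance).
    """
    pq = p * (1 - p)
    use = (ncov > 1) & (pq > 0)
    if not use.any():
        return 1.0
    num = d2[use].sum()
    den = (pq[use] * mean_inv[use]).sum()
    if den <= 0:
        return 1.0
    return float(num / den)


def _wald_variance(p, phi, total) -> np.ndarray:
    infl = 1.0 + (total - 1.0) * phi[:, None]
    return (total * (p * (1 - p))[:, None] * infl).sum(axis=1) / total.sum(
        axis=1
    ).astype(float) ** 2


def wald_test_counts(
    meth1: np.ndarray,
    total1: np.ndarray,
    meth2: np.ndarray,
    total2: np.ndarray,
    force_phi: float | None = None,
    dispersion: str = "pooled",
) -> pd.DataFrame:
    """Vectorized beta-binomial Wald test on region count matrices.

    Each input is (m x r_g).  ``dispersion`` selects how the replicate-level
    variance entering the Wald denominator is estimated per group:

    * ``"pooled"`` (default) — one genome-wide variance inflation factor
      kappa per group scales the binomial variance of every region
      (:func:`_kappa_pooled`).  With two or three replicates the per-region
      dispersion estimate is far too noisy (floored at zero for most
      regions) and makes the test anti-conservative; pooling restores
      calibration and is a simple stand-in for hierarchical dispersion
      shrinkage.  The reported phi is the per-replicate dispersion implied
      by kappa, phi = (kappa - 1)/(mean coverage - 1); it can be negative
      when regions are internally heterogeneous.
    * ``"region"`` — the raw per-region MoM dispersion, floored at 0.
    * ``"blend"`` — the even blend of the per-region and genome-pooled
      dispersions (both floored at 0).

    ``force_phi`` overrides all of this with a fixed value (phi = 0 reduces
    the test to the unpooled two-proportion z-test for single replicates).
    """
    meth1, total1 = np.atleast_2d(meth1), np.atleast_2d(total1)
    meth2, total2 = np.atleast_2d(meth2), np.atleast_2d(total2)
    phis = []
    ps = []
    vars_ = []
    for meth, total in ((meth1, total1), (meth2, total2)):
        p, d2, mean_inv, mean_frac, ncov = _moment_pieces(meth, total)
        if force_phi is not None:
            phi = np.full(len(p), float(force_phi))
        elif dispersion == "region":
            phi = _phi_region(p, d2, mean_inv, mean_frac, ncov)
        elif dispersion == "pooled":
            kappa = _kappa_pooled(p, d2, mean_inv, ncov)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_n = np.where(ncov > 0, total.sum(axis=1) / np.maximum(ncov, 1), 1.0)
            phi = (kappa - 1.0) / np.maximum(mean_n - 1.0, 1.0)
            ps.append(p)
            phis.append(phi)
            binom_var = (total * (p * (1 - p))[:, None]).sum(axis=1) / total.sum(
                axis=1
            ).astype(float) ** 2
            vars_.append(kappa * binom_var)
            continue
        elif dispersion == "blend":
            phi = 0.5 * _phi_region(p, d2, mean_inv, mean_frac, ncov) + 0.5 * _phi_pooled(
                p, d2, mean_inv, mean_frac, ncov
            )
        else:
            raise ValidationError(f"unknown dispersion mode {dispersion!r}")
        ps.append(p)
        phis.append(phi)
        vars_.append(_wald_variance(p, phi, total))
    p1, p2 = ps
    phi1, phi2 = phis
    var1, var2 = vars_

    denom = np.sqrt(var1 + var2)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(denom > 0, (p1 - p2) / np.maximum(denom, 1e-300), 0.0)
    p = 2 * stats.norm.sf(np.abs(W))
    diff = p1 - p2
    direction = np.where(diff > 0, "hyper", np.where(diff < 0, "hypo", "none"))
    return pd.DataFrame(
        {
            "p1": p1, "p2": p2, "diff": diff,
            "phi1": phi1, "phi2": phi2,
            "W": W, "p": p, "direction": direction,
        }
    )


def betabinom_wald(
    region_meth1, region_total1, region_meth2, region_total2,
    force_phi=None, dispersion="region",
) -> dict:
    """Single-region convenience wrapper around :func:`wald_test_counts`.

    Inputs are per-replicate count vectors for the two groups; returns a dict
    with p1, p2, diff, phi1, phi2, W, p, direction.
    """
    df = wald_test_counts(
        np.asarray(region_meth1)[None, :],
        np.asarray(region_total1)[None, :],
        np.asarray(region_meth2)[None, :],
        np.asarray(region_total2)[None, :],
        force_phi=force_phi,
        dispersion=dispersion,
    )
    return df.iloc[0].to_dict()


def call_dmrs(
    tables: Sequence[MethylCallTable],
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: ClusterParams | None = None,
    force_phi: float | None = None,
    dispersion: str = "pooled",
) -> pd.DataFrame:
    """Cluster sites and Wald-test every region between two sample groups.

    ``group_a``/``group_b`` name sample_ids; the reported ``diff`` is group A
    minus group B.  Regions where either group has zero total coverage are
    flagged untestable and skipped (logged).  Output is sorted by
    (chrom, start) and carries :data:`DMR_COLUMNS`.
    """
    params = params or ClusterParams()
    wanted = set(group_a) | set(group_b)
    have = {t.sample_id for t in tables}
    if not wanted <= have:
        raise ValidationError(f"unknown sample ids {sorted(wanted - have)}")
    rcm = cluster_sites([t for t in tables if t.sample_id in wanted], params)
    ia = [rcm.sample_ids.index(s) for s in group_a]
    ib = [rcm.sample_ids.index(s) for s in group_b]
    if len(rcm) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS)

    testable = (rcm.total[:, ia].sum(axis=1) > 0) & (rcm.total[:, ib].sum(axis=1) > 0)
    if not testable.all():
        logger.info("call_dmrs: %d untestable region(s) skipped", (~testable).sum())
    regions = rcm.regions[testable].reset_index(drop=True)
    statdf = wald_test_counts(
        rcm.meth[testable][:, ia],
        rcm.total[testable][:, ia],
        rcm.meth[testable][:, ib],
        rcm.total[testable][:, ib],
        force_phi=force_phi,
        dispersion=dispersion,
    )
    out = pd.concat([regions, statdf], axis=1)
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out[DMR_COLUMNS]


def write_dmr_table(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as TSV with BED-compatible first three columns."""
    dmrs.to_csv(path, sep="\t", index=False)
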
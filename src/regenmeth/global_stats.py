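"""Genome-wide methylation fractions and their comparison across conditions.

The unit of analysis is the biological replicate: each sample contributes one
genome-wide percent-methylated value per sequence context (CpG, CHG, CHH,
plus a call-weighted total).  Conditions are then compared per context with a
classical fixed-effects one-way ANOVA followed, when requested, by Fisher's
least-significant-difference (LSD) pairwise t-tests on the pooled error term.
LSD applies no multiplicity adjustment beyond the protected-ANOVA protocol
(post-hocs are interpreted only when the omnibus ANOVA is significant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateVarianceError, ValidationError
from .meth_io import MethylCallTable

logger = logging.getLogger(__name__)

CONTEXT_ORDER = ["total", "CpG", "CHG", "CHH"]


def context_fractions(table: MethylCallTable) -> pd.DataFrame:
    """Percent of methylated calls per context for one sample.

    Returns a DataFrame with columns ``sample_id, condition, context,
    percent_methylated`` including a ``total`` row that is the call-weighted
    combination of the per-context rows.  Contexts with zero calls are
    omitted (with a log note).
    """
    df = table.df
    if df.empty or (df["meth"].sum() + df["unmeth"].sum()) == 0:
        raise ValidationError("context_fractions requires at least one call")
    rows = []
    tot_meth = tot_calls = 0
    for context in ("CpG", "CHG", "CHH"):
        sub = df[df["context"] == context]
        meth = int(sub["meth"].sum())
        calls = meth + int(sub["unmeth"].sum())
        if calls == 0:
            logger.info("sample %s: no %s calls; context omitted", table.sample_id, context)
            continue
        rows.append((table.sample_id, table.condition, context, 100.0 * meth / calls))
        tot_meth += meth
        tot_calls += calls
    rows.insert(0, (table.sample_id, table.condition, "total", 100.0 * tot_meth / tot_calls))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "context", "percent_methylated"]
    )


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA summary with optional LSD pairs."""

    F: float
    df_between: int
    df_within: int
    p: float
    mse: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)


def _as_groups(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]):
    if isinstance(groups, Mapping):
        names = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(data))]
    return names, data


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA over named replicate groups.

    ``groups`` is a mapping name -> replicate values (or a sequence of
    sequences).  Requires >= 2 groups with >= 2 replicates each and non-zero
    within-group variance.
    """
    names, data = _as_groups(groups)
    if len(data) < 2:
        raise ValidationError("ANOVA requires at least two groups")
    if any(len(g) < 2 for g in data):
        raise DegenerateVarianceError("every group needs >= 2 replicates")
    alldata = np.concatenate(data)
    grand = alldata.mean()
    n = len(alldata)
    k = len(data)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in data)
    df_b, df_w = k - 1, n - k
    if ssw <= 0:
        raise DegenerateVarianceError("zero within-group variance")
    mse = ssw / df_w
    F = (ssb / df_b) / mse
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        mse=float(mse),
        group_means={nm: float(g.mean()) for nm, g in zip(names, data)},
        group_sizes={nm: len(g) for nm, g in zip(names, data)},
    )


def fisher_lsd(groups, anova: AnovaResult) -> list[tuple[str, str, float, float]]:
    """Fisher LSD pairwise t-tests using the ANOVA pooled error term.

    For each pair t = (mean_a - mean_b) / sqrt(MSE * (1/n_a + 1/n_b)),
    two-sided p on the ANOVA's within-group degrees of freedom; by the LSD
    definition no further multiplicity adjustment is applied.
    """
    names, data = _as_groups(groups)
    if anova.mse <= 0:
        raise DegenerateVarianceError("zero pooled variance")
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = data[i], data[j]
            se = np.sqrt(anova.mse * (1 / len(a) + 1 / len(b)))
            t = float((a.mean() - b.mean()) / se)
            p = float(2 * stats.t.sf(abs(t), anova.df_within))
            out.append((names[i], names[j], t, p))
    anova.pairwise = out
    return out


def compare_conditions(
    fractions: pd.DataFrame, alpha: float = 0.05
) -> dict[str, AnovaResult]:
    """Per-context ANOVA + LSD over a stacked context-fractions table.

    ``fractions`` is the concatenation of :func:`context_fractions` rows over
    all samples.  Per the protected-LSD protocol, pairwise tests are attached
    only when the omnibus ANOVA reaches ``alpha``.
    """
    results: dict[str, AnovaResult] = {}
    for context, sub in fractions.groupby("context"):
        groups = {
            str(cond): grp["percent_methylated"].to_numpy()
            for cond, grp in sub.groupby("condition")
        }
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            logger.info("context %s: not enough replicate groups for ANOVA", context)
            continue
        try:
            res = one_way_anova(groups)
        except DegenerateVarianceError:
            logger.info("context %s: degenerate variance, ANOVA skipped", context)
            continue
        if res.p < alpha:
            fisher_lsd(groups, res)
        results[str(context)] = res
    return results
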
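"""Two-stage empirical FDR filtering of DMR p-values.

The null proportion pi0 is estimated from the flat tail of the p-value
distribution above a threshold lambda (default 0.3): under the null,
p-values are uniform, so #{p > lambda} / ((1 - lambda) * m) estimates the
fraction of tests that are true nulls.  q-values are then the Storey
step-down transform q_(j) = min_{k >= j} pi0 * m * p_(k) / k, and the final
DMR list is the subset with p below a first-stage cutoff (default 0.05)
whose q-value does not exceed the chosen FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FdrConfig:
    """lambda: tail threshold for pi0; p_max: first-stage p cutoff;
    q_max: FDR applied to the p < p_max subset."""

    lambda_: float = 0.3
    p_max: float = 0.05
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.lambda_ < 1:
            raise ValidationError("lambda must be in (0, 1)")
        if not 0 < self.p_max < self.lambda_:
            raise ValidationError("p_max must be in (0, lambda)")
        if not 0 < self.q_max <= 1:
            raise ValidationError("q_max must be in (0, 1]")


@dataclass
class FdrResult:
    pi0: float
    m: int
    qvalues: np.ndarray = field(repr=False)
    retained: pd.DataFrame = field(repr=False)
    config: FdrConfig = field(default_factory=FdrConfig)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def estimate_pi0(pvalues, lambda_: float = 0.3) -> float:
    """Tail estimator of the null proportion, clipped to [0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot estimate pi0 from zero p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    pi0 = np.count_nonzero(p > lambda_) / ((1.0 - lambda_) * p.size)
    return float(min(1.0, pi0))


def qvalues(pvalues, pi0: float = 1.0) -> np.ndarray:
    """Storey q-values at a given pi0, returned in the input order.

    Order statistics p_(j) receive q_(j) = min over k >= j of
    pi0 * m * p_(k) / k, so q is monotone non-decreasing in p and bounded by
    pi0.
    """
    if not 0 <= pi0 <= 1:
        raise ValidationError("pi0 must lie in [0, 1]")
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, pi0)
    return q


def filter_dmrs(dmrs: pd.DataFrame, config: FdrConfig | None = None) -> FdrResult:
    """Apply the two-stage empirical FDR filter to a DMR table.

    pi0 is estimated on ALL p-values; q-values are computed on all and
    written into a ``q`` column; the retained set is
    {p < p_max and q <= q_max}.
    """
    config = config or FdrConfig()
    if "p" not in dmrs.columns:
        raise ValidationError("DMR table lacks a 'p' column")
    p = dmrs["p"].to_numpy(dtype=float)
    pi0 = estimate_pi0(p, config.lambda_)
    q = qvalues(p, pi0)
    annotated = dmrs.copy()
    annotated["q"] = q
    retained = annotated[(annotated["p"] < config.p_max) & (annotated["q"] <= config.q_max)]
    retained = retained.reset_index(drop=True)
    logger.info(
        "empirical FDR: m=%d pi0=%.3f q_max=%.3g retained=%d",
        len(p), pi0, config.q_max, len(retained),
    )
    return FdrResult(pi0=pi0, m=len(p), qvalues=q, retained=retained, config=config)
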
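"""Non-parametric tolerance limits and Equivalent Score bands.

The Equivalent Scores (ES) method standardises adjusted test scores onto a
5-level ordinal scale anchored to distribution-free tolerance limits:

* the **outer tolerance limit** (oTL) is the adjusted score at the largest
  order-statistic rank r such that, with the stated confidence (default
  0.95), at least a fraction ``coverage_p`` (default 0.05) of the
  population falls below the r-th order statistic - i.e. a one-sided
  distribution-free bound on the population 5th centile;
* the **inner tolerance limit** (iTL) is the symmetric upper bound;
* ES 0 ("abnormal") is any adjusted score <= oTL, ES 4 ("normal") any
  score above the sample median, and ES 1-3 partition the scores in
  between.

Ranks come from exact binomial tail sums - no normal approximation - so
the minimum feasible sample size at p = 0.05, confidence 0.95 is n = 59.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ToleranceLimits",
    "EquivalentScoreBands",
    "InfeasibleSampleError",
    "DegenerateBandsError",
    "ES_LABELS",
    "minimum_n",
    "tl_ranks",
    "compute_tls",
    "es_bands",
    "assign_es",
    "sample_median",
    "norm_table",
    "norm_table_to_json",
]

ES_LABELS = {
    0: "abnormal",
    1: "borderline",
    2: "low-end normal",
    3: "normal",
    4: "normal",
}


class InfeasibleSampleError(ValueError):
    """Sample too small for a distribution-free tolerance limit."""


class DegenerateBandsError(ValueError):
    """Not enough distinct values between oTL and median to form bands."""


@dataclass(frozen=True)
class ToleranceLimits:
    n: int
    coverage_p: float
    confidence: float
    outer_rank: int  # 1-based rank into the ascending sorted sample
    inner_rank: int
    oTL: float
    iTL: float

    def __post_init__(self) -> None:
        if not 1 <= self.outer_rank <= self.inner_rank <= self.n:
            raise ValueError("ranks must satisfy 1 <= outer <= inner <= n")
        if self.oTL > self.iTL:
            raise ValueError("oTL must not exceed iTL")


@dataclass(frozen=True)
class EquivalentScoreBands:
    """Four ascending cut points; ES k is assigned by half-open intervals
    ES0: x <= t0, ES1: t0 < x <= t1, ..., ES4: x > t3 (t3 = sample
    median, t0 = oTL)."""

    thresholds: tuple[float, float, float, float]
    method: str = "rank"

    def __post_init__(self) -> None:
        t = self.thresholds
        if any(t[i] > t[i + 1] for i in range(3)):
            raise ValueError("thresholds must be non-decreasing")


def minimum_n(coverage_p: float = 0.05, confidence: float = 0.95) -> int:
    """Smallest n for which an outer tolerance rank exists:
    (1 - p)**n <= 1 - confidence."""
    return int(math.ceil(math.log(1.0 - confidence) / math.log(1.0 - coverage_p)))


def tl_ranks(
    n: int, coverage_p: float = 0.05, confidence: float = 0.95
) -> tuple[int, int]:
    """Order-statistic ranks of the outer and inner tolerance limits.

    outer_rank: largest r >= 1 with BinomCDF(r - 1; n, p) <= 1 - confidence
    inner_rank: smallest r with BinomCDF(r - 1; n, p) >= confidence

    computed from exact binomial tail probabilities.
    """
    if not 0 < coverage_p < 1 or not 0 < confidence < 1:
        raise ValueError("coverage_p and confidence must lie in (0, 1)")
    n_min = minimum_n(coverage_p, confidence)
    if n < n_min:
        raise InfeasibleSampleError(
            f"n = {n} below the minimum feasible size {n_min} for "
            f"p = {coverage_p}, confidence = {confidence}"
        )
    cdf = stats.binom.cdf(np.arange(0, n), n, coverage_p)  # CDF(r-1), r=1..n
    outer_candidates = np.nonzero(cdf <= 1.0 - confidence)[0]
    outer_rank = int(outer_candidates[-1]) + 1
    inner_candidates = np.nonzero(cdf >= confidence)[0]
    if len(inner_candidates) == 0:
        raise InfeasibleSampleError(
            f"no inner rank exists at n = {n}, p = {coverage_p}, "
            f"confidence = {confidence}"
        )
    inner_rank = int(inner_candidates[0]) + 1
    return outer_rank, inner_rank


def compute_tls(
    adjusted: Sequence[float],
    coverage_p: float = 0.05,
    confidence: float = 0.95,
) -> ToleranceLimits:
    """Tolerance limits of a sample of adjusted scores.

    The sample is sorted ascending and the limits are the values at the
    outer/inner ranks; ties are kept as they fall in the sorted multiset.
    """
    values = np.sort(np.asarray(adjusted, dtype=float))
    n = len(values)
    outer_rank, inner_rank = tl_ranks(n, coverage_p, confidence)
    return ToleranceLimits(
        n=n,
        coverage_p=coverage_p,
        confidence=confidence,
        outer_rank=outer_rank,
        inner_rank=inner_rank,
        oTL=float(values[outer_rank - 1]),
        iTL=float(values[inner_rank - 1]),
    )


def sample_median(values: np.ndarray) -> float:
    """Median as the lower of the two middle order statistics for even n,
    so that "above the median" has an exact sample meaning."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    return float(values[(n - 1) // 2])


def es_bands(
    adjusted: Sequence[float],
    tls: ToleranceLimits,
    method: str = "rank",
) -> EquivalentScoreBands:
    """Derive the 5-level ES cut points from a sample and its limits.

    ``method="rank"`` (default) places the inner cut points at the sample
    values whose ranks split the ranks strictly between the outer rank and
    the median rank into three near-equal bins (remainders to the lower
    bins).  ``method="z"`` spaces the cut points at equal standard-score
    intervals between the oTL and the median.
    """
    values = np.sort(np.asarray(adjusted, dtype=float))
    n = len(values)
    if n != tls.n:
        raise ValueError("tolerance limits were computed on a different sample")
    t0 = tls.oTL
    t3 = sample_median(values)
    median_rank = (n - 1) // 2 + 1  # 1-based

    if method == "rank":
        between = median_rank - tls.outer_rank - 1  # ranks strictly between
        if between < 3:
            raise DegenerateBandsError(
                f"only {max(between, 0)} ranks strictly between the outer "
                "rank and the median rank; cannot form three inner bands"
            )
        base, rem = divmod(between, 3)
        sizes = [base + (1 if i < rem else 0) for i in range(3)]
        r1 = tls.outer_rank + sizes[0]
        r2 = r1 + sizes[1]
        t1 = float(values[r1 - 1])
        t2 = float(values[r2 - 1])
    elif method == "z":
        mu = float(values.mean())
        sd = float(values.std(ddof=1))
        if sd == 0:
            raise DegenerateBandsError("zero variance sample")
        z0 = (t0 - mu) / sd
        z3 = (t3 - mu) / sd
        t1 = mu + (z0 + (z3 - z0) / 3.0) * sd
        t2 = mu + (z0 + 2.0 * (z3 - z0) / 3.0) * sd
    else:
        raise ValueError(f"unknown method {method!r}")

    thresholds = (t0, t1, t2, t3)
    if len(set(thresholds)) < 4:
        warnings.warn(
            "tied ES thresholds: an intermediate band is empty "
            f"(thresholds {thresholds})",
            stacklevel=2,
        )
    return EquivalentScoreBands(thresholds=thresholds, method=method)


def assign_es(adjusted_value: float, bands: EquivalentScoreBands) -> int:
    """ES level (0-4) of an adjusted score; boundary values resolve to the
    lower band (x <= oTL is 0, x <= median is at most 3)."""
    t0, t1, t2, t3 = bands.thresholds
    x = float(adjusted_value)
    if x <= t0:
        return 0
    if x <= t1:
        return 1
    if x <= t2:
        return 2
    if x <= t3:
        return 3
    return 4


def norm_table(
    index_name: str,
    tls: ToleranceLimits,
    bands: EquivalentScoreBands,
) -> dict:
    """NormTable payload: limits, band thresholds and method metadata."""
    return {
        "index_name": index_name,
        "n": tls.n,
        "coverage_p": tls.coverage_p,
        "confidence": tls.confidence,
        "outer_rank": tls.outer_rank,
        "inner_rank": tls.inner_rank,
        "oTL": tls.oTL,
        "iTL": tls.iTL,
        "thresholds": list(bands.thresholds),
        "method": {
            "partition": bands.method,
            "rank_rule": "exact binomial tail sums",
            "median": "lower middle order statistic",
        },
    }


def norm_table_to_json(table: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(table, indent=2))
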
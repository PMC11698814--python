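"""Descriptive statistics, Pearson associations and regression power.

Covers the statistical checks that accompany the norming pipeline:
moment-based normality screening of raw score distributions, Pearson
correlations between test scores and demographic/covariate measures with
pairwise-complete missing-data handling, and the a-priori sample-size
computation for a multiple-regression effect of size Cohen's f**2 via the
noncentral F distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalityFlags",
    "AssociationResult",
    "PowerSpec",
    "normality_flags",
    "pearson_matrix",
    "required_n_f2",
]


@dataclass(frozen=True)
class NormalityFlags:
    skewness: float
    kurtosis: float  # excess kurtosis (normal = 0)
    abnormal: bool


@dataclass(frozen=True)
class AssociationResult:
    x: str
    y: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclass(frozen=True)
class PowerSpec:
    u: int
    f2: float
    alpha: float
    power: float
    v: int
    n_required: int
    achieved_power: float
    lambda_convention: str = "total"


def normality_flags(
    values: Sequence[float],
    skew_threshold: float = 1.0,
    kurt_threshold: float = 3.0,
) -> NormalityFlags:
    """Moment-based normality screen.

    Sample skewness and excess kurtosis (conventional moment estimators);
    the distribution is flagged abnormal when |skewness| >= 1 or
    |excess kurtosis| >= 3.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input: moments undefined")
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return NormalityFlags(
        skewness=skew,
        kurtosis=kurt,
        abnormal=abs(skew) >= skew_threshold or abs(kurt) >= kurt_threshold,
    )


def pearson_matrix(
    cohort: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> list[AssociationResult]:
    """Pearson correlations for the requested column pairs.

    Missing covariates are handled pairwise-complete (e.g. MoCA, which is
    administered only to participants aged >= 50, automatically restricts
    its pairs to that subset).  Pairs with fewer than 3 complete cases are
    skipped with a warning.
    """
    results = []
    for x, y in pairs:
        xs = cohort[x].astype(float)
        ys = cohort[y].astype(float)
        mask = xs.notna() & ys.notna()
        n = int(mask.sum())
        if n < 3:
            warnings.warn(
                f"pair ({x}, {y}) has only {n} complete cases; skipped",
                stacklevel=2,
            )
            continue
        if x == y:
            r, p = 1.0, 0.0
        else:
            r, p = stats.pearsonr(xs[mask], ys[mask])
        results.append(
            AssociationResult(x=x, y=y, r=float(r), p=float(p), n=n)
        )
    return results


def _f_power(u: int, v: float, lam: float, alpha: float) -> float:
    crit = stats.f.isf(alpha, u, v)
    return float(stats.ncf.sf(crit, u, v, lam))


def required_n_f2(
    u: int,
    f2: float,
    alpha: float = 0.05,
    power: float = 0.90,
    lambda_convention: str = "total",
) -> PowerSpec:
    """Minimum total sample size for a multiple-regression F test.

    Finds the smallest denominator df v such that the level-``alpha`` F
    test with df (u, v) and noncentrality lambda attains the target power,
    and returns N = u + v + 1.  ``lambda_convention`` selects the
    noncentrality parameterisation:

    * ``"total"`` (default): lambda = f2 * (u + v + 1) = f2 * N, the
      convention of the pwr/G*Power tool family;
    * ``"error"``: lambda = f2 * v.
    """
    if f2 <= 0:
        raise ValueError("f2 must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if u < 1:
        raise ValueError("u must be >= 1")
    if lambda_convention not in ("total", "error"):
        raise ValueError(f"unknown lambda_convention {lambda_convention!r}")

    def lam(v: int) -> float:
        return f2 * (u + v + 1) if lambda_convention == "total" else f2 * v

    def achieved(v: int) -> float:
        return _f_power(u, v, lam(v), alpha)

    # power is monotone increasing in v (lambda grows with v while the
    # critical value shrinks): bracket by doubling, then bisect for the
    # smallest v meeting the target
    hi = 2
    while achieved(hi) < power:
        hi *= 2
        if hi > 10**6:
            raise RuntimeError("power target not reached by v = 1e6")
    lo = max(2, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    v = hi
    return PowerSpec(
        u=u, f2=f2, alpha=alpha, power=power, v=v,
        n_required=u + v + 1, achieved_power=achieved(v),
        lambda_convention=lambda_convention,
    )
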
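"""Non-parametric tolerance limits and Equivalent Score banding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from earnorms import assign_es, compute_tls, es_bands, tl_ranks
from earnorms.limits import (
    DegenerateBandsError,
    EquivalentScoreBands,
    InfeasibleSampleError,
    ToleranceLimits,
    minimum_n,
    norm_table,
    sample_median,
)


def oracle_ranks(n, p=0.05, conf=0.95):
    """Brute-force rank rule from explicit binomial probability sums."""
    log_pmf = (
        gammaln(n + 1)
        - gammaln(np.arange(n + 1) + 1)
        - gammaln(n - np.arange(n + 1) + 1)
        + np.arange(n + 1) * math.log(p)
        + (n - np.arange(n + 1)) * math.log(1 - p)
    )
    cdf = np.cumsum(np.exp(log_pmf))
    outer = max(r for r in range(1, n + 1) if cdf[r - 1] <= 1 - conf)
    inner = min(r for r in range(1, n + 1) if cdf[r - 1] >= conf)
    return outer, inner


@pytest.mark.parametrize("n", [59, 60, 100, 286, 522, 777, 1000])
def test_tl_ranks_match_brute_force(n):
    assert tl_ranks(n) == oracle_ranks(n)


def test_minimum_feasible_size():
    assert minimum_n(0.05, 0.95) == 59
    assert tl_ranks(59)[0] == 1  # 0.95**59 = 0.0485 <= 0.05
    with pytest.raises(InfeasibleSampleError, match="59"):
        tl_ranks(58)


def test_median_symmetry_case():
    """At p = 0.5, confidence 0.5, odd n the two ranks bracket the median
    rank."""
    n = 101
    outer, inner = tl_ranks(n, coverage_p=0.5, confidence=0.5)
    median_rank = (n + 1) // 2
    assert outer <= median_rank <= inner
    assert inner - outer <= 2


def test_compute_tls_on_known_sample():
    values = np.arange(1, 101, dtype=float)  # 1..100
    tls = compute_tls(values)
    outer, inner = oracle_ranks(100)
    assert tls.oTL == values[outer - 1]
    assert tls.iTL == values[inner - 1]
    assert tls.outer_rank == outer and tls.inner_rank == inner


def test_degenerate_distribution():
    values = np.full(200, 47.25)
    tls = compute_tls(values)
    assert tls.oTL == tls.iTL == 47.25


def test_es_bands_equal_rank_partition():
    """On 1..522 the three inner bands hold near-equal counts, level 0
    holds exactly the outer rank and level 4 exactly half the sample."""
    values = np.arange(1, 523, dtype=float)
    tls = compute_tls(values)
    bands = es_bands(values, tls)
    levels = np.array([assign_es(v, bands) for v in values])
    counts = np.bincount(levels, minlength=5)
    assert counts[0] == tls.outer_rank
    assert counts[4] == len(values) - (len(values) - 1) // 2 - 1  # n/2 here
    assert counts[4] == 261
    inner = counts[1:4]
    assert inner.max() - inner.min() <= 1
    assert counts.sum() == len(values)


def test_es_band_boundaries():
    bands = EquivalentScoreBands(thresholds=(10.0, 20.0, 30.0, 40.0))
    eps = 1e-9
    assert assign_es(10.0, bands) == 0
    assert assign_es(10.0 + eps, bands) == 1
    assert assign_es(40.0, bands) == 3
    assert assign_es(40.0 + eps, bands) == 4
    assert assign_es(-1e9, bands) == 0
    assert assign_es(1e9, bands) == 4


def test_published_band_assignments():
    """Threshold checks against the published ES tables for both indices."""
    er = EquivalentScoreBands(thresholds=(42.35, 46.09, 48.87, 51.45))
    ea = EquivalentScoreBands(thresholds=(41.25, 45.09, 47.77, 50.62))
    assert assign_es(42.35, er) == 0
    assert assign_es(51.46, er) == 4
    assert assign_es(41.25, ea) == 0
    assert assign_es(47.0, ea) == 2


def test_assign_es_monotone(rng):
    bands_values = np.sort(rng.normal(50, 5, 600))
    tls = compute_tls(bands_values)
    bands = es_bands(bands_values, tls)
    xs = np.sort(rng.uniform(30, 70, 500))
    levels = [assign_es(x, bands) for x in xs]
    assert all(a <= b for a, b in zip(levels, levels[1:]))


@settings(derandomize=True, max_examples=200)
@given(
    x=st.floats(allow_nan=False, allow_infinity=False, width=32),
    y=st.floats(allow_nan=False, allow_infinity=False, width=32),
)
def test_assign_es_order_preserving(x, y):
    """assign_es is a total, order-preserving map from the reals onto
    {0..4}."""
    bands = EquivalentScoreBands(thresholds=(42.35, 46.09, 48.87, 51.45))
    ex, ey = assign_es(x, bands), assign_es(y, bands)
    assert 0 <= ex <= 4
    if x <= y:
        assert ex <= ey


def test_z_partition_method(rng):
    values = np.sort(rng.normal(50, 5, 522))
    tls = compute_tls(values)
    bands = es_bands(values, tls, method="z")
    t = bands.thresholds
    assert t[0] < t[1] < t[2] < t[3]
    assert t[0] == tls.oTL
    assert t[3] == sample_median(values)


def test_degenerate_bands_error():
    values = np.arange(1, 101, dtype=float)
    tls = ToleranceLimits(
        n=100, coverage_p=0.05, confidence=0.95,
        outer_rank=48, inner_rank=60, oTL=48.0, iTL=60.0,
    )
    with pytest.raises(DegenerateBandsError, match="three inner bands"):
        es_bands(values, tls)


def test_tied_thresholds_warn():
    values = np.r_[np.full(300, 1.0), np.full(300, 2.0)]
    tls = compute_tls(values)
    with pytest.warns(UserWarning, match="tied ES thresholds"):
        bands = es_bands(values, tls)
    assert bands.thresholds[0] == 1.0


def test_lower_median_convention():
    assert sample_median(np.array([1.0, 2.0, 3.0, 4.0])) == 2.0
    assert sample_median(np.array([1.0, 2.0, 3.0])) == 2.0


def test_outer_rank_fraction_converges():
    """outer_rank / n approaches the coverage fraction as n grows.

    The one-sided rank rule places outer_rank about 1.645 binomial SEs
    below n * p (that offset is what buys the 95% confidence), so the
    deviation is bounded by 2 SEs and shrinks like 1/sqrt(n).
    """
    devs = []
    for n in (1000, 10_000, 100_000):
        outer, _ = tl_ranks(n)
        se = math.sqrt(0.05 * 0.95 / n)
        dev = abs(outer / n - 0.05)
        assert dev <= 2.0 * se + 1 / n
        devs.append(dev)
    assert devs[0] > devs[1] > devs[2]


def test_norm_table_payload():
    values = np.arange(1, 523, dtype=float)
    tls = compute_tls(values)
    bands = es_bands(values, tls)
    table = norm_table("ER", tls, bands)
    assert table["n"] == 522
    assert table["outer_rank"] == tls.outer_rank
    assert table["thresholds"][0] == tls.oTL
    assert table["method"]["partition"] == "rank"
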
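"""Contingency-table and rank tests, implemented from first principles.

The battery covers the tests used to evaluate trough-attainment cohorts:

* Pearson chi-square test of independence on an r×c table, with the
  optional Yates continuity correction for 2×2 tables;
* Fisher's exact test for 2×2 tables (two-sided, by summation of
  hypergeometric probabilities no larger than the observed table's);
* Mann-Whitney U (exact by rank-split enumeration for small samples,
  normal approximation with tie and continuity correction otherwise);
* Kruskal-Wallis one-way analysis of variance on ranks;
* the classical two-proportion sample-size formula (pooled variance under
  the null, unpooled under the alternative).

Only distribution primitives (chi-square and normal tails, the
hypergeometric pmf) and midranking come from scipy; every statistic and
p-value is computed here. All p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom, norm, rankdata

__all__ = [
    "ContingencyTable",
    "TestResult",
    "PowerSpec",
    "pearson_chi_square",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "kruskal_wallis",
    "two_proportion_sample_size",
]

# relative slack when comparing hypergeometric pmfs: tables whose
# probability ties the observed one up to float noise are included
_PMF_RTOL = 1e-7


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero; the test is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """An r×c table of non-negative integer counts with optional labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    @classmethod
    def from_array(cls, counts, row_labels=None, col_labels=None) -> "ContingencyTable":
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"need an r×c table with r,c ≥ 2, got shape {arr.shape}")
        if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be non-negative integers")
        return cls(
            counts=tuple(tuple(int(v) for v in row) for row in arr),
            row_labels=tuple(row_labels) if row_labels is not None else None,
            col_labels=tuple(col_labels) if col_labels is not None else None,
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.counts), len(self.counts[0]))


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom (None for exact tests) and p-value."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a two-proportion comparison."""

    p1: float
    p2: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "alpha", "power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.p1 == self.p2:
            raise ValueError("p1 = p2: required sample size diverges")


def _as_table(t) -> ContingencyTable:
    return t if isinstance(t, ContingencyTable) else ContingencyTable.from_array(t)


def pearson_chi_square(table, continuity: bool = False) -> TestResult:
    """Pearson chi-square test of independence.

    The statistic is Σ (O − E)² / E with expected counts E from the table
    margins; the p-value is the upper chi-square tail on (r−1)(c−1)
    degrees of freedom. With ``continuity=True`` (2×2 tables only) each
    |O − E| is reduced by 0.5 before squaring — the Yates correction —
    but never below zero.
    """
    t = _as_table(table)
    obs = t.to_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError("zero row or column margin")
    if continuity and t.shape != (2, 2):
        raise ValueError("continuity correction applies only to 2×2 tables")
    expected = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(chi2_dist.sf(stat, df))
    return TestResult(
        statistic=stat,
        p_value=p,
        method="pearson_chi_square",
        df=df,
        continuity_corrected=continuity,
    )


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test on a 2×2 table (two-sided).

    With both margins fixed, the top-left cell ``a`` follows a
    hypergeometric law. The two-sided p-value sums the probabilities of
    every table at least as extreme as — i.e. no more probable than — the
    observed one. The reported statistic is the sample odds ratio
    (ad)/(bc), infinite when bc = 0.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"Fisher's exact test needs a 2×2 table, got {t.shape}")
    (a, b), (c, d) = t.counts
    n1, n2 = a + b, c + d
    m1 = a + c
    n = n1 + n2
    if 0 in (n1, n2, m1, b + d):
        raise DegenerateTableError("zero row or column margin")
    rv = hypergeom(n, m1, n1)  # a ~ Hypergeom(N=n, K=m1, n=n1)
    support = np.arange(max(0, n1 - (n - m1)), min(n1, m1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + _PMF_RTOL)].sum())
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return TestResult(
        statistic=odds, p_value=min(p, 1.0), method="fisher_exact", df=None
    )


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> TestResult:
    """Mann-Whitney U test (two-sided) for two independent samples.

    U is computed from midranks of the pooled sample. ``method`` is
    ``"exact"`` (enumerate every rank split — feasible only for small
    samples), ``"normal"`` (large-sample approximation with tie correction
    and a 0.5 continuity correction), or ``"auto"`` (exact when
    n1 + n2 ≤ 10, normal otherwise).

    The exact two-sided p-value is the permutation probability of a U at
    least as far from its null mean n1·n2/2 as the observed U, which
    remains valid in the presence of ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = _u_from_ranks(float(ranks[:n1].sum()), n1)
    mu = n1 * n2 / 2.0

    if method == "auto":
        method = "exact" if n1 + n2 <= 10 else "normal"

    if method == "exact":
        dev_obs = abs(u1 - mu)
        total = 0
        hits = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_from_ranks(float(ranks[list(idx)].sum()), n1)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
        return TestResult(statistic=u1, p_value=p, method="mann_whitney_u_exact")

    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all observations tied
        return TestResult(statistic=u1, p_value=1.0, method="mann_whitney_u_normal")
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return TestResult(statistic=u1, p_value=p, method="mann_whitney_u_normal")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test across k ≥ 2 independent groups.

    H = 12 / (N(N+1)) · Σ nᵢ (r̄ᵢ − r̄)², computed on midranks and divided
    by the tie-correction factor 1 − Σ(t³ − t)/(N³ − N); the p-value is
    the chi-square upper tail on k − 1 degrees of freedom. When every
    observation is tied the correction factor vanishes and H is defined
    as 0 (p = 1): there is no rank variation to explain.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")
    sizes = np.array([s.size for s in samples])
    n = int(sizes.sum())
    pooled = np.concatenate(samples)
    ranks = rankdata(pooled)
    grand = (n + 1) / 2.0
    h = 0.0
    start = 0
    for size in sizes:
        mean_rank = float(ranks[start : start + size].mean())
        h += size * (mean_rank - grand) ** 2
        start += size
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    df = len(samples) - 1
    if correction <= 0:  # all values identical
        return TestResult(statistic=0.0, p_value=1.0, method="kruskal_wallis", df=df)
    h /= correction
    p = float(chi2_dist.sf(h, df))
    return TestResult(statistic=h, p_value=p, method="kruskal_wallis", df=df)


def two_proportion_sample_size(spec: PowerSpec) -> int:
    """Per-group n for a two-sided two-proportion comparison.

    n = (z₁₋α/₂ √(2 p̄ q̄) + z₁₋β √(p₁q₁ + p₂q₂))² / (p₁ − p₂)²

    with p̄ the average of the two proportions (pooled variance under the
    null, unpooled under the alternative), rounded to the nearest integer.
    """
    p1, p2 = spec.p1, spec.p2
    pbar = (p1 + p2) / 2.0
    z_alpha = float(norm.ppf(1.0 - spec.alpha / 2.0))
    z_beta = float(norm.ppf(spec.power))
    num = (
        z_alpha * math.sqrt(2.0 * pbar * (1.0 - pbar))
        + z_beta * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))
    ) ** 2
    n = num / (p1 - p2) ** 2
    return int(round(n))
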
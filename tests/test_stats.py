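"""First-principles statistical battery, checked against independent oracles.

Each test family has two routes: the package's implementation versus
either a brute-force enumeration written here or the corresponding scipy
routine (which the implementation itself never calls).
"""

import math
from itertools import combinations

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as hst

from vancotdm.stats import (
    ContingencyTable,
    DegenerateTableError,
    PowerSpec,
    fisher_exact_2x2,
    kruskal_wallis,
    mann_whitney_u,
    pearson_chi_square,
    two_proportion_sample_size,
)

# ---------------------------------------------------------------- chi-square


def _chi2_oracle(table):
    """Textbook Σ(O−E)²/E computed with explicit loops."""
    table = np.asarray(table, dtype=float)
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestPearsonChiSquare:
    def test_subgroup_table(self):
        # therapeutic vs not for three cohorts, 60–80 kg stratum
        table = [[6, 13], [7, 7], [36, 14]]
        res = pearson_chi_square(table)
        assert res.statistic == pytest.approx(_chi2_oracle(table), rel=1e-12)
        assert res.df == 2
        assert res.statistic == pytest.approx(9.87, abs=0.005)
        assert res.p_value == pytest.approx(0.0072, abs=5e-4)

    def test_proportional_rows_give_zero(self):
        res = pearson_chi_square([[10, 20], [20, 40], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_supratherapeutic_comparison(self):
        res = pearson_chi_square([[13, 62], [19, 89]])
        assert round(res.p_value, 2) == 0.96

    def test_continuity_corrected_2x2(self):
        res = pearson_chi_square([[24, 51], [14, 94]], continuity=True)
        assert res.continuity_corrected
        assert round(res.p_value, 3) == 0.003

    def test_continuity_rejected_beyond_2x2(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[1, 2], [3, 4], [5, 6]], continuity=True)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square([[0, 0], [3, 4]])

    @given(
        data=hst.lists(
            hst.lists(hst.integers(1, 50), min_size=2, max_size=4),
            min_size=2, max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_matches_scipy_and_permutation_invariant(self, data):
        res = pearson_chi_square(data)
        stat, p, df, _ = sps.chi2_contingency(np.asarray(data), correction=False)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)
        assert res.df == df
        shuffled = pearson_chi_square(list(reversed(data)))
        assert shuffled.statistic == pytest.approx(res.statistic, rel=1e-10)

    @given(
        a=hst.integers(1, 30), b=hst.integers(1, 30),
        c=hst.integers(1, 30), d=hst.integers(1, 30),
    )
    def test_corrected_2x2_matches_scipy(self, a, b, c, d):
        res = pearson_chi_square([[a, b], [c, d]], continuity=True)
        stat, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=True)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)


# ------------------------------------------------------------- Fisher exact


def _fisher_oracle(a, b, c, d):
    """Brute force: enumerate every table with the observed margins."""
    n1, m1, n = a + b, a + c, a + b + c + d

    def prob(k):
        # hypergeometric pmf via binomial coefficients
        return (
            math.comb(m1, k) * math.comb(n - m1, n1 - k) / math.comb(n, n1)
        )

    p_obs = prob(a)
    lo, hi = max(0, n1 - (n - m1)), min(n1, m1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[1, 0], [0, 1]], 1.0),       # both tables equally likely
            ([[2, 0], [0, 2]], 1 / 3),     # pmf 1/6, 4/6, 1/6
            ([[5, 5], [5, 5]], 1.0),       # observed table is the mode
        ],
    )
    def test_enumerable_examples(self, table, expected):
        assert fisher_exact_2x2(table).p_value == pytest.approx(expected, rel=1e-12)

    @given(
        a=hst.integers(0, 12), b=hst.integers(0, 12),
        c=hst.integers(0, 12), d=hst.integers(0, 12),
    )
    def test_equals_brute_force_enumeration(self, a, b, c, d):
        """Exact p equals full table enumeration for every 2×2 with N ≤ 48."""
        if 0 in (a + b, c + d, a + c, b + d):
            with pytest.raises(DegenerateTableError):
                fisher_exact_2x2([[a, b], [c, d]])
            return
        got = fisher_exact_2x2([[a, b], [c, d]]).p_value
        assert got == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-9)

    @given(
        a=hst.integers(1, 20), b=hst.integers(1, 20),
        c=hst.integers(1, 20), d=hst.integers(1, 20),
    )
    def test_matches_scipy(self, a, b, c, d):
        got = fisher_exact_2x2([[a, b], [c, d]]).p_value
        _, p = sps.fisher_exact([[a, b], [c, d]])
        assert got == pytest.approx(p, rel=1e-9)


# ------------------------------------------------------------ Mann-Whitney


def _mwu_exact_oracle(x, y):
    """Permutation distribution of U over every rank split."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        hits += abs(u - mu) >= dev - 1e-12
    return hits / total


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n1·n2/2
        assert res.p_value == 1.0

    def test_disjoint_pairs(self):
        assert mann_whitney_u([1, 2], [3, 4]).p_value == pytest.approx(1 / 3)

    def test_disjoint_triples(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(
        x=hst.lists(hst.integers(0, 8), min_size=2, max_size=5),
        y=hst.lists(hst.integers(0, 8), min_size=2, max_size=5),
    )
    def test_exact_equals_rank_split_enumeration(self, x, y):
        """With ties allowed, exact p equals the permutation oracle."""
        got = mann_whitney_u(x, y, method="exact").p_value
        assert got == pytest.approx(
            _mwu_exact_oracle(np.asarray(x, float), np.asarray(y, float)), rel=1e-12
        )

    @settings(max_examples=25)
    @given(
        x=hst.lists(hst.floats(0, 50, allow_nan=False), min_size=12, max_size=30),
        y=hst.lists(hst.floats(0, 50, allow_nan=False), min_size=12, max_size=30),
    )
    def test_normal_approximation_matches_scipy(self, x, y):
        got = mann_whitney_u(x, y, method="normal")
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        if got.p_value < 1.0:  # scipy clips differently at exactly 1
            assert got.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------- Kruskal-Wallis


class TestKruskalWallis:
    def test_all_tied_defined_as_zero(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5], [5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_brute_force_rank_formula(self):
        # groups {1,2},{3,4},{5,6}: H = 12/(6·7)·(2·4 + 0 + 2·4) = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7, rel=1e-12)
        assert res.df == 2

    def test_two_groups_equal_mwu_z_squared(self):
        """Without ties, H equals the squared MWU normal deviate."""
        x, y = [3.1, 9.4, 1.2, 7.7], [4.4, 12.0, 8.1, 2.2, 6.3]
        h = kruskal_wallis([x, y]).statistic
        n1, n2 = len(x), len(y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        z = (u - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-10)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    @given(
        groups=hst.lists(
            hst.lists(hst.integers(0, 20), min_size=2, max_size=8),
            min_size=2, max_size=4,
        )
    )
    def test_matches_scipy_with_ties(self, groups):
        res = kruskal_wallis(groups)
        flat = [v for g in groups for v in g]
        if len(set(flat)) == 1:
            assert res.p_value == 1.0
            return
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


# ------------------------------------------------------------- sample size


def _sample_size_oracle(p1, p2, alpha, power):
    za, zb = sps.norm.ppf(1 - alpha / 2), sps.norm.ppf(power)
    pbar = (p1 + p2) / 2
    n = (
        za * math.sqrt(2 * pbar * (1 - pbar))
        + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))
    ) ** 2 / (p1 - p2) ** 2
    return n


class TestTwoProportionSampleSize:
    def test_study_design_parameters(self):
        """34% → 14% subtherapeutic at 80% power needs 70 per group."""
        assert two_proportion_sample_size(PowerSpec(0.34, 0.14)) == 70

    def test_direct_formula_evaluation(self):
        # 0.50 vs 0.10: formula evaluates to 19.38, nearest integer 19
        assert _sample_size_oracle(0.5, 0.1, 0.05, 0.8) == pytest.approx(19.38, abs=0.005)
        assert two_proportion_sample_size(PowerSpec(0.5, 0.1)) == 19

    def test_more_power_needs_more_patients(self):
        sizes = [
            two_proportion_sample_size(PowerSpec(0.34, 0.14, power=p))
            for p in (0.5, 0.7, 0.8, 0.9, 0.99)
        ]
        assert sizes == sorted(sizes) and len(set(sizes)) == len(sizes)

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(0.3, 0.3)

    @given(
        p1=hst.floats(0.05, 0.95), delta=hst.floats(0.05, 0.4),
        power=hst.floats(0.5, 0.99),
    )
    def test_matches_oracle_everywhere(self, p1, delta, power):
        p2 = p1 - delta
        if not 0.0 < p2 < 1.0:
            return
        got = two_proportion_sample_size(PowerSpec(p1, p2, power=power))
        assert got == int(round(_sample_size_oracle(p1, p2, 0.05, power)))


def test_all_pvalues_in_unit_interval(rng):
    """Spot check across the battery on random inputs."""
    for _ in range(25):
        t = rng.integers(1, 30, size=(2, 2))
        assert 0 <= pearson_chi_square(t).p_value <= 1
        assert 0 <= fisher_exact_2x2(t).p_value <= 1
        x, y = rng.normal(size=8), rng.normal(size=12)
        assert 0 <= mann_whitney_u(x, y).p_value <= 1
        assert 0 <= kruskal_wallis([x, y, rng.normal(size=5)]).p_value <= 1


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable.from_array([[1, 2]])
    with pytest.raises(ValueError):
        ContingencyTable.from_array([[1, -2], [3, 4]])
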
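"""Trough classification, cohort summaries, and between-group comparisons.

The protocol's therapeutic window is 10–20 mcg/ml for the first
steady-state trough: below 10 is subtherapeutic (the primary outcome the
nomogram exists to reduce), above 20 supratherapeutic. This module
classifies troughs, summarises a cohort (counts, proportions, median and
interquartile range), and builds the category-by-group contingency tables
that the stats module tests — including subgroup analyses at the extremes
of weight and renal function.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import stats as st
from .nomogram import WeightStratum, weight_stratum
from .renal import RenalModality, RenalStratum, renal_stratum

__all__ = [
    "THERAPEUTIC_LOW",
    "THERAPEUTIC_HIGH",
    "TroughCategory",
    "TroughObservation",
    "CohortSummary",
    "CategoryComparison",
    "ComparisonReport",
    "ComparisonConfig",
    "classify_trough",
    "summarize_cohort",
    "compare_cohorts",
    "subgroup_analysis",
]

THERAPEUTIC_LOW = 10.0   # mcg/ml, exclusive lower edge of the goal range
THERAPEUTIC_HIGH = 20.0  # mcg/ml, inclusive upper edge


class TroughCategory(str, enum.Enum):
    SUBTHERAPEUTIC = "subtherapeutic"      # < 10 mcg/ml
    THERAPEUTIC = "therapeutic"            # 10 – 20 mcg/ml
    SUPRATHERAPEUTIC = "supratherapeutic"  # > 20 mcg/ml


@dataclass(frozen=True)
class TroughObservation:
    """A measured steady-state trough with its cohort label.

    ``weight_kg`` and ``egfr`` are optional and only needed for subgroup
    analyses; ``modality`` matters only for eGFR subgrouping (any
    renal-replacement modality lands in the <15-or-RRT stratum).
    """

    concentration: float
    group: str
    weight_kg: float | None = None
    egfr: float | None = None
    modality: RenalModality = RenalModality.NONE

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be ≥ 0, got {self.concentration}")


def classify_trough(concentration: float) -> TroughCategory:
    """Classify a trough against the 10–20 mcg/ml goal range.

    Strictly below 10 → subtherapeutic; 10 through 20 inclusive →
    therapeutic; strictly above 20 → supratherapeutic. The three
    categories partition [0, ∞).
    """
    if concentration < 0:
        raise ValueError(f"concentration must be ≥ 0, got {concentration}")
    if concentration < THERAPEUTIC_LOW:
        return TroughCategory.SUBTHERAPEUTIC
    if concentration <= THERAPEUTIC_HIGH:
        return TroughCategory.THERAPEUTIC
    return TroughCategory.SUPRATHERAPEUTIC


@dataclass(frozen=True)
class CohortSummary:
    n: int
    counts: dict[TroughCategory, int]
    proportions: dict[TroughCategory, float]
    median: float
    iqr: tuple[float, float]


def summarize_cohort(
    observations: Sequence[TroughObservation | float],
) -> CohortSummary:
    """Category counts/proportions plus median and IQR of a trough cohort.

    The median uses the midrank convention and the IQR the 25th/75th
    percentiles with linear interpolation between order statistics.
    """
    values = np.array(
        [
            o.concentration if isinstance(o, TroughObservation) else float(o)
            for o in observations
        ]
    )
    if values.size == 0:
        raise ValueError("cannot summarise an empty cohort")
    counts = {c: 0 for c in TroughCategory}
    for v in values:
        counts[classify_trough(float(v))] += 1
    n = int(values.size)
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return CohortSummary(
        n=n,
        counts=counts,
        proportions={c: counts[c] / n for c in TroughCategory},
        median=float(q50),
        iqr=(float(q25), float(q75)),
    )


@dataclass(frozen=True)
class ComparisonConfig:
    """Which test to run per trough category.

    Values are test names: ``"chi2_corrected"`` (continuity-corrected
    Pearson, 2 groups only), ``"chi2"`` (uncorrected Pearson) or
    ``"fisher"`` (2 groups only). The default mirrors the evaluation this
    package reproduces: the primary (subtherapeutic) comparison uses the
    continuity-corrected chi-square, the secondary comparisons the
    uncorrected Pearson test.
    """

    tests: Mapping[TroughCategory, str] = field(
        default_factory=lambda: {
            TroughCategory.SUBTHERAPEUTIC: "chi2_corrected",
            TroughCategory.THERAPEUTIC: "chi2",
            TroughCategory.SUPRATHERAPEUTIC: "chi2",
        }
    )


@dataclass(frozen=True)
class CategoryComparison:
    category: TroughCategory
    table: st.ContingencyTable  # group × (in-category, not-in-category)
    test: str
    result: st.TestResult


@dataclass(frozen=True)
class ComparisonReport:
    groups: tuple[str, ...]
    summaries: dict[str, CohortSummary]
    comparisons: dict[TroughCategory, CategoryComparison]

    def distribution(self) -> dict[str, dict[TroughCategory, float]]:
        """Per-group category proportions (the stacked-bar view)."""
        return {g: dict(s.proportions) for g, s in self.summaries.items()}


def _run_test(table: st.ContingencyTable, name: str) -> st.TestResult:
    if name == "chi2":
        return st.pearson_chi_square(table, continuity=False)
    if name == "chi2_corrected":
        return st.pearson_chi_square(table, continuity=True)
    if name == "fisher":
        return st.fisher_exact_2x2(table)
    raise ValueError(f"unknown test {name!r}")


def _category_table(
    groups: Mapping[str, Sequence[TroughObservation]], category: TroughCategory
) -> st.ContingencyTable:
    rows = []
    for g, obs in groups.items():
        in_cat = sum(1 for o in obs if classify_trough(o.concentration) is category)
        rows.append((in_cat, len(obs) - in_cat))
    return st.ContingencyTable.from_array(
        rows, row_labels=list(groups), col_labels=[category.value, "other"]
    )


def compare_cohorts(
    groups: Mapping[str, Sequence[TroughObservation]],
    config: ComparisonConfig | None = None,
) -> ComparisonReport:
    """Compare trough-category attainment across two or more cohorts.

    For each category a group × (in-category / not) table is built and the
    configured test applied. Continuity-corrected chi-square and Fisher
    requests fall back to the uncorrected Pearson test when more than two
    groups are compared, since both are defined for 2×2 tables only.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    config = config or ComparisonConfig()
    summaries = {g: summarize_cohort(obs) for g, obs in groups.items()}
    comparisons = {}
    for category in TroughCategory:
        table = _category_table(groups, category)
        test = config.tests.get(category, "chi2")
        if len(groups) > 2 and test in ("chi2_corrected", "fisher"):
            test = "chi2"
        comparisons[category] = CategoryComparison(
            category=category, table=table, test=test, result=_run_test(table, test)
        )
    return ComparisonReport(
        groups=tuple(groups), summaries=summaries, comparisons=comparisons
    )


def _stratify(obs: TroughObservation, by: str) -> str | None:
    if by == "weight":
        if obs.weight_kg is None:
            return None
        return weight_stratum(obs.weight_kg).value
    if by == "egfr":
        if obs.egfr is None and obs.modality is RenalModality.NONE:
            return None
        return renal_stratum(obs.egfr if obs.egfr is not None else 1.0, obs.modality).value
    raise ValueError(f"unknown stratifier {by!r} (expected 'weight' or 'egfr')")


_STRATUM_ORDER = {
    "weight": [s.value for s in WeightStratum],
    "egfr": [s.value for s in RenalStratum],
}


@dataclass(frozen=True)
class SubgroupResult:
    stratum: str
    # per group: (therapeutic count, total)
    attainment: dict[str, tuple[int, int]]
    table: st.ContingencyTable
    result: st.TestResult


def subgroup_analysis(
    groups: Mapping[str, Sequence[TroughObservation]], by: str = "weight"
) -> dict[str, SubgroupResult]:
    """Therapeutic-range attainment by weight or renal stratum.

    Within each stratum the group × (therapeutic / non-therapeutic) table
    is tested with the uncorrected Pearson chi-square, df = groups − 1.
    Strata in which some group has no observations are skipped with a
    warning rather than producing a degenerate table.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    results: dict[str, SubgroupResult] = {}
    for stratum in _STRATUM_ORDER[by]:
        attainment: dict[str, tuple[int, int]] = {}
        for g, obs in groups.items():
            members = [o for o in obs if _stratify(o, by) == stratum]
            thera = sum(
                1
                for o in members
                if classify_trough(o.concentration) is TroughCategory.THERAPEUTIC
            )
            attainment[g] = (thera, len(members))
        if any(total == 0 for _, total in attainment.values()):
            warnings.warn(
                f"stratum {stratum!r} skipped: some group has no observations",
                stacklevel=2,
            )
            continue
        rows = [(t, n - t) for t, n in attainment.values()]
        table = st.ContingencyTable.from_array(
            rows, row_labels=list(groups), col_labels=["therapeutic", "other"]
        )
        try:
            res = st.pearson_chi_square(table, continuity=False)
        except st.DegenerateTableError:
            warnings.warn(f"stratum {stratum!r} skipped: degenerate table", stacklevel=2)
            continue
        results[stratum] = SubgroupResult(
            stratum=stratum, attainment=attainment, table=table, result=res
        )
    return results
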
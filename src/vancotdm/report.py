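"""Regenerate the reference study's comparisons from packaged aggregates.

Patient-level troughs from the published cohorts are unavailable, but
every reported comparison is a function of category counts, so the whole
report can be rebuilt from the packaged integers: cohort trough-category
distributions, pairwise control-versus-intervention tests per category,
and the subgroup chi-square tests at the extremes of weight and renal
function.

Counts are expanded into representative observations (one concentration
per category, placed safely inside its range) and pushed through the same
``compare_cohorts`` pipeline used for real data — the tests only ever see
the category, so the representative values are immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import reference_study as ref
from . import stats as st
from .evaluation import (
    ComparisonConfig,
    ComparisonReport,
    TroughCategory,
    TroughObservation,
    compare_cohorts,
)

__all__ = ["ReferenceReport", "reference_report", "expand_counts"]

_REPRESENTATIVE = {
    TroughCategory.SUBTHERAPEUTIC: 5.0,
    TroughCategory.THERAPEUTIC: 15.0,
    TroughCategory.SUPRATHERAPEUTIC: 25.0,
}


def expand_counts(
    counts: dict[TroughCategory, int], group: str
) -> list[TroughObservation]:
    """Expand category counts into per-category representative observations."""
    obs = []
    for category, n in counts.items():
        obs.extend(
            TroughObservation(concentration=_REPRESENTATIVE[category], group=group)
            for _ in range(n)
        )
    return obs


@dataclass(frozen=True)
class ReferenceReport:
    # per-group category proportions (the stacked-bar distribution)
    distribution: dict[str, dict[TroughCategory, float]]
    # control vs intervention, default test variants per category
    primary_comparison: ComparisonReport
    # stratifier → stratum → TestResult (3-group Pearson chi-square)
    subgroups: dict[str, dict[str, st.TestResult]]
    power_n_per_group: int


def reference_report(
    counts: dict[str, dict[TroughCategory, int]] | None = None,
) -> ReferenceReport:
    """Rebuild the reference study's evaluation from packaged aggregates.

    ``counts`` overrides the packaged cohort compositions (mostly for
    testing); an empty override is rejected explicitly.
    """
    if counts is None:
        counts = ref.COHORT_CATEGORY_COUNTS
    if not counts:
        raise ValueError("empty fixture override: no cohorts to report on")

    groups = {g: expand_counts(c, g) for g, c in counts.items()}
    distribution = {
        g: {
            cat: sum(
                1 for o in obs if _REPRESENTATIVE[cat] == o.concentration
            ) / len(obs)
            for cat in TroughCategory
        }
        for g, obs in groups.items()
    }

    pair = {k: groups[k] for k in ("control", "intervention") if k in groups}
    if len(pair) == 2:
        primary = compare_cohorts(pair, ComparisonConfig())
    else:
        keys = list(groups)[:2]
        primary = compare_cohorts({k: groups[k] for k in keys}, ComparisonConfig())

    subgroups: dict[str, dict[str, st.TestResult]] = {}
    for stratifier, strata in ref.SUBGROUP_THERAPEUTIC_COUNTS.items():
        subgroups[stratifier] = {}
        for stratum, by_group in strata.items():
            table = st.ContingencyTable.from_array(
                [(t, n - t) for t, n in by_group.values()],
                row_labels=list(by_group),
                col_labels=["therapeutic", "other"],
            )
            subgroups[stratifier][stratum] = st.pearson_chi_square(
                table, continuity=False
            )

    n_power = st.two_proportion_sample_size(ref.POWER_SPEC)
    return ReferenceReport(
        distribution=distribution,
        primary_comparison=primary,
        subgroups=subgroups,
        power_n_per_group=n_power,
    )
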
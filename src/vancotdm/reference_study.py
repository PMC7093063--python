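"""Packaged summary data from the published collaborative-practice study.

The study that motivated this package reported only aggregate results:
the nomogram grid, trough-category percentages for three cohorts
(historical controls, intervention-period nomogram non-users, and
nomogram-dosed patients), subgroup attainment counts at the extremes of
weight and renal function, and the design parameters of its power
computation. Those aggregates are stored here as integers so the
evaluation pipeline can regenerate every reported comparison without
patient-level data.

Cohort category counts are reconstructed from the printed percentages and
group sizes; each reconstruction is the unique integer within ±0.5
percentage points of the printed proportion (arithmetic in comments).
"""

from __future__ import annotations

from .evaluation import TroughCategory
from .nomogram import Interval, WeightStratum
from .renal import RenalStratum
from .stats import PowerSpec

__all__ = [
    "DOSE_GRID",
    "COHORT_SIZES",
    "COHORT_CATEGORY_COUNTS",
    "SUBGROUP_THERAPEUTIC_COUNTS",
    "POWER_SPEC",
    "POWER_N_PER_GROUP",
    "cohort_composition",
]

# The published 4×4 dose grid: (renal stratum, weight stratum) → (mg, interval).
DOSE_GRID: dict[tuple[RenalStratum, WeightStratum], tuple[int, Interval]] = {
    (r, w): (dose, interval)
    for r, interval in (
        (RenalStratum.GT90, Interval.Q8),
        (RenalStratum.S50_90, Interval.Q12),
        (RenalStratum.S15_49, Interval.Q24),
        (RenalStratum.LT15_OR_RRT, Interval.SINGLE_DOSE),
    )
    for w, dose in (
        (WeightStratum.LT60, 750),
        (WeightStratum.S60_80, 1000),
        (WeightStratum.S81_100, 1250),
        (WeightStratum.GT100, 1500),
    )
}

COHORT_SIZES = {"control": 75, "non_user": 70, "intervention": 108}

# Reconstructed integer counts per trough category:
#   control      n=75:  32.0% → 24;  50.7% → 38;  17.3% → 13   (24+38+13 = 75)
#   non_user     n=70:  27.1% → 19;  51.4% → 36;  21.4% → 15   (19+36+15 = 70)
#   intervention n=108: 13.0% → 14;  69.4% → 75;  17.6% → 19   (14+75+19 = 108)
COHORT_CATEGORY_COUNTS: dict[str, dict[TroughCategory, int]] = {
    "control": {
        TroughCategory.SUBTHERAPEUTIC: 24,
        TroughCategory.THERAPEUTIC: 38,
        TroughCategory.SUPRATHERAPEUTIC: 13,
    },
    "non_user": {
        TroughCategory.SUBTHERAPEUTIC: 19,
        TroughCategory.THERAPEUTIC: 36,
        TroughCategory.SUPRATHERAPEUTIC: 15,
    },
    "intervention": {
        TroughCategory.SUBTHERAPEUTIC: 14,
        TroughCategory.THERAPEUTIC: 75,
        TroughCategory.SUPRATHERAPEUTIC: 19,
    },
}

# Therapeutic-range attainment (therapeutic, total) per subgroup and cohort,
# as printed in the study's subgroup table.
SUBGROUP_THERAPEUTIC_COUNTS: dict[str, dict[str, dict[str, tuple[int, int]]]] = {
    "weight": {
        "lt60": {"control": (4, 10), "non_user": (5, 14), "intervention": (9, 11)},
        "s60_80": {"control": (6, 19), "non_user": (7, 14), "intervention": (36, 50)},
        "s81_100": {"control": (18, 30), "non_user": (10, 20), "intervention": (14, 23)},
        "gt100": {"control": (10, 16), "non_user": (14, 22), "intervention": (16, 24)},
    },
    "egfr": {
        "lt15_or_rrt": {"control": (5, 9), "non_user": (9, 17), "intervention": (12, 16)},
        "s15_49": {"control": (8, 14), "non_user": (6, 8), "intervention": (14, 20)},
        "s50_90": {"control": (12, 24), "non_user": (9, 17), "intervention": (28, 42)},
        "gt90": {"control": (13, 28), "non_user": (12, 28), "intervention": (21, 30)},
    },
}

# Power computation the study design used: 34% subtherapeutic at baseline,
# a 20-point absolute decrease, two-sided α 0.05, 80% power → 70 per group.
POWER_SPEC = PowerSpec(p1=0.34, p2=0.14, alpha=0.05, power=0.80)
POWER_N_PER_GROUP = 70


def cohort_composition(group: str) -> tuple[int, dict[TroughCategory, int]]:
    """(n, category counts) for one of the three study cohorts."""
    counts = COHORT_CATEGORY_COUNTS[group]
    n = COHORT_SIZES[group]
    assert sum(counts.values()) == n
    return n, dict(counts)
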
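"""Initial vancomycin dose selection and therapeutic drug monitoring rules.

The nomogram is a 4×4 grid: actual body weight picks the dose per
administration (750 / 1000 / 1250 / 1500 mg, i.e. roughly 15–20 mg/kg
rounded to 250 mg increments) and the renal stratum picks the frequency
(q8 / q12 / q24, or a single level-guided dose for patients with
eGFR < 15, on renal replacement, or with unstable renal function). The
maximum initial regimen is capped at 4500 mg/day (1500 mg q8) for safety.

Each recommendation carries its monitoring plan: a steady-state trough
before the 4th dose (q8/q12) or 3rd dose (q24), or — for single-dose
regimens — a random level whose value drives redosing: < 20 mcg/ml means
repeat the dose, ≥ 20 mcg/ml means hold and recheck.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .renal import (
    EGFRResult,
    PatientCovariates,
    RenalModality,
    RenalStratum,
    compute_egfr,
    renal_stratum,
    round_half_away,
)

__all__ = [
    "WeightStratum",
    "Interval",
    "MonitoringPlan",
    "RandomLevelRule",
    "RandomLevelAction",
    "DoseRecommendation",
    "weight_stratum",
    "select_dose",
    "monitoring_plan",
    "random_level_decision",
    "RANDOM_LEVEL_THRESHOLD",
    "MAX_DAILY_DOSE_MG",
    "DOSE_BY_WEIGHT",
    "INTERVAL_BY_RENAL",
]

MAX_DAILY_DOSE_MG = 4500
RANDOM_LEVEL_THRESHOLD = 20.0  # mcg/ml


class WeightStratum(str, enum.Enum):
    LT60 = "lt60"        # < 60 kg
    S60_80 = "s60_80"    # 60 – 80 kg
    S81_100 = "s81_100"  # 81 – 100 kg
    GT100 = "gt100"      # > 100 kg


class Interval(str, enum.Enum):
    Q8 = "q8"
    Q12 = "q12"
    Q24 = "q24"
    SINGLE_DOSE = "single_dose"

    @property
    def hours(self) -> float | None:
        return {"q8": 8.0, "q12": 12.0, "q24": 24.0}.get(self.value)

    @property
    def doses_per_day(self) -> int | None:
        return {"q8": 3, "q12": 2, "q24": 1}.get(self.value)


DOSE_BY_WEIGHT: dict[WeightStratum, int] = {
    WeightStratum.LT60: 750,
    WeightStratum.S60_80: 1000,
    WeightStratum.S81_100: 1250,
    WeightStratum.GT100: 1500,
}

INTERVAL_BY_RENAL: dict[RenalStratum, Interval] = {
    RenalStratum.GT90: Interval.Q8,
    RenalStratum.S50_90: Interval.Q12,
    RenalStratum.S15_49: Interval.Q24,
    RenalStratum.LT15_OR_RRT: Interval.SINGLE_DOSE,
}


class RandomLevelAction(str, enum.Enum):
    REPEAT_DOSE = "repeat_dose"
    HOLD_AND_RECHECK = "hold_and_recheck"


@dataclass(frozen=True)
class RandomLevelRule:
    """Level-guided redosing rule attached to single-dose regimens.

    Below ``threshold_mcg_ml`` the dose is repeated; at or above it the
    dose is held and the level rechecked — 12 h later for eGFR < 15 /
    continuous RRT / unstable renal function, or after the next session
    for intermittent hemodialysis.
    """

    threshold_mcg_ml: float = RANDOM_LEVEL_THRESHOLD
    recheck_offset_h: float | None = 12.0
    recheck_after_dialysis: bool = False


@dataclass(frozen=True)
class MonitoringPlan:
    """When to draw the level and, for random levels, what to do with it."""

    specimen: str  # "steady_state_trough" | "random_level"
    timing: str    # human-readable timing rule
    before_dose_number: int | None = None     # troughs: drawn 30 min prior
    hours_after_dose: float | None = None     # random levels off a timed draw
    decision_rule: RandomLevelRule | None = None


@dataclass(frozen=True)
class DoseRecommendation:
    """An initial vancomycin regimen plus its monitoring plan.

    ``total_daily_dose_mg`` is ``None`` for single-dose regimens: redosing
    is level-driven, so a daily total is not defined at ordering time.
    """

    dose_mg: int
    interval: Interval
    total_daily_dose_mg: int | None
    weight_stratum: WeightStratum
    renal_stratum: RenalStratum
    egfr: float
    monitoring: MonitoringPlan = field(compare=False)

    def __post_init__(self) -> None:
        if self.dose_mg % 250 != 0:
            raise ValueError(f"dose must be a 250 mg multiple, got {self.dose_mg}")
        if (
            self.total_daily_dose_mg is not None
            and self.total_daily_dose_mg > MAX_DAILY_DOSE_MG
        ):
            raise ValueError(
                f"daily dose {self.total_daily_dose_mg} exceeds cap {MAX_DAILY_DOSE_MG}"
            )


def weight_stratum(weight_kg: float) -> WeightStratum:
    """Bin actual body weight onto the nomogram's integer-labelled columns.

    Weight is rounded to the nearest kg (ties away from zero), then
    ≤ 59 → <60, 60–80, 81–100, ≥ 101 → >100.
    """
    if not weight_kg > 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    w = round_half_away(weight_kg)
    if w <= 59:
        return WeightStratum.LT60
    if w <= 80:
        return WeightStratum.S60_80
    if w <= 100:
        return WeightStratum.S81_100
    return WeightStratum.GT100


def monitoring_plan(interval: Interval, modality: RenalModality) -> MonitoringPlan:
    """Monitoring attached to a regimen.

    q8/q12 → steady-state trough 30 min before the 4th dose; q24 → trough
    30 min before the 3rd dose; single dose → random level 24 h after the
    dose (recheck in 12 h), or 2 h after hemodialysis (recheck after the
    next session) for intermittent-hemodialysis patients.
    """
    if interval in (Interval.Q8, Interval.Q12):
        return MonitoringPlan(
            specimen="steady_state_trough",
            timing="30 minutes prior to 4th dose",
            before_dose_number=4,
        )
    if interval is Interval.Q24:
        return MonitoringPlan(
            specimen="steady_state_trough",
            timing="30 minutes prior to 3rd dose",
            before_dose_number=3,
        )
    if modality is RenalModality.INTERMITTENT_HEMODIALYSIS:
        return MonitoringPlan(
            specimen="random_level",
            timing="2 hours after hemodialysis",
            hours_after_dose=None,
            decision_rule=RandomLevelRule(
                recheck_offset_h=None, recheck_after_dialysis=True
            ),
        )
    return MonitoringPlan(
        specimen="random_level",
        timing="24 hours after the dose",
        hours_after_dose=24.0,
        decision_rule=RandomLevelRule(recheck_offset_h=12.0),
    )


def select_dose(
    cov: PatientCovariates, egfr: EGFRResult | float | None = None
) -> DoseRecommendation:
    """Select the initial regimen from the nomogram grid.

    The dose per administration depends only on the weight stratum and the
    dosing interval only on the renal stratum; the two choices are
    independent, which is what keeps the grid a plain 4×4 lookup. An
    explicit ``egfr`` overrides recomputation from covariates (useful when
    a laboratory-reported eGFR is available).
    """
    if egfr is None:
        egfr = compute_egfr(cov)
    egfr_value = egfr.value if isinstance(egfr, EGFRResult) else float(egfr)
    ws = weight_stratum(cov.weight_kg)
    rs = renal_stratum(egfr_value, cov.modality)
    dose = DOSE_BY_WEIGHT[ws]
    interval = INTERVAL_BY_RENAL[rs]
    per_day = interval.doses_per_day
    tdd = dose * per_day if per_day is not None else None
    return DoseRecommendation(
        dose_mg=dose,
        interval=interval,
        total_daily_dose_mg=tdd,
        weight_stratum=ws,
        renal_stratum=rs,
        egfr=egfr_value,
        monitoring=monitoring_plan(interval, cov.modality),
    )


def random_level_decision(
    level_mcg_ml: float, modality: RenalModality
) -> tuple[RandomLevelAction, RandomLevelRule]:
    """Apply the random-level redosing rule to a measured concentration.

    Levels below 20 mcg/ml call for repeating the dose. Levels at or above
    20 mcg/ml (the boundary is assigned to the conservative hold arm) call
    for holding and rechecking: 12 h later, or after the next dialysis
    session for intermittent hemodialysis.
    """
    if level_mcg_ml < 0:
        raise ValueError(f"level must be non-negative, got {level_mcg_ml}")
    on_ihd = modality is RenalModality.INTERMITTENT_HEMODIALYSIS
    rule = RandomLevelRule(
        recheck_offset_h=None if on_ihd else 12.0,
        recheck_after_dialysis=on_ihd,
    )
    if level_mcg_ml < RANDOM_LEVEL_THRESHOLD:
        return RandomLevelAction.REPEAT_DOSE, rule
    return RandomLevelAction.HOLD_AND_RECHECK, rule
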
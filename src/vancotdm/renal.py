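"""Renal function estimation and stratification for vancomycin dosing.

Estimates the glomerular filtration rate with the four-variable MDRD
equation (creatinine, age, sex, race) and maps the result — together with
the patient's renal-replacement status — onto the four renal strata used by
the dosing nomogram.

The MDRD4 estimate is already indexed to 1.73 m² body surface area, so no
further body-surface normalisation is applied. Serum creatinine is accepted
in mg/dL only; callers working in µmol/L must convert explicitly (silent
unit auto-detection is a classic source of 88-fold dosing errors).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Sex",
    "RenalModality",
    "RenalStratum",
    "PatientCovariates",
    "EGFRResult",
    "compute_egfr",
    "renal_stratum",
    "round_half_away",
]

# MDRD4 (units: mg/dL creatinine, years age; result ml/min/1.73 m²)
_MDRD_SCALE = 186.0
_MDRD_SCR_EXP = -1.154
_MDRD_AGE_EXP = -0.203
_MDRD_FEMALE = 0.742
_MDRD_BLACK = 1.210


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class RenalModality(str, enum.Enum):
    """Renal-replacement / renal-stability status.

    ``UNSTABLE`` is a caller-supplied flag: the protocol gives no
    quantitative definition of unstable renal function, so detection from
    laboratory trends is deliberately out of scope.
    """

    NONE = "none"
    INTERMITTENT_HEMODIALYSIS = "ihd"
    CONTINUOUS_RRT = "crrt"
    UNSTABLE = "unstable"


class RenalStratum(str, enum.Enum):
    """The nomogram's four renal bins (eGFR in ml/min/1.73 m²)."""

    GT90 = "gt90"          # eGFR > 90
    S50_90 = "s50_90"      # 50 – 90
    S15_49 = "s15_49"      # 15 – 49
    LT15_OR_RRT = "lt15_or_rrt"  # < 15, any RRT, or unstable renal function


@dataclass(frozen=True)
class PatientCovariates:
    """Demographic and renal inputs consumed by the dosing engine.

    Parameters
    ----------
    age_years : float
        Age in years, > 0 (the protocol targets adults).
    sex : Sex
    black_race : bool
        Race multiplier flag of the MDRD4 equation.
    scr_mg_dl : float
        Serum creatinine in mg/dL, > 0.
    weight_kg : float
        Actual body weight in kg, > 0 (the nomogram doses on actual, not
        ideal or adjusted, body weight).
    modality : RenalModality
    """

    age_years: float
    sex: Sex
    black_race: bool
    scr_mg_dl: float
    weight_kg: float
    modality: RenalModality = RenalModality.NONE

    def __post_init__(self) -> None:
        if not self.age_years > 0:
            raise ValueError(f"age_years must be > 0, got {self.age_years}")
        if not self.scr_mg_dl > 0:
            raise ValueError(f"scr_mg_dl must be > 0, got {self.scr_mg_dl}")
        if not self.weight_kg > 0:
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")


@dataclass(frozen=True)
class EGFRResult:
    """An MDRD4 eGFR point estimate in ml/min/1.73 m²."""

    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"eGFR must be positive, got {self.value}")


def compute_egfr(cov: PatientCovariates) -> EGFRResult:
    """Four-variable MDRD estimate of the glomerular filtration rate.

    eGFR = 186 · SCr^−1.154 · age^−0.203 · (0.742 if female) · (1.210 if Black)

    with SCr in mg/dL and age in years; the product is already normalised
    to 1.73 m² body surface area.
    """
    value = (
        _MDRD_SCALE
        * cov.scr_mg_dl ** _MDRD_SCR_EXP
        * cov.age_years ** _MDRD_AGE_EXP
    )
    if cov.sex is Sex.FEMALE:
        value *= _MDRD_FEMALE
    if cov.black_race:
        value *= _MDRD_BLACK
    return EGFRResult(value)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (80.5 → 81)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def renal_stratum(
    egfr: EGFRResult | float, modality: RenalModality = RenalModality.NONE
) -> RenalStratum:
    """Map (eGFR, renal-replacement status) to a nomogram renal stratum.

    Any renal-replacement modality or the unstable-renal-function flag
    forces the ``LT15_OR_RRT`` stratum regardless of the eGFR value.
    Otherwise the eGFR is rounded to the nearest integer (ties away from
    zero) and binned on the integer labels: ≥ 91 → GT90, 50–90 → S50_90,
    15–49 → S15_49, ≤ 14 → LT15_OR_RRT. The rounding convention makes the
    bins a gap-free partition of the positive reals.
    """
    if modality is not RenalModality.NONE:
        return RenalStratum.LT15_OR_RRT
    value = egfr.value if isinstance(egfr, EGFRResult) else float(egfr)
    if not value > 0:
        raise ValueError(f"eGFR must be positive, got {value}")
    g = round_half_away(value)
    if g >= 91:
        return RenalStratum.GT90
    if g >= 50:
        return RenalStratum.S50_90
    if g >= 15:
        return RenalStratum.S15_49
    return RenalStratum.LT15_OR_RRT
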
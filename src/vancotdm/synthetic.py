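"""Synthetic cohorts and steady-state troughs for end-to-end testing.

Real trough data are patient-level records this package cannot ship, so
this module manufactures them: covariate-realistic patients (age, sex,
actual body weight, serum creatinine back-solved from a target renal
stratum, renal-replacement mix) and first steady-state troughs from a
one-compartment intermittent-infusion model

    C_max,ss = (dose / t_inf) / CL · (1 − e^{−k·t_inf}) / (1 − e^{−k·τ})
    C_trough = C_max,ss · e^{−k·(τ − t_inf)}

with clearance CL (L/h), volume V (L), k = CL/V (1/h), infusion duration
t_inf (h) and dosing interval τ (h); mg/L ≡ mcg/ml. Population PK values
are linear in eGFR (clearance) and weight (volume) with lognormal
between-subject variability. Every constant here is invented plumbing for
testing the dosing and evaluation pipeline — none is an estimate from
clinical data, and none is used to assert a clinical result.

The default covariate targets mimic a published ICU vancomycin cohort:
median age ≈ 53 y, 56% male, weight median ≈ 78 kg (IQR ≈ 67–96), and a
renal-stratum mix of 28 / 39 / 19 / 15 % across >90 / 50–90 / 15–49 /
<15-or-RRT. Strata are sampled directly from that mix and creatinine is
solved through the MDRD4 equation, so the generated stratum frequencies
are unbiased for the configured targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nomogram import DoseRecommendation, Interval, select_dose
from .renal import (
    PatientCovariates,
    RenalModality,
    RenalStratum,
    Sex,
    compute_egfr,
)

__all__ = [
    "PKParameters",
    "CovariateModel",
    "PKModel",
    "SimulationConfig",
    "generate_cohort",
    "assign_pk",
    "simulate_trough",
    "simulate_single_dose_level",
    "simulate_trial",
]


@dataclass(frozen=True)
class PKParameters:
    """One-compartment parameters: clearance (L/h), volume (L), k = CL/V."""

    clearance_l_h: float
    volume_l: float
    infusion_duration_h: float = 1.0

    def __post_init__(self) -> None:
        for name in ("clearance_l_h", "volume_l", "infusion_duration_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def k(self) -> float:
        return self.clearance_l_h / self.volume_l


@dataclass(frozen=True)
class CovariateModel:
    """Parametric covariate distributions (targets, not fitted values).

    Age is normal truncated at 18 y; weight lognormal (median
    exp(log_weight_mu) kg); the renal stratum is drawn from
    ``stratum_probs`` (order: >90, 50–90, 15–49, <15-or-RRT) and serum
    creatinine back-solved from a uniform eGFR draw inside the stratum;
    within the lowest stratum ``modality_probs`` splits patients across
    none / intermittent hemodialysis / continuous RRT / unstable.
    """

    age_mean: float = 53.0
    age_sd: float = 16.0
    age_min: float = 18.0
    male_fraction: float = 0.56
    black_fraction: float = 0.15
    log_weight_mu: float = math.log(78.0)
    log_weight_sigma: float = 0.27
    # exact cohort fractions (30, 42, 20, 16 of 108) rather than the printed
    # rounded percentages (28/39/19/15), which sum to 101%
    stratum_probs: tuple[float, float, float, float] = (
        30 / 108, 42 / 108, 20 / 108, 16 / 108,
    )
    # ranges the uniform eGFR draw uses per stratum
    egfr_ranges: dict[RenalStratum, tuple[float, float]] = field(
        default_factory=lambda: {
            RenalStratum.GT90: (91.0, 140.0),
            RenalStratum.S50_90: (50.0, 90.0),
            RenalStratum.S15_49: (15.0, 49.0),
            RenalStratum.LT15_OR_RRT: (4.0, 14.0),
        }
    )
    modality_probs: tuple[float, float, float, float] = (0.3, 0.4, 0.2, 0.1)

    def __post_init__(self) -> None:
        if abs(sum(self.stratum_probs) - 1.0) > 1e-9:
            raise ValueError("stratum_probs must sum to 1")
        if abs(sum(self.modality_probs) - 1.0) > 1e-9:
            raise ValueError("modality_probs must sum to 1")
        if self.age_sd < 0 or self.log_weight_sigma < 0:
            raise ValueError("dispersion parameters must be ≥ 0")


@dataclass(frozen=True)
class PKModel:
    """Invented population PK constants (not estimates from any study).

    clearance = (theta0 + theta1 · eGFR) · exp(η),   η ~ N(0, omega_cl²)
    volume    = v_per_kg · weight · exp(η′),         η′ ~ N(0, omega_v²)

    Renal-replacement and eGFR<15 patients get a fixed low clearance
    ``rrt_clearance_l_h`` (times the same lognormal variability); dialysis
    session kinetics are not modelled.
    """

    theta0_l_h: float = 0.4
    theta1_l_h_per_unit: float = 0.045
    v_per_kg: float = 0.7
    omega_cl: float = 0.25
    omega_v: float = 0.15
    rrt_clearance_l_h: float = 1.0
    infusion_duration_h: float = 1.0

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.omega_v < 0:
            raise ValueError("variability SDs must be ≥ 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_per_arm: int = 500
    covariates: CovariateModel = field(default_factory=CovariateModel)
    pk: PKModel = field(default_factory=PKModel)
    # comparator: one flat regimen for everyone
    comparator_dose_mg: int = 1000
    comparator_interval_h: float = 12.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be ≥ 1")


_MODALITIES = (
    RenalModality.NONE,
    RenalModality.INTERMITTENT_HEMODIALYSIS,
    RenalModality.CONTINUOUS_RRT,
    RenalModality.UNSTABLE,
)
_STRATA = (
    RenalStratum.GT90,
    RenalStratum.S50_90,
    RenalStratum.S15_49,
    RenalStratum.LT15_OR_RRT,
)


def _scr_for_egfr(
    egfr: float, age: float, sex: Sex, black: bool
) -> float:
    """Invert MDRD4 for creatinine at a target eGFR."""
    c = 186.0 * age**-0.203
    if sex is Sex.FEMALE:
        c *= 0.742
    if black:
        c *= 1.210
    return (egfr / c) ** (1.0 / -1.154)


def generate_cohort(
    config: CovariateModel | SimulationConfig, n: int, rng: np.random.Generator
) -> list[PatientCovariates]:
    """Draw ``n`` synthetic patients; reproducible given the generator state."""
    cm = config.covariates if isinstance(config, SimulationConfig) else config
    patients = []
    for _ in range(n):
        age = float(rng.normal(cm.age_mean, cm.age_sd))
        while age < cm.age_min:
            age = float(rng.normal(cm.age_mean, cm.age_sd))
        sex = Sex.MALE if rng.random() < cm.male_fraction else Sex.FEMALE
        black = bool(rng.random() < cm.black_fraction)
        weight = float(rng.lognormal(cm.log_weight_mu, cm.log_weight_sigma))
        stratum = _STRATA[int(rng.choice(4, p=cm.stratum_probs))]
        lo, hi = cm.egfr_ranges[stratum]
        egfr = float(rng.uniform(lo, hi))
        scr = _scr_for_egfr(egfr, age, sex, black)
        if stratum is RenalStratum.LT15_OR_RRT:
            modality = _MODALITIES[int(rng.choice(4, p=cm.modality_probs))]
        else:
            modality = RenalModality.NONE
        patients.append(
            PatientCovariates(
                age_years=age,
                sex=sex,
                black_race=black,
                scr_mg_dl=scr,
                weight_kg=weight,
                modality=modality,
            )
        )
    return patients


def assign_pk(
    cov: PatientCovariates, model: PKModel, rng: np.random.Generator
) -> PKParameters:
    """Sample individual PK parameters from the population model."""
    egfr = compute_egfr(cov).value
    if cov.modality is not RenalModality.NONE or egfr < 15:
        cl_typ = model.rrt_clearance_l_h
    else:
        cl_typ = model.theta0_l_h + model.theta1_l_h_per_unit * egfr
    eta_cl = float(rng.normal(0.0, model.omega_cl)) if model.omega_cl > 0 else 0.0
    eta_v = float(rng.normal(0.0, model.omega_v)) if model.omega_v > 0 else 0.0
    return PKParameters(
        clearance_l_h=cl_typ * math.exp(eta_cl),
        volume_l=model.v_per_kg * cov.weight_kg * math.exp(eta_v),
        infusion_duration_h=model.infusion_duration_h,
    )


def simulate_trough(pk: PKParameters, dose_mg: float, interval_h: float) -> float:
    """Closed-form steady-state trough (mcg/ml) for intermittent infusion."""
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if interval_h <= pk.infusion_duration_h:
        raise ValueError(
            f"interval ({interval_h} h) must exceed infusion duration "
            f"({pk.infusion_duration_h} h)"
        )
    k = pk.k
    t_inf = pk.infusion_duration_h
    rate = dose_mg / t_inf  # mg/h
    c_max = rate / pk.clearance_l_h * (1 - math.exp(-k * t_inf)) / (
        1 - math.exp(-k * interval_h)
    )
    return c_max * math.exp(-k * (interval_h - t_inf))


def simulate_single_dose_level(
    pk: PKParameters, dose_mg: float, hours_after_dose_start: float
) -> float:
    """Concentration (mcg/ml) at a random-level draw after one dose."""
    t_inf = pk.infusion_duration_h
    if hours_after_dose_start <= t_inf:
        raise ValueError("sampling time must be after the end of the infusion")
    k = pk.k
    c_end = dose_mg / t_inf / pk.clearance_l_h * (1 - math.exp(-k * t_inf))
    return c_end * math.exp(-k * (hours_after_dose_start - t_inf))


def _first_level(pk: PKParameters, rec: DoseRecommendation) -> float:
    if rec.interval is Interval.SINGLE_DOSE:
        # random level 24 h after the dose starts
        return simulate_single_dose_level(pk, rec.dose_mg, 24.0)
    return simulate_trough(pk, rec.dose_mg, rec.interval.hours)


def simulate_trial(
    config: SimulationConfig, rng: np.random.Generator | int
) -> pd.DataFrame:
    """Dose one synthetic cohort with the nomogram and with a comparator.

    Each patient is dosed twice — once by the nomogram and once with the
    flat comparator regimen (default 1000 mg q12 for everyone) — and the
    first measured level is simulated from the same individual PK
    parameters, so arms differ only in the dosing strategy. Returns a
    tidy frame with columns ``patient_id, group, trough_mcg_ml,
    weight_kg, egfr, modality``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    patients = generate_cohort(config.covariates, config.n_per_arm, rng)
    rows = []
    for i, cov in enumerate(patients):
        pk = assign_pk(cov, config.pk, rng)
        egfr = compute_egfr(cov).value
        rec = select_dose(cov)
        nomogram_level = _first_level(pk, rec)
        comparator_level = simulate_trough(
            pk, config.comparator_dose_mg, config.comparator_interval_h
        )
        for group, level in (
            ("nomogram", nomogram_level),
            ("comparator", comparator_level),
        ):
            rows.append(
                {
                    "patient_id": f"P{i:05d}",
                    "group": group,
                    "trough_mcg_ml": round(level, 6),
                    "weight_kg": round(cov.weight_kg, 3),
                    "egfr": round(egfr, 3),
                    "modality": cov.modality.value,
                }
            )
    return pd.DataFrame(rows)
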
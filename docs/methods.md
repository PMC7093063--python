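# Methods

## The dosing nomogram

The engine is a deterministic 4×4 lookup. Actual body weight (kg) selects
the dose per administration and the renal stratum selects the interval:

| | <60 kg | 60–80 kg | 81–100 kg | >100 kg |
|---|---|---|---|---|
| eGFR >90 | 750 q8 | 1000 q8 | 1250 q8 | 1500 q8 |
| 50–90 | 750 q12 | 1000 q12 | 1250 q12 | 1500 q12 |
| 15–49 | 750 q24 | 1000 q24 | 1250 q24 | 1500 q24 |
| <15 / RRT / unstable | 750 ×1 | 1000 ×1 | 1250 ×1 | 1500 ×1 |

Doses are multiples of 250 mg and the recurring maximum is 4500 mg/day
(1500 mg q8); both are enforced as invariants of `DoseRecommendation`.
Renal function is the four-variable MDRD estimate (coefficients 186,
−1.154, −0.203, 0.742, 1.210), already indexed to 1.73 m², computed from
a point-in-time creatinine; dynamic renal function is out of scope, and
"unstable renal function" is a caller-supplied flag with no quantitative
definition.

**Boundary conventions.** The grid's row/column labels are integers, so
continuous eGFR and weight are rounded to the nearest integer (ties away
from zero) before binning: eGFR 90.4 → 90 → q12, 90.5 → 91 → q8; weight
80.4 → 80 → 1000 mg, 80.5 → 81 → 1250 mg. A random level of exactly
20 mcg/ml goes to the hold-and-recheck arm — the conservative choice,
since the written rule covers only strict inequalities. Creatinine is
accepted in mg/dL only; no µmol/L auto-conversion.

Single-dose regimens report `total_daily_dose_mg = None`: redosing is
level-driven, so a daily total is undefined at ordering time.

## Trough evaluation

Troughs are classified against the 10–20 mcg/ml goal range: < 10
subtherapeutic, 10–20 inclusive therapeutic, > 20 supratherapeutic — a
partition of [0, ∞). Cohort summaries report counts, proportions, the
midrank median, and the IQR as 25th/75th percentiles with linear
interpolation between order statistics (the source aggregates do not
state a quantile convention; this one is fixed and documented here).

`compare_cohorts` builds, per category, the group × (in-category / not)
table and applies a configurable test. The default variant map mirrors
the published evaluation this package reproduces: the primary
(subtherapeutic) 2×2 comparison uses the continuity-corrected chi-square,
the secondary comparisons the uncorrected Pearson test, and three-group
subgroup tables the uncorrected Pearson test with df = groups − 1. The
source does not say which software variant produced each printed p-value;
these are the variants that reproduce them, and every choice is
overridable through `ComparisonConfig`. p-values are kept at full
precision; rounding to the printed 2–3 decimals happens only in reports.

Packaged aggregates (`reference_study.py`) store the published cohort
compositions as integers reconstructed from printed percentages and group
sizes — each is the unique integer within ±0.5 percentage points of the
printed proportion (e.g. 13.0% of 108 → 14; the arithmetic is in the
module's comments). `report.reference_report()` expands those counts into
representative observations and pushes them through the same pipeline
used for real data.

## The statistical battery

Authored from first principles; scipy supplies only distribution
primitives (chi-square and normal tails, the hypergeometric pmf) and
midranking. The scipy test functions serve as independent cross-checks in
the test suite, never as the implementation.

* **Pearson chi-square**: Σ(O−E)²/E with margin-derived expectations;
  Yates correction (|O−E| reduced by 0.5, floored at 0) available for
  2×2; zero margins raise `DegenerateTableError`.
* **Fisher exact (2×2, two-sided)**: sum of hypergeometric probabilities
  of all tables with the observed margins whose probability is ≤ the
  observed table's, with a 1 + 1e−7 relative slack so float-tied tables
  are included.
* **Mann-Whitney U**: U from midranks. Exact mode enumerates all
  C(n1+n2, n1) rank splits and computes P(|U − n1n2/2| ≥ observed), which
  stays valid under ties; it is the default for n1 + n2 ≤ 10. Otherwise a
  normal approximation with tie-corrected variance and 0.5 continuity
  correction. The switch point is an overridable argument.
* **Kruskal-Wallis**: H = 12/(N(N+1)) Σ nᵢ(r̄ᵢ − r̄)² divided by the tie
  factor 1 − Σ(t³−t)/(N³−N); chi-square tail with df = k − 1. When every
  observation is tied the factor vanishes and H is defined as 0 (p = 1).
* **Two-proportion sample size**:
  n = (z₁₋α/₂ √(2p̄q̄) + z₁₋β √(p₁q₁ + p₂q₂))² / (p₁ − p₂)², pooled under
  the null and unpooled under the alternative, rounded to the *nearest*
  integer. Nearest (not ceiling) rounding is what reproduces the
  historical design value of 70 per group for (0.34, 0.14, α 0.05,
  power 0.80), where the formula evaluates to 70.40.

## The synthetic cohort and PK simulator

The simulator exists so the dosing engine and evaluation pipeline can be
exercised end-to-end; none of its constants is estimated from clinical
data and none is used to assert a clinical result.

**Covariates.** Age ~ Normal(53, 16) truncated at 18 y; sex male with
probability 0.56; weight lognormal with median 78 kg and log-SD 0.27
(IQR ≈ 66–94 kg); race flag Bernoulli(0.15). The renal stratum is drawn
directly from the target mix — the exact cohort fractions 30/42/20/16 of
108 across >90 / 50–90 / 15–49 / <15-or-RRT, used instead of the printed
rounded percentages, which sum to 101% — an eGFR is drawn uniformly
inside the stratum's range, and creatinine is back-solved through MDRD4.
Sampling the stratum directly makes the generated stratum frequencies
unbiased for the configured targets; the cost is that creatinine's
marginal distribution is implied rather than controlled. These are
parametric approximations to marginal summaries of a real ICU cohort:
the joint covariate structure (e.g. weight-creatinine correlation,
sicker-patient clustering) is not emulated, so passing tests demonstrate
pipeline correctness, not clinical realism.

**Pharmacokinetics.** One-compartment intermittent infusion at steady
state:

    C_max,ss = (dose/t_inf)/CL · (1 − e^{−k·t_inf}) / (1 − e^{−k·τ}),
    C_trough = C_max,ss · e^{−k·(τ − t_inf)},  k = CL/V,  mg/L ≡ mcg/ml.

Population model: CL = (0.4 + 0.045·eGFR)·e^η L/h with η ~ N(0, 0.25²),
V = 0.7·weight·e^η′ L with η′ ~ N(0, 0.15²), t_inf = 1 h. The clearance
slope puts a typical eGFR-100 patient near 4.9 L/h, in the range expected
from vancomycin's predominantly renal elimination; 0.7 L/kg is the
textbook distribution volume. Patients with eGFR < 15 or on renal
replacement get a fixed low typical clearance (1.0 L/h); dialysis-session
kinetics are not modelled, consistent with the protocol's
single-dose-plus-random-level path, and their first level is simulated
24 h after the single dose. The closed form is verified in the tests
against an independent superposition-of-doses oracle (sum of ≥ 300
single-dose tails) to < 0.1%.

**Trial simulation.** Each synthetic patient is dosed twice — by the
nomogram and by a flat comparator (1000 mg q12 for everyone) — with the
same individual PK parameters, so the arms differ only in strategy. The
whole pipeline is reproducible bit-for-bit under a fixed seed.

## Numerical choices and degenerate inputs

* Rounding for binning is half-away-from-zero, matching how clinicians
  read integer-labelled charts.
* Empty cohorts, single groups, empty samples, zero margins, negative
  concentrations/levels and non-positive covariates all raise
  `ValueError` (or its subclasses) rather than returning sentinels.
* Subgroup strata in which any group has no observations are skipped
  with a warning instead of producing a degenerate table.
* Test problem sizes: property batteries use 100–200 randomized draws;
  cohort-summary recovery uses n = 5000; the simulated trial uses 500
  patients per arm — sizes at which the checked tolerances (±3 points on
  a 56% binomial proportion, ±5 points on stratum mix) hold with large
  margin under the seeded generators.

## Known limitations

The engine stops at the initial regimen plus the first-level decision;
no adjustment nomogram after the first trough, no AUC:MIC estimation, no
continuous-infusion dosing, no doses above 4500 mg/day, and no
alternative eGFR equations (CKD-EPI, Cockcroft-Gault). The published
cohort medians (13.0 vs 14.8 mcg/ml) require patient-level data that do
not exist in aggregate form and are therefore not reproduced anywhere in
this package.
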
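# vancotdm

Decision support for initial intravenous vancomycin dosing in critically
ill adults, plus the statistics used to evaluate how well a dosing
protocol attains therapeutic trough concentrations.

Vancomycin needs 36–48 h to reach steady state, so a wrong first dose
means a patient is under- or overdosed for days: underdosing risks
treatment failure and selection of resistant staphylococci, overdosing
risks nephrotoxicity. `vancotdm` implements a nomogram that picks the
initial regimen from two covariates:

* **dose per administration** from actual body weight
  (<60 / 60–80 / 81–100 / >100 kg → 750 / 1000 / 1250 / 1500 mg,
  roughly 15–20 mg/kg rounded to 250 mg increments);
* **dosing interval** from renal function, estimated with the
  four-variable MDRD equation

  eGFR = 186 · SCr⁻¹·¹⁵⁴ · age⁻⁰·²⁰³ · (0.742 if female) · (1.210 if Black)

  in ml/min/1.73 m² (>90 → q8, 50–90 → q12, 15–49 → q24; eGFR <15, any
  renal replacement, or unstable renal function → a single dose with
  level-guided redosing).

The maximum initial regimen is capped at 4500 mg/day (1500 mg q8). Each
recommendation carries its monitoring plan — a steady-state trough 30 min
before the 4th dose (q8/q12) or 3rd dose (q24), or a random level for
single-dose patients: below 20 mcg/ml repeat the dose, at or above hold
and recheck. Troughs are classified against the 10–20 mcg/ml goal range
(subtherapeutic < 10, supratherapeutic > 20).

The package also ships:

* a first-principles statistical battery (Pearson chi-square with
  optional Yates correction, Fisher's exact test, Mann-Whitney U,
  Kruskal-Wallis, two-proportion sample size) for comparing
  trough-attainment cohorts;
* an evaluation layer that builds the category-by-group contingency
  tables and subgroup analyses at the extremes of weight and renal
  function;
* a synthetic-cohort simulator (one-compartment intermittent-infusion
  pharmacokinetics) so the whole pipeline is testable end-to-end without
  patient data;
* packaged aggregate counts from the published collaborative-practice
  study the nomogram comes from, so its reported evaluation can be
  regenerated from integers.

## Worked example

A 50-year-old 78 kg man, serum creatinine 1.0 mg/dL, no renal
replacement:

```bash
$ vancotdm dose --age 50 --sex M --scr 1.0 --weight 78
{
  "dose_mg": 1000,
  "interval": "q12",
  "tdd_mg": 2000,
  "weight_stratum": "s60_80",
  "renal_stratum": "s50_90",
  "egfr": 84.06631936684785,
  "monitoring": {
    "specimen": "steady_state_trough",
    "timing": "30 minutes prior to 4th dose",
    ...
  }
}
```

His MDRD4 eGFR is 84.1 ml/min/1.73 m² (renal stratum 50–90 → every 12
hours) and his weight falls in the 60–80 kg column (→ 1000 mg), so the
engine recommends 1000 mg q12 — 2000 mg/day — with a trough drawn 30
minutes before the 4th dose.

The design-stage power computation — detecting a drop in subtherapeutic
troughs from 34% to 14% with two-sided α = 0.05 and 80% power:

```bash
$ vancotdm power --p1 0.34 --p2 0.14
{ "n_per_group": 70, ... }
```

Python API equivalents live in `vancotdm.renal`, `vancotdm.nomogram`,
`vancotdm.stats`, `vancotdm.evaluation` and `vancotdm.synthetic`; see
`docs/methods.md` for the models and conventions.

Other subcommands: `vancotdm simulate` (synthetic nomogram-vs-flat-dosing
trial), `vancotdm evaluate` / `vancotdm subgroups` (trough CSV analysis),
`vancotdm random-level` (redosing decision), and
`vancotdm reference-report`, which regenerates the published evaluation
from the packaged counts — e.g. the subtherapeutic comparison
(32.0% vs 13.0%) gives p = 0.003 with the continuity-corrected
chi-square, and the 60–80 kg subgroup comparison gives p = 0.01.

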
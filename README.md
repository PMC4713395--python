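# icu-intensity

Severity-adjusted analysis of treatment intensity, age and hospital
mortality in adult ICU cohorts, built for administrative (claims-style)
data where each hospital stay carries stay-level procedure summaries, a
SAPS II severity score and a vital status — the kind of data used to ask
whether the higher mortality of elderly ICU patients reflects higher
severity, lower treatment intensity, or lower treatment efficacy.

The package provides, as composable library functions and as a CLI:

* **SAPS II scoring** (`icu_intensity.saps2`) — the 15-variable
  Simplified Acute Physiology Score II with its component point table,
  the age-related points on the six canonical bands (<40, 40–59, 60–69,
  70–74, 75–79, ≥80 → 0/7/12/15/16/18 points), the *age-adjusted* score
  (total − age points), and the published logistic conversion to a
  predicted hospital-mortality probability,
  `logit p = −7.7631 + 0.0737·S + 0.9971·ln(S + 1)`.
* **Treatment-intensity classification** (`icu_intensity.intensity`) — a
  four-group indicator built from the three most frequent organ
  supports. Each organ is graded *low-intense* (dobutamine/dopamine
  ≤ 8 µg/kg/min; noninvasive ventilation; invasive ventilation with
  FiO2 < 0.6 and PEEP < 6 cm H2O) or *high-intense*
  (dobutamine/dopamine > 8 µg/kg/min or any epinephrine/norepinephrine;
  invasive ventilation with FiO2 ≥ 0.6 or PEEP ≥ 6 cm H2O; any renal
  replacement therapy); groups are 0 = no support, 1 = one low-intense
  support, 2 = two low-intense or one high-intense support, 3 = more
  intense support.
* **Cohort filtering** (`icu_intensity.filters`) — inclusion of stays
  with a unique medical-ICU stay, known SAPS II and age-adjusted
  SAPS II > 15, with per-reason flowchart accounting.
* **Stratified analysis** (`icu_intensity.analysis`) — intensity × age
  contingency tables, mortality per age × intensity stratum, and the
  standardized mortality ratio SMR = observed/expected deaths (expected
  = Σ per-stay predicted mortality) with exact Poisson 95 % intervals,
  plus chi-square, Kruskal–Wallis and ANOVA helpers and an SMR-vs-age
  trend fit.
* **Synthetic cohorts** (`icu_intensity.simulate`) — a generator with a
  known ground truth: hospital death is Bernoulli with
  `p = min(1, m_stratum · p_SAPS2)`, so each (age band × intensity
  group) stratum's SMR equals its configured multiplier in expectation.
  Used throughout the test suite for parameter-recovery checks.

## Worked example

```python
from icu_intensity import (SimulationConfig, generate_cohort, score_frame,
                           classify_frame, apply_inclusion, run_full_analysis)

cohort = generate_cohort(SimulationConfig(n_stays=10_000))
included, flowchart = apply_inclusion(classify_frame(score_frame(cohort)))
print(flowchart)
report = run_full_analysis(included)
print(f"n={report.n_stays} deaths={report.n_deaths} "
      f"mortality={report.hospital_mortality_pct}%")
t = report.mortality_table
print(t[t.age_label == "All ages"]
      [["intensity_group", "n", "observed_deaths", "mortality_pct", "smr"]]
      .to_string(index=False))
```

prints

```
FlowchartCounts(n_input=10000, n_excluded_non_medical_icu=467,
    n_excluded_multiple_icu=1690, n_excluded_unknown_saps2=249,
    n_excluded_low_severity=1113, n_included=6481)
n=6481 deaths=2832 mortality=43.7%
 intensity_group    n  observed_deaths  mortality_pct      smr
               0 1895              465           24.5 1.025153
               1  550              201           36.5 0.958350
               2 1850              737           39.8 1.023793
               3 2186             1429           65.4 1.003246
```

Of 10,000 simulated stays, 6481 pass the inclusion rules (the others are
non-medical-ICU, multiple-ICU, unknown-SAPS II or low-severity stays).
Mortality rises steeply with treatment intensity, while the SMR in every
group is ≈ 1: the default generator applies no stratum multiplier, so
observed deaths match what severity predicts — exactly the calibration
the SMR is designed to detect departures from.

The same pipeline runs from a shell:

```bash
icu-intensity run --out-dir out/ --seed 42 --n 10000
icu-intensity analyze --fixture paper --out-dir tables/   # printed-counts fixture
```

`--fixture paper` analyzes the built-in stratum counts of the reference
study (n = 23,578 medical-ICU stays) and reproduces its printed
percentage tables from their integer numerators and denominators.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the whole chain — synthetic-cohort generation at the given seed,
scoring, classification, filtering, stratified analysis — plus the
reference-counts fixture path, and writes the JSON report to `--out`.

## Documentation

`docs/methods.md` describes the scoring tables, the classification
rules, the synthetic-data model with its defaults and limitations, and
the numerical conventions (rounding, confidence intervals, exclusion
precedence).
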
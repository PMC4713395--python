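# Methods

## Scope and data model

The package analyzes administrative hospital-stay records of adult ICU
patients: one row per hospital stay, with demographics, the scoreable
(worst-of-first-24 h) SAPS II physiology, stay-level organ-support
summaries (agent and maximum catecholamine dose, ventilation mode with
maximum FiO2/PEEP, renal replacement flag) and hospital vital status.
No timeline exists within a stay; every rule below therefore operates on
stay-level maxima. Age at ICU admission is the only age available and is
used everywhere.

## SAPS II scoring

The component weight table and the logistic mortality conversion are the
original 1993 definitions, frozen in `saps2.py` as one constant table
and pinned by checksum tests (component-weight sum 322, maximal score
163) so silent edits fail. Conventions:

* All bands are left-closed, right-open, except the terminal open bands
  (e.g. ages [40,60), …, [80,∞)). This matches the band labels
  "40–59 … ≥80" and places an 80-year-old in the upper band.
* The oxygenation (PaO2/FiO2) component is defined only on mechanical
  ventilation or CPAP; a null value contributes 0 points, and a supplied
  value with an explicit `ventilated=False` flag is rejected.
* The age-adjusted score is total − age points. It is used as the
  age-independent severity index and as the inclusion threshold; the
  *full* score feeds the mortality prediction and therefore the SMR
  denominators (age-adjusting the expected deaths would remove exactly
  the age effect under study).
* Missing physiology is never imputed: the stay is flagged
  `saps2_unknown` and excluded by the cohort filter.

## Treatment-intensity indicator

Two levels per organ, three organs, summed as low = 1 / high = 2 points;
the group is `min(points, 3)`. "More intense support" (group 3) is
formalized as points ≥ 3 — the unique monotone extension of the defined
groups (0 points → group 0, 1 → 1, 2 → 2). Per organ the maximum level
attained during the stay counts; when both noninvasive and invasive
ventilation occurred, the invasive settings decide the level.

The dobutamine/dopamine boundary is ≤ 8 µg/kg/min = low-intense: the
operational (tabular) definition of the indicator uses "≤ 8" although the
accompanying prose says "less than 8"; the tabular convention is adopted
here and exactly-8 doses are generated and tested. Epinephrine and
norepinephrine are high-intense at any dose. CPAP counts as respiratory
support only when coded as noninvasive ventilation.

## Cohort filter

Included: medical ICU, exactly one ICU stay in the hospital stay, known
SAPS II, age-adjusted SAPS II strictly > 15 (the French threshold
separating intensive from intermediate care). A stay failing several
criteria is counted once, in the fixed precedence order non-medical →
multiple stays → unknown SAPS II → low severity. The order is a package
convention (the source material does not state one); it affects only the
per-reason flowchart counts, never the included set. The filter is
idempotent and partitions its input.

## Stratified analysis

* Age is analyzed three ways: continuous, the six SAPS II bands, and the
  <80 / ≥80 dichotomy.
* SMR = observed deaths / expected deaths per stratum, expected being
  the sum of per-stay predicted mortalities. The 95 % interval is the
  exact (Garwood) Poisson interval on the observed count with expected
  treated as fixed — a deliberate design choice, since no interval
  method is prescribed by the reference analysis; it is conservative and
  exact at small counts, where SMR curves are otherwise over-read.
* Chi-square is Pearson's statistic without continuity correction (all
  intended tables are large-sample); Kruskal–Wallis uses the standard
  tie correction with the all-identical degenerate case mapped to
  H = 0, p = 1; ANOVA is the ordinary one-way F test. All three wrap
  scipy.stats and are cross-checked in the tests against hand-written
  closed-form oracles.
* Displayed percentages are rounded half away from zero to one decimal,
  matching the reference tables' display convention.
* The SMR-vs-age trend per intensity group is a weighted least-squares
  line over the six band indices with inverse-variance weights
  (Var(SMR) ≈ O/E² per band); its 95 % slope interval is the flatness
  criterion ("no age trend" ⇔ CI covers 0).

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, with a
closed-form ground truth; it does not attempt the real joint
distribution of any hospital system.

* **Age**: truncated normal mixture, components N(40, 12²), N(63, 10²),
  N(84, 5.5²) with weights 0.35/0.49/0.16 on [16, 105] — mean ≈ 58.3 y,
  SD ≈ 18.4 y, ≈ 14 % aged ≥ 80, emulating a large adult medical-ICU
  case mix.
* **Severity**: one standard-normal latent per stay with a small age
  loading (0.15 per age-SD), so age-adjusted severity rises slightly
  with age. Physiology fields are monotone linear (bilirubin:
  log-linear) deformations of the latent plus independent noise, each
  field sharing loading 0.7 with the latent, clipped to physiologic
  bounds. The deformation scales were calibrated once so the *included*
  cohort's age-adjusted SAPS II has mean ≈ 41 and SD ≈ 21 — the severity
  of a real medical-ICU population above the inclusion threshold — and
  then frozen.
* **Supports**: each channel (invasive ventilation, NIV, catecholamine,
  renal replacement) is Bernoulli with logistic-in-latent probability,
  inducing the severity–intensity correlation. Doses, FiO2 and PEEP are
  drawn on both sides of every classification threshold and land exactly
  on 8 µg/kg/min, 0.6 and 6 cm H2O with small probability, so boundary
  behavior is always exercised.
* **Mortality**: Bernoulli with `p = min(1, m_stratum · p_SAPS2)`,
  strata assigned by the same scoring/classification/banding code the
  analysis uses. With all multipliers 1 (the default) the cohort is
  perfectly calibrated: observed deaths match expected deaths in every
  stratum up to binomial noise. The **clamp matters**: with a severe
  case mix, multipliers ≥ ~1.5 saturate `m·p` at 1 for the sickest
  stays, so the exact ground-truth SMR of a stratum is
  `Σ min(1, m·p_i) / Σ p_i ≤ m`, with equality only when no stay clamps.
  Recovery tests compare estimates against this exact expectation — the
  true known parameter of the generated world — not against the nominal
  multiplier.
* **Plumbing fractions**: 17.6 % of stays get multiple ICU stays
  (matching the reference exclusion rate 6346/36,002), 5 % a
  non-medical ICU and 3 % unknown SAPS II. The unknown-SAPS II and
  non-medical rates are not published anywhere; they are fixed
  convenience values whose only purpose is to exercise every exclusion
  branch. Deaths are drawn *before* physiology is nulled, so missingness
  is non-informative by construction.
* **Determinism**: all randomness flows from one
  `numpy.random.default_rng(seed)`; identical configurations give
  bit-identical cohorts (default seed 20060101).

What a green synthetic test does **not** establish: agreement with any
real hospital system's case mix, coding behavior (e.g. threshold-chasing
"FiO2 61 %" upcoding), informative missingness, within-stay treatment
timelines, or inter-hospital variation — none of which the generator
models.

## Reference-counts fixture

The printed stratum counts of the reference study (stays and deaths per
age band × intensity group, n = 23,578) are embedded as a fixture; the
table builders reproduce every printed percentage from these integers
after 1-decimal rounding. One printed inconsistency is carried as such:
the <80 group-0 count appears as 6624 in the binary table, but the band
sums give 6224, and only 6224 is consistent with the printed 30.5 % and
8.2 % figures; the fixture uses 6224. Other published-prose
inconsistencies (a 14.6 % share whose count/total gives 12.6 %) are
outside the fixture's scope and are not "fixed".

## Known limitations

* The SAPS II logistic is the 1993 fit; it is known to over-predict in
  modern cohorts and is deliberately not recalibrated, so absolute SMRs
  below 1 are expected on contemporary-like data.
* SMR intervals treat expected deaths as fixed, ignoring the (small)
  sampling variability of the severity model itself.
* The intensity indicator has no dose threshold for epinephrine or
  norepinephrine and does not grade renal support by modality — by
  design of the indicator, not of this implementation.
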
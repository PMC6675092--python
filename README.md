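# pulmhet

Growth-rate heterogeneity analysis of multiple pulmonary metastatic nodules
from longitudinal CT measurements.

## The problem

When a patient has many lung metastases, RECIST 1.1 tracks at most two
target lesions per organ. If the nodules grow at different rates — one
phenotypic signature of spatial tumor heterogeneity — two lesions cannot
represent the whole burden, and a fast-growing "outlier" nodule can be
missed entirely. `pulmhet` implements the full analysis chain for
two-visit CT measurements of every countable nodule (3D maximum diameter
in cm, volume in cm³):

- **Change metrics** — per-nodule rate of change
  `100 · (visit2 − visit1) / visit1` (%), for either metric.
- **Response assessment** — RECIST 1.1 categories from the change rate of
  the *sums* of target-lesion values, under both the linear thresholds
  (PD > +20 %, PR < −30 %) and their volumetric equivalents
  (PD > +73 %, PR < −66 %), for the two largest nodules or all of them.
- **Outlier nodules** — growth beyond 1.5× linear scale between scans:
  change ratio > 0.5 for diameter, > 1.5³ − 1 = 2.375 for volume.
- **Minimum combination t-test** — the heterogeneity statistic: split a
  patient's n nodules into two groups of ⌊n/2⌋ and ⌈n/2⌉ in every possible
  way (complement-equivalent splits counted once; capped at 4,000 splits by
  uniform seeded sampling), run a two-sample t-test of H₀: μ₁ = μ₂ on each
  split's change rates, and reject homogeneity when the minimum p-value
  falls below α = 0.05. min(min(p)) over both metrics gives the overall
  per-patient verdict. Note this statistic is deliberately uncorrected for
  multiplicity and therefore anti-conservative; `pulmhet.calibration`
  measures by how much (see `docs/methods.md`).
- **Agreement analyses** — paired t-tests and Bland–Altman limits of
  agreement (mean difference ± 1.96 SD) between selection modes and between
  metrics.
- **Synthetic cohorts** — a seeded generator of study-shaped cohorts
  (log-normal baseline diameters, cube-law volumes, homogeneous or
  two-subgroup growth, multiplicative measurement noise) with ground truth,
  so every stage is testable without imaging data.

## Worked example

```python
import math
from pulmhet import (NoduleMeasurement, PatientSeries, Metric, SelectionMode,
                     assess, assess_heterogeneity, detect_outliers)

mk = lambda i, d1, d2: NoduleMeasurement(i, d1, d2, math.pi/6*d1**3, math.pi/6*d2**3)
patient = PatientSeries("pt-4", interval_days=53, nodules=tuple(
    mk(*n) for n in [("n1", 1.8, 1.0), ("n2", 1.4, 1.1), ("n3", 1.2, 1.2),
                     ("n4", 1.1, 1.2), ("n5", 0.8, 0.9), ("n6", 0.7, 1.2),
                     ("n7", 0.4, 0.4), ("n8", 0.3, 0.3)]))

two = assess(patient, Metric.DIAMETER, SelectionMode.TWO_LARGEST)
alln = assess(patient, Metric.DIAMETER, SelectionMode.ALL)
print(f"two largest: {two.sum_v1:.1f} -> {two.sum_v2:.1f} cm, "
      f"{two.change_percent:+.1f}% => {two.category.value}")
print(f"all nodules: {alln.sum_v1:.1f} -> {alln.sum_v2:.1f} cm, "
      f"{alln.change_percent:+.1f}% => {alln.category.value}")
out = detect_outliers(patient, Metric.DIAMETER)
print(f"outliers (diameter ratio > {out.criterion}): {out.outlier_nodule_ids}")
het = assess_heterogeneity(patient, seed=1)
print(f"min p: diameter {het.min_p_diameter:.4f}, volume {het.min_p_volume:.4f} "
      f"-> min(min(p)) = {het.min_min_p:.4f}, heterogeneous: {het.heterogeneous}")
```

prints

```
two largest: 3.2 -> 2.1 cm, -34.4% => PR
all nodules: 7.7 -> 7.3 cm, -5.2% => SD
outliers (diameter ratio > 0.5): ('n6',)
min p: diameter 0.0868, volume 0.1686 -> min(min(p)) = 0.0868, heterogeneous: False
```

The two-largest assessment calls this patient a partial responder while the
all-nodule assessment calls the disease stable — the discordance the
analysis is about — and one small nodule grew more than 1.5× in diameter
while the targets shrank. With only 8 nodules the combination test does not
reach significance here.

The same stages run from the shell on any measurement table
(`patient_id,nodule_id,diameter_v1_cm,diameter_v2_cm,volume_v1_cm3,volume_v2_cm3,interval_days`):

```sh
pulmhet simulate --seed 3 --n-patients 4 --out cohort.csv --truth-out truth.csv
pulmhet run --input cohort.csv --output-dir reports/ --seed 1
```

which writes the response, outlier, heterogeneity and agreement reports
plus a YAML manifest.

## The study analysis

The numbered drivers under `analysis/` rerun the cohort analyses on the
packaged study tables (10 patients, 155 nodules) and on synthetic cohorts:

1. `01_reproduce_response_tables.py` — recomputes every change-rate cell and
   RECIST category from the printed sums (10 manual + 40 volumetry cells).
2. `02_agreement_contrasts.py` — the four paired contrasts; reproduces
   p = 0.013 / 0.464 / 0.164 / 0.070 and all four limit-of-agreement pairs.
3. `03_heterogeneity_verdicts.py` — the min(min(p)) < 0.05 rule on the
   per-patient minimum p-values; flags patients 5–10.
4. `04_synthetic_pipeline.py` — full pipeline on a half-homogeneous,
   half-two-subgroup synthetic cohort.
5. `05_operating_characteristics.py` — null rejection rate of the minimum-p
   statistic versus nodule count, and detection power on separated
   two-subgroup patients.

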
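# Methods

## Measurements and change metrics

Each nodule carries four numbers: 3D maximum diameter (cm) and volume (cm³)
at two CT visits separated by a known interval (days). Baselines must be
strictly positive; follow-up values may be exactly zero, encoding lesion
disappearance (a −100 % change) so that the complete-response rule at the
patient level is reachable. The elementary statistic everywhere is the
rate of change, `100 · (v2 − v1) / v1` %, or equivalently the change ratio
`(v2 − v1) / v1`. Internally values are kept at full precision; report
writers round rates to 1 decimal and p-values to 4 decimals, the precision
of the tables the analysis reproduces.

Under an exact cube law `v = k·d³` the volume change ratio is
`(1 + r)³ − 1` for diameter ratio `r`; this identity links the linear and
volumetric thresholds below and is used as a cross-metric consistency check
throughout the tests.

## Response assessment

Targets are either the two nodules with the largest baseline value of the
metric under assessment, or all nodules; ties are broken by ascending
nodule id so selection is deterministic. Whether the volumetric "two
largest" should be ranked by volume or by diameter is not decidable from
the source tables (in the study cohort both rankings give the same printed
sums, which are patient-level inputs here); ranking by the assessed metric
is the default and `select_by=diameter` is available.

The change rate is computed on the sums of the target values, never as a
mean of per-nodule rates, and classified: PD above +20 %, PR below −30 %
for diameter; PD above +73 %, PR below −66 % for volume; CR when every
target's follow-up value is exactly zero. Boundaries are exclusive
("more than"): exactly +20 / −30 / +73 / −66 % is SD. RECIST's 5-mm
absolute-increase requirement and new-lesion rules are out of scope — only
the percentage thresholds are applied, matching the analysis this package
implements.

## Outlier nodules

A nodule is an outlier on a metric when its change ratio strictly exceeds
0.5 (diameter) or 1.5³ − 1 = 2.375 (volume): growth beyond 1.5× linear
scale. Exactly-1.5× growth does not flag, and shrinkage never flags. Under
an exact cube law the two flags coincide nodule by nodule; with measurement
noise they can disagree, which is itself informative.

## The minimum combination t-test

Per patient and metric, the n per-nodule change rates are split into two
groups of ⌊n/2⌋ and ⌈n/2⌉ in every possible way. A split and its complement
give the same two-sided test, so for even n complements are deduplicated
(C(n, n/2)/2 distinct splits; for odd n the count is C(n, ⌊n/2⌋), e.g.
300,540,195 for n = 31). At least 4 nodules are required — smaller inputs
are a hard error, not a silent skip. When the count exceeds the cap
(default 4,000) a uniform random sample of `cap` distinct splits is drawn
under an explicit seed; sampling can only raise the minimum p, never lower
it, and both the cap and the sampling seed are exposed configuration.

Each split gets a two-sample t-test of equal group means. Pooled-variance
Student's t is the default, Welch is a flag; the choice is a genuine
fidelity uncertainty of the procedure being reimplemented, so both are
exposed and the tests pin each variant to an independent scipy oracle. The
statistic is made total by two degenerate conventions, logged when
triggered: both group variances zero with equal means → p = 1; with
unequal means → p = 0 (perfect separation). "Zero" and "equal" are judged
at relative tolerance 1e-12 of the data scale; computed group variances
are clipped at zero against cancellation error. Both metrics of a patient
are evaluated over the same split set, and the overall verdict is
min(min(p)) < α with α = 0.05.

The implementation evaluates all splits at once: group sums and sums of
squares over a partition index matrix give every split's t in a handful of
vectorized operations. For n ≤ 10 the result is tested to agree exactly
with an exhaustive `itertools` + `scipy.stats.ttest_ind` brute force.

**The statistic is anti-conservative by design.** The minimum over
thousands of correlated tests is compared to the nominal α with no
multiplicity correction — faithfully to the procedure, which interprets
any sub-α split as evidence of heterogeneity. The calibration harness
(`pulmhet.calibration`, driver `05`) measures the consequence: the null
rejection rate on homogeneous synthetic patients is far above 0.05 already
at 6 nodules and approaches 1 as the nodule count grows. A heterogeneity
"Yes" should therefore be read as "some balanced split separates", not as
a calibrated 5 % false-positive decision; the per-patient minimum p-values
are comparable between patients with similar n only.

## Agreement analyses

Four paired contrasts of per-patient change rates: two-largest vs all
nodules on each metric, and diameter vs volume under each selection mode.
Each gets a paired t-test (two-sided, n − 1 df) and Bland–Altman limits of
agreement, mean difference ± 1.96 × sample SD (ddof = 1). Differences are
oriented second − first with first = two-largest (resp. diameter); the
orientation is not fixed by the procedure itself and was chosen as the one
that reproduces the published limits — verified empirically, and the swap
property (negated mean and t, mirrored limits, unchanged p) is tested.
When the study tables are the input, the contrasts use the table-precision
(1-decimal) change rates, since those are what the published limits derive
from; full-precision rates shift the limits by a few hundredths.

## Synthetic cohorts

The generator emulates the measured structure of the study cohort, not its
images: per patient, a nodule count uniform on [4, 52], an interval uniform
on [32, 151] days, baseline diameters log-normal (default median 1.0 cm,
log-SD 0.5 — two-largest diameter sums then span roughly 1.5–8 cm), and
true volume (π/6)·d³ times a per-nodule persistent log-normal shape factor
(default σ = 0.15) acknowledging non-spherical lesions. Growth acts on the
diameter — rates drawn from one normal component (homogeneous, default
mean 0 %, SD 10 %: a stable-disease cohort) or a two-component mixture
(heterogeneous; second component displaced by 30 % by default) — and
propagates to the volume through the cube, so dual-metric consistency is
exact before noise. The displaced component receives exactly
round(n · fraction) nodules at shuffled positions, so subgroup sizes are
controlled by configuration rather than binomially random; power
statements at "≥ 4 nodules per subgroup" are then conditions one can set,
not events one hopes for. Rate draws below −95 % are truncated there to
keep measurements positive, and truncations are counted in the truth
table. Measurement error is multiplicative mean-one log-normal noise with
coefficient of variation `measurement_cv` (default 0.05), independent per
visit and per metric, keeping all outputs strictly positive for any valid
configuration.

What the generator does **not** emulate: segmentation error structure
beyond a homogeneous multiplicative cv (real volumetry error grows sharply
for small nodules), correlation of growth with nodule size or location,
inter-reader variability, and new or vanishing lesions between visits.
Passing simulation tests therefore demonstrate the statistical machinery
under the stated model, not robustness to real CT measurement pathology.

## Simulation sizes

The operating-characteristic experiments use single-patient replicates at
fixed nodule counts: detection power on two-subgroup patients with 6 + 6
nodules, subgroup means 3 within-group SDs apart (Δ = 30 %, SD = 10 %) and
2 % measurement noise, 500 replicates; null rejection rates at 6–16
nodules, 300–400 replicates each. These sizes give Monte-Carlo standard
errors around 1–2 percentage points, adequate for the ≥ 95 % power check
and for the shape of the null curve.

## Known limitations

- Per-nodule raw change rates of the study cohort are unpublished, so the
  published per-patient minimum p-values cannot be recomputed; the package
  reproduces the decision rule on them and validates the statistic itself
  on synthetic data and against the exhaustive oracle.
- One printed fixture row (patient 8) has a two-largest volume sum
  exceeding its all-nodule sum; the fixture carries the values verbatim and
  no cross-row consistency is asserted for it.
- The pipeline handles exactly two visits; multi-timepoint tracking,
  non-target lesions and cross-organ response integration are out of scope.
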
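# Methods

## The model

`foodspan` treats a sustained diet change as a condition that multiplies
all-cause mortality. Remaining life expectancy (LE) at age `x0` under
diet `D` is computed from a period life table whose age-specific rates
are scaled by the hazard ratio of the change; the reported quantity is
`LE_x0(D) - LE_x0(D0)`, life-years gained (or lost), always conditional
on survival to `x0`.

### Life table

Rates arrive in age bands (typically 5-year groups ending in an open
interval, as in GBD-style extracts) and are expanded to single-year ages
piecewise-constantly: each age receives its band's rate unchanged. This
is the minimal assumption; no graduation or smoothing is applied, so
band-averaging the expanded schedule recovers the band rates identically.

Conversion from a central rate `m` to an annual death probability uses
the uniform-deaths assumption, `q = m/(1 + 0.5 m)` (capped at 1), deaths
credit half a year, and the table closes at age 110 with an open interval
contributing `l/m` person-years (constant-hazard tail). These are the
standard period-life-table conventions; note the useful identity
`(1 - 0.5 q)/q = 1/m` under this conversion, which makes the constant-rate
table exact at any closure age — the basis of the engine's sharpest
correctness test (closed form reproduced to better than 1e-9).

Real national life tables (e.g. GBD's own) differ in their `a_x`
separation factors, infant-mortality handling and closure; reproducing a
specific published baseline LE to the decimal is therefore a calibration
exercise against that producer's conventions, not something the engine
guarantees.

### Dose-response hazard ratios

Each food group's curve tabulates HR against intake (g/day) with 95% CI
bands. Evaluation is linear in HR between points and flat beyond the
first/last dose — the plateau reading: optimized intakes sit where the
mortality response flattens, so no benefit or harm is extrapolated past
the tabulated range. Because changes use the ratio `HR(to)/HR(from)`, the
meta-analysis's reference category cancels; curves may be stored against
any reference. Adding a collinear point never changes a result.

Groups combine multiplicatively (independent risk factors). This mirrors
how the underlying meta-analyses adjust for other food groups; the
sensitivity family below is the instrument for doubting it.

### Time to full effect

Cardiovascular risk reverses within years; cancer risk over decades. The
default compromise is T = 10 years with a linear ramp (20% of the full
effect after 2 years), applied to the *combined* multiplier on the HR
scale: `mult(t) = 1 + min(t/T, 1)(HR_full - 1)`. Ramping per-group and
then multiplying is a mathematically different (and less transparent)
choice and is not used. The ramp is sampled at the midpoint of each model
year (`t = a - x0 + 0.5`) to minimise discretisation bias and make
results bit-reproducible; T ∈ {5, 30, 50} are provided as sensitivity
settings (`--horizons`).

### Uncertainty interval

200 replicates (default, `n_draws`), fixed seed. Per replicate and per
food group one uniform deviate `u` places the whole curve between its
bands, `lo + u (hi - lo)` pointwise — group-level, not point-level,
perturbation, preserving within-curve shape. Draws are independent across
groups and replicates (no correlation structure is claimed by the
sources). The 95% UI is the 2.5/97.5 percentile of replicate gains,
computed with numpy's linear interpolation between order statistics; the
percentile method, the PCG64 generator and the default seed (20190101)
are all part of the reproducibility contract — the same seed yields
byte-identical reports. Per-group intervals redraw only the focal group,
holding the others central, matching forest-plot semantics. Mortality-rate
uncertainty is out of scope.

### Sensitivity family

`HRa = HR0 + (1 - HR0)(1 - m)` for `HR0 <= 1`; for `HR0 > 1` the formula
is applied to `1/HR0` and inverted. `m = 1` is the central model, `m =
0.5` halves every effect's distance from the null (overlap between
adjusted food groups), `m = 1.5` amplifies it (over-adjustment toward the
null in the sources). The construction gives exact reciprocal symmetry,
`HRa(h, m) * HRa(1/h, m) = 1`, so protective and harmful effects attenuate
alike. The reported sensitivity interval is the gain recomputed with all
non-neutral curves adjusted at m = 0.5 and m = 1.5.

### Energy gate and evidence score

Diets totalling under 4,000 or over 16,000 kJ/day are refused — the
calculator reports nothing rather than extrapolate to starvation or
implausible intakes. Boundaries are strict ("below"/"above"), so exactly
4,000 or 16,000 passes; the gate applies to both the baseline and the
target diet. Energy-restriction effects on longevity are deliberately not
modelled.

The per-scenario NutriGrade score is the mean of per-group scores
weighted by each group's absolute single-group LE contribution
(`sum s_g |dLE_g| / sum |dLE_g|`); categories: very low [0, 4), low
[4, 6), moderate [6, 8), high [8, 10], boundaries belonging to the upper
class. Which stratum's contributions should weight a single published
overall score is ambiguous, so the tool reports the score per scenario.
Neutral groups carry zero weight.

## Presets

TW/FA/OD intakes are fixed verbatim from the published list; FA is the
per-group arithmetic midpoint of TW and OD for every group. One source
inconsistency exists for fish (125 g in the diet list, 100 g in a table
footnote); the midpoint construction (125 g) is taken as canonical.

## Synthetic defaults — what they are and are not

The package must run with no downloads, so it bundles:

* **Mortality**: Gompertz-Makeham hazards `c + a e^{bx}` per sex
  (male c = 6e-4, a = 2.8e-5, b = 0.095; female c = 4e-4, a = 1.35e-5,
  b = 0.101; closure 110). Chosen so a 20-year-old's remaining LE is
  ~59/62 years, the realistic adult regime. They reproduce the *shape*
  of adult mortality, not any country's level, cohort effects, or
  young-age excess mortality.
* **HR curves**: piecewise-linear from (0, HR 1) to a plateau with
  symmetric CI bands shrinking toward the null end. Plateau values
  (e.g. whole grains 0.82, red meat 1.14) are plausible placeholders,
  **not** transcriptions of any meta-analysis. Consequently the gains the
  defaults produce characterise the engine, not any population.
* **Energy densities** (kJ/g): seeded from typical food-composition
  values, then least-squares calibrated (minimal relative adjustment) so
  the preset totals equal the published 8,085/7,615 kJ/day figures.
* **NutriGrade scores** are the published per-group values (whole grains
  8 … white meat 2) and ship as real metadata, with a nominal 5.0 for
  added oils, whose weight is always zero.

Passing tests on these fixtures demonstrates the engine's arithmetic,
monotonicity, reproducibility and oracle agreement; they say nothing
about any real population until real rate and HR tables are supplied.

## Verification strategy

* Constant-hazard closed form `(1 - 0.5q)/q`, exact by construction.
* A brute-force plain-Python life table, written independently in the
  test suite, must match the engine's gains to 1e-9 on instant-effect and
  ramped scenarios.
* A 200,000-lifetime cohort simulation (year-by-year Bernoulli deaths,
  half-year death credit, exponential terminal tail) must agree with the
  analytic LE within 3 standard errors on every default fixture — the
  repository's strongest end-to-end guarantee.
* The 200-draw UI must match a 10,000-draw recomputation within the
  order-statistic Monte-Carlo tolerance.
* Property tests (hypothesis, seeded): HR ratio symmetry, collinear-point
  invariance, `adjust_hr` identity/symmetry/monotonicity, energy-gate
  monotonicity, weighted-score bounds and scale invariance.

## Numerical choices and degenerate inputs

Double precision throughout; presentation rounds to 0.1 years, machine
output never rounds. `q` is capped at 1 (a rate of 1e12 means certain
death, LE = 0.5). Zero rates are allowed except in the terminal interval
(LE would diverge). Negative doses, non-positive multipliers, gapped or
overlapping age bands, out-of-range m, and all-zero quality weights raise
named errors. Problem sizes are small — 111 ages, 14 groups, 200 draws —
so the full default test suite and the acceptance script each run in
seconds.

## Known limitations

No morbidity or quality-of-life modelling; no nutrient-level or
substitution effects beyond independent multiplicative groups; HRs are
age-constant; no cohort projection (period rates from a single year); no
correlated uncertainty across food groups; no mortality-rate uncertainty.
The per-group forest rows change one group against the full baseline, so
they do not sum exactly to the joint total (non-additivity is surfaced,
not hidden).
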
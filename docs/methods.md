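# Methods

## The model

`oralrisk` implements the standard US EPA chain for chronic oral exposure of
children to metal(loid)s — Mn, Pb, Cr, Cd and As — through three ingestion
pathways (food, drinking water, incidental soil ingestion):

```
ADD = C · IngR · EF · ED / (BW · AT) · k        [mg · kg⁻¹ · day⁻¹]
HQ  = ADD / RfD
HI  = Σ_pathways HQ          (one substance)
HIt = Σ_substances HI
```

with the non-carcinogenic convention `AT = ED × 365` days and `EF = 365`
days/year, so the time factor is exactly 1 and the dose reduces to
`C · IngR · k / BW`.  `k` is the pathway-owned unit conversion to mg/day of
ingested metal:

| pathway | concentration | intake | k |
|---|---|---|---|
| soil  | mg/kg | mg/day | 10⁻⁶ |
| food  | mg/kg | g/day  | 10⁻³ |
| water | ng/mL (≡ µg/L) | mL/day | 10⁻⁶ |

The single 10⁻⁶ that risk formulas conventionally print is a soil-specific
convention; making each pathway own its conversion keeps the three media
dimensionally honest and is unit-tested independently.

Oral reference doses (mg·kg⁻¹·day⁻¹) ship as an editable CSV: Mn 0.14,
Pb 0.0014 and As 0.0003 for all pathways; Cr 1.5 (food, soil) and 3 (water);
Cd 0.001 (food, soil) and 0.0005 (water).  HQ (or HI) ≤ 1 is read as no
appreciable non-carcinogenic concern.

Cohort reporting is **percentile-after-sum**: per-child HQs are summed into
per-child HI/HIt first and percentiles (5/50/95, linear interpolation
between closest ranks) are taken across children second.  Summing cohort
percentiles instead would overstate the extremes; the two orderings are
tested against brute-force enumeration on small cohorts.  Presentation
rounding is 2 significant figures, half away from zero; raw doubles are
retained in every output.

## Distribution fitting

Published summaries (quartiles for concentrations, median/mean pairs for
exposure factors) are turned into sampling distributions.  The default
family is the lognormal — nonnegative, right-skewed, the conventional model
for environmental exposure variables.

* **From quartiles** (P25, median, P75): log-median = ln(median); log-sd =
  mean{ln(median/P25), ln(P75/median)} / 0.6745.  The median is honoured
  exactly; an asymmetric spread is averaged.  Three constraints against two
  parameters means asymmetric rows cannot have both printed quartiles
  reproduced: the fitted quartile deviates by exp(|s_hi − s_lo|/2) per side,
  which is < 12% for 12 of the 15 shipped concentration rows but
  irreducibly ~94% for the strongly asymmetric diet-Cd row
  (0.001/0.007/0.013 mg/kg) and ~12–14% for diet As and water As.  A
  least-squares variant (`method="lsq"`, which gives up median exactness)
  is available.  Equal quartiles (the water-Cd row) collapse to a point
  mass.
* **From median/mean**: log-median = ln(median), log-variance =
  2·ln(mean/median), which reproduces the arithmetic mean exactly.  When
  the printed mean is *below* the median (left skew, impossible for a
  lognormal — four of the twelve factor rows), the fit falls back to a
  normal centred on the mean with sd = mean·√(2·ln(median/mean)), the
  mirror image of the lognormal spread-from-skew relation, truncated at
  zero, with a logged warning.  sd = |mean − median| alone would imply
  implausibly tight spreads (e.g. 4 mg/day for soil ingestion).

Sampling uses `numpy.random.default_rng` with rejection against the
truncation bounds; body weight is additionally truncated to [8, 80] kg.

## Synthetic cohort

The generator emulates a 60-child field cohort: 30 children aged 3–6 and 30
aged 7–12.  Exposure factors come from age-group-specific fits (3–6: BW
median 17 kg, food 513 g/day, soil 40 mg/day, water 953 mL/day; 7–12: BW 32
kg, food 612 g/day, soil 66 mg/day, water 1238 mL/day); concentrations come
from the pooled quartile fits, identical across groups except for two
documented age effects:

* **Diet Pb and Cr are higher in the younger group.**  Group multipliers on
  the concentration draws default to 1.85 (ages 3–6) and 1/1.85 (ages
  7–12).  Being symmetric on the log scale they preserve the pooled median
  exactly, and the log-separation ln(1.85²) ≈ 1.23 against the diet-Pb
  log-sd of 1.36 gives a two-sided Mann–Whitney test at n = 30 per group
  ≈ 90% power at α = 0.05 — "significant in most realisations", matching
  the qualitative field finding.  A smaller separation (e.g. 1.6 vs 0.7)
  leaves the Pb comparison under 70% power and would make the documented
  age effect a coin flip.
* **Soil ingestion is higher in the older group**, which follows directly
  from the group factor fits (66 vs 40 mg/day medians).

Diet As carries a 10% per-child nondetect probability (the published cohort
5th-percentile diet-As HQ is exactly 0, implying zeros in the distribution);
nondetects substitute zero by default (configurable: zero / half-LOD / LOD,
LOD defaulting to 0.002 mg/kg, the low end of the stated analytical
detection limits).  An optional shared-site mode lets all children of a
group share one soil draw; it is off by default because the emulated survey
sampled soil per child.

Everything is reproducible from the config seed; config and cohort
round-trip losslessly through JSON/CSV.

**What the generator does not emulate.**  Inputs are drawn independently
per child: there are no BW–intake correlations, no household or school
clustering (unless shared-site soil is enabled), and no within-child
correlation across metals or media, because the published summaries carry
no joint information.  Consequently cohort-level extreme percentiles
(P95 of heavy-tailed cells such as diet Pb) are wider than a real cohort's,
and cohort-cell agreement with the published percentile grid is checked
only directionally, never cell-exact.  The published grid itself contains
cells inconsistent with its own marginal concentration table (its diet-As
median HQ is ~20× below what the printed diet-As median implies), which
only per-child raw data could explain.  Passing tests therefore demonstrate
calibration to the printed marginals and the documented age effects, not
per-child realism.

Calibration recovery is assessed on medians aggregated over seeds (or large
n): a single 60-child cohort's pooled median of a log-sd ≈ 1.9 variable
(diet Cd) carries ~30% sampling error by itself.  One structural caveat:
the printed group soil-ingestion medians (40 and 66 mg/day) cannot pool to
the printed whole-cohort median of 41 under any overlapping two-component
mixture centred on them; the generator calibrates to the group columns,
leaving the pooled soil-ingestion median ~15% high by construction.

## Monte Carlo propagation

`run_mc` draws C, IngR and BW independently per iteration (default 10,000),
pushes them through the dose chain and summarises mean, median, percentiles
1/5/25/50/75/95/99, the empirical CDF and P(HQ > 1).  Plain independent
sampling is deliberate — no antithetic or Latin-hypercube variance
reduction — to mirror how spreadsheet risk tools sample.  Which inputs are
randomised is configurable (`freeze`); the default randomises all three.
The default Pb-via-soil spec centres IngR and BW on the whole-cohort
("Average") rows — median 41 / mean 51 mg/day and median 25 / mean 27 kg —
the combination consistent with the deterministic point value 9.9 × 10⁻².

The module's primary oracle is the closed-form product moment for
all-lognormal inputs, E[HQ] = E[C]·E[IngR]·E[1/BW]·k/RfD with
E[1/BW] = exp(−µ + σ²/2); the MC mean must land within 3 standard errors.
Convergence checks reuse nested prefixes of a single draw stream, so
successive medians are positively correlated and their relative change
(< 2% from 5,000 to 10,000 iterations) measures stabilisation rather than
independent-run noise.  Scale equivariance (doubling the concentration
scale doubles every percentile exactly, same seed) is asserted as a
property.

## Statistics

The cohort toolbox wraps scipy with the conventions pinned: two-sided
Mann–Whitney U (exact null for tie-free samples with n ≤ 20 per group,
tie-corrected normal approximation otherwise — the paths agree to < 0.02
in p at n = 15), Spearman correlation with average ranks (constant input
raises rather than reporting 0), and a one-sample Kolmogorov–Smirnov test
against a normal with estimated mean/sd (the Lilliefors caveat — estimated
parameters make the p-value conservative — is logged and recorded in the
method label).  No multiple-testing correction is applied, matching the
survey practice being emulated.

## Numerical choices and degenerate inputs

* Percentile definition everywhere: numpy's linear interpolation between
  closest ranks, inclusive.
* Zero spread anywhere (equal quartiles, mean = median) collapses to a
  point mass; point-mass pipelines reproduce the deterministic chain
  bit-for-bit and are used as collapse tests.
* All-zero contribution maps, empty cohorts/record sets, non-monotone
  quartiles, incomplete RfD grids, nonpositive body weights and unknown
  metals/media are rejected with row-addressed messages rather than
  propagated as NaN.
* Problem sizes in the test suite (200-seed calibration loops at n = 60,
  recovery at n = 600, 10⁴ MC iterations, 4 × 10⁴-draw sampling checks)
  were chosen as the smallest sizes at which the Monte Carlo error of each
  checked quantity is several times smaller than its tolerance band.

## Known limitations

* Carcinogenic risk, dermal/inhalation routes and bioavailability
  adjustment are out of scope (no slope factors or models are published
  for the emulated survey).
* The generator's marginals are faithful; its joint structure is an
  independence assumption.
* The KS normality test is conservative without the Lilliefors correction;
  it is used here as a screening device, as in the emulated survey.
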
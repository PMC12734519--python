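# Methods

## Study design being modelled

The pipeline targets a cross-sectional case–comparator analysis of
young-onset type 1 diabetes: 27 patients with proliferative diabetic
retinopathy (PDR) versus 31 with no retinopathy or non-proliferative
retinopathy only. Inclusion requires diagnosis at or before 30 years of
age and diabetes duration over five years; these are hard record
invariants. Four exposures are dichotomised: long-term glycaemic control
(poor = historical mean HbA1c > 7% / 53 mmol/mol), regularity of eye
examinations per screening guidelines, onset age (≤ 18 y vs > 18 y,
inclusive on the risk side), and diabetes duration split at the cohort
median (22.5 y in the reference cohort). Each exposure is analysed
univariately; no multivariable adjustment is performed, and no
multiple-testing correction is applied (tests are reported raw, matching
the univariate design).

## Synthetic cohort generator

Raw patient data for this design are typically not deposited, so the
generator emulates the published summary structure and makes every
downstream stage testable:

- **Skewed bounded variables** (duration, onset age, LDL, triglycerides)
  are drawn from a Beta distribution scaled to the published [min, max],
  with one shape parameter fixed at 2 (identifiability; also guarantees a
  unimodal density with zero mass at the bounds) and the other solved by
  Brent's method so the distribution median equals the published median.
  The sample median therefore converges to the target as n grows; at
  10⁵ per group recovery is well within 2% relative error.
- **Approximately normal variables** (current HbA1c, fasting glucose,
  systolic/diastolic BP, total cholesterol) are drawn from normals
  truncated at wide physiologic bounds (e.g. HbA1c 3–20%, SBP 70–250
  mmHg); at the target means the truncation bias is negligible.
- **Age is derived**, not sampled: age = onset + duration, then pulled
  toward the published age range. The published group medians are mutually
  consistent (PDR: 18 + 31 = 49), and downstream factors depend on onset
  and duration, not age. Where an extreme draw puts onset + duration far
  outside the nominal age range, the record invariant
  |age − (onset + duration)| ≤ 2 y takes precedence: clipping is limited
  to 2 years, so a small tail of records can fall outside the nominal age
  range. This is the deliberate resolution of a conflict between the two
  requirements.
- **Categorical fields** (sex, long-term control, exam regularity) are
  independent Bernoulli draws at the published fractions. Long-term
  control is sampled independently of the current HbA1c measurement: the
  category reflects historical records, not the value measured at the
  study visit.
- Durations landing exactly on 22.5 y are nudged off by 10⁻⁹ so the
  conventional median split never encounters ties by construction.
- The generator is a pure function of (spec, seed); seeds are explicit
  arguments and there is no global random state.

What the generator does **not** emulate: between-variable correlations
other than age = onset + duration (none are published), measurement error
structure, missingness (missing data are an I/O error by design), or any
longitudinal dynamics. Passing tests therefore demonstrate that the
statistical machinery recovers known marginal structure — not that it
would behave identically on real, correlated patient data.

The **fixture cohort** is the complementary tool: a deterministic 58-record
cohort whose four dichotomised factors reproduce the published 2×2 counts
*exactly* (risk levels assigned positionally). Its continuous fields are
two-point fills chosen only for invariant consistency; its group-comparison
rows are meaningful only for the categorical factors.

## Statistical battery

- **Odds ratio**: cross-product *ad/bc*, identical to exp(β) from a
  univariate binary-exposure logistic regression (verified against a
  maximum-likelihood logit fit to 6 significant figures in tests). The CI
  is Woolf's log-normal interval with z = 1.959964 at the default 95%
  level; the p value is a two-sided Wald test of ln OR. A single zero cell
  triggers Haldane–Anscombe +0.5 on all four cells (flagged in the
  result); zero cells across a diagonal are an error, since the OR is then
  genuinely undefined.
- **Chi-square**: Yates continuity correction with the |O−E|−0.5 deviation
  clamped at zero, 1 df. The correction is the default because the
  reference cohort's printed statistics match the corrected form (the
  plain Pearson statistic for the control table is 18.4, not 16.2); an
  uncorrected variant sits behind a flag. Note two of the four printed
  reference values (11.7, 9.9) appear truncated rather than rounded — the
  corrected statistic gives 11.75 and 9.98 — so tests compare within 0.1.
- **Mann–Whitney / Hodges–Lehmann**: U by rank summation with midranks;
  z from the normal approximation with tie-corrected variance and a 0.5
  continuity correction toward the null (the correction measurably
  improves small-sample agreement with the exact permutation null:
  exhaustively over all tie-free partitions of 6–8 pooled values the
  worst two-sided-p gap is < 0.05; at pooled n ≤ 5 or with heavy ties the
  permutation distribution is too lumpy for any smooth approximation to
  track within 0.05, which is a limit of the approximation itself). The
  shift estimate is the median of all pairwise differences x−y; its CI
  takes the k-th smallest and k-th largest pairwise differences with
  k = ⌊nm/2 − z·√var⌋ (clamped to valid indices).
- **t test**: pooled-variance Student by default — the common historical
  statistics-package default for this design — with Welch behind a flag;
  zero pooled variance is an explicit error.
- **Normality routing**: one-sample KS distance against a normal with
  estimated mean/SD judged at Lilliefors-corrected critical values (via
  statsmodels), because plain KS with estimated parameters is
  anti-conservative. Routing needs n ≥ 4; zero-spread samples route to the
  rank test rather than crashing. A variable is handled rank-based if
  either group rejects normality at α = 0.05, and the summary style
  follows the test family (median [min–max] vs mean ± SD).
- **Duration split**: defaults to the analysed cohort's own median
  (midpoint convention for even n). Records exactly at an exclusive
  threshold raise an error listing their ids unless a tie policy
  (`lower`/`upper`) is configured — silent tie handling would change the
  table unpredictably.

## Economic model

A deterministic, single-period budget-impact model — no discounting,
Markov states, QALYs or probabilistic sensitivity analysis. Parameters and
defaults:

| parameter | default | meaning |
|---|---|---|
| population | 10,000 | modelled national young-onset T1D cohort |
| uptake | 0.30 / 0.60 / 0.90 | fraction attending screening |
| interval_years | 1 or 2 | screening frequency (annualises programme cost) |
| pdr_prevalence | 0.47 | expected lifetime PDR fraction among screened |
| preventive_effect | 0.70 | fractional reduction in PDR cases with screening |
| fundus + OCT per visit | €40.16 + €36.71 = €76.87 | combined screening visit |
| annual treated-patient cost | €7207.45 | 4×76.87 + 84.32 + 5×(304.91+655.91) + 2011.55 |

Modelling conventions (each deliberate):

- The screening programme pays **one** combined visit per screened person
  per round; the "4 visits/year" multiplier belongs only inside the
  treated-patient bundle. This is what makes the medium-uptake programme
  cost 6000 × 76.87 = €461,220.
- Prevented cases are rounded half-up to whole patients **before** the
  monetary multiplication; unrounded internals are retained in `*_raw`
  fields. At medium uptake 2820 × 0.7 = 1974 exactly (a printed reference
  value of 1973 is unreachable under any rounding and treated as a typo;
  the headline €14.2M at millions/1-dp precision is unaffected).
- Biennial screening halves the annualised programme cost and leaves the
  preventive effect unchanged — reproducing the reference biennial row as
  printed rather than arguing for it epidemiologically.
- The headline "economic impact" column is **avoided treatment cost**
  (prevented × €7207.45) with no subtraction of programme cost; the model
  also reports `net_of_screening_eur` (avoided − screening cost) as the
  economically net quantity.
- All money is `Decimal` arithmetic quantized half-up to the cent; counts
  round half-up. No binary-float drift can enter the monetary outputs.
- `break_even` bisects the *continuous* model (case rounding disabled) to
  10⁻⁶ relative tolerance; a parameter whose admissible range never
  reaches non-negative net savings is an error, not a boundary value.
  Net savings are linear in uptake through the origin, so the uptake
  break-even is 0 whenever the programme is profitable at all.

## Problem sizes and numerical choices

Parameter-recovery tests run at 10⁵ records per group (seconds); the CI
coverage check simulates 1000 binomial 2×2 tables (n = 50 per arm, true
OR 3.5) and requires 93–97% coverage of the 95% Woolf interval; normality
routing power/size checks use 100 seeds × 200 draws. The acceptance script
uses 2000 records per group for the generator-recovery and
Hodges–Lehmann-shift quantities — large enough that the duration shift
stabilises near the ~11-year target while keeping the run in seconds.

## Known limitations

- The synthetic generator matches marginal summaries only; odds ratios
  computed from a *generated* cohort's categorical factors scatter around
  the target fractions' implied OR and are not fixed — exact published
  counts come from the fixture cohort.
- The Mann–Whitney inference is asymptotic; no exact/conditional test is
  exposed (the exact enumeration lives in the test suite as an oracle).
- The economic model is single-period and linear; it deliberately ignores
  incidence dynamics, attenuation of screening benefit at longer
  intervals, and capacity constraints.
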
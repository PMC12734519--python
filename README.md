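# pdrscreen

Risk-factor statistics and screening budget-impact modelling for
**proliferative diabetic retinopathy (PDR) in young-onset type 1 diabetes
(T1D)**.

People diagnosed with T1D before age 30 carry a high lifetime risk of PDR,
the neovascular, sight-threatening stage of diabetic retinopathy. In a
cross-sectional case–comparator design (PDR cases vs patients with no or
only non-proliferative retinopathy), four dichotomised exposures are the
classic candidates: poor long-term glycaemic control (historical mean
HbA1c > 7%), irregular ophthalmological examinations, diabetes onset at or
before 18 years, and diabetes duration above the cohort median. The second
question is economic: what would a national screening programme (combined
fundus photography + OCT per visit) cost, and how much PDR treatment
expenditure would it avoid?

`pdrscreen` implements that analysis as a tested, reusable pipeline, for
epidemiologists and health-economics analysts who want to rerun it on their
own cohort CSVs or on synthetic cohorts:

- **Cohort layer** — a patient-record schema with inclusion invariants
  (duration > 5 y, onset ≤ 30 y, internal age consistency), CSV I/O with
  row/field-level validation, a seeded synthetic-cohort generator that
  targets per-group medians/ranges (scaled Beta) and means/SDs (truncated
  normal), and a deterministic 58-patient fixture cohort (27 PDR + 31
  comparators) reproducing the published 2×2 factor counts exactly.
- **Statistics layer** — for a 2×2 table with cells *a,b,c,d* (risk/reference
  × case/comparator): the cross-product odds ratio OR = *ad/bc* with Woolf
  interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) and Haldane–Anscombe +0.5
  adjustment for single zero cells; the Yates-corrected chi-square
  Σ(max(0, |O−E|−½))²/E on 1 df; the Mann–Whitney U test (midranks,
  tie-corrected variance, continuity-corrected z) with the Hodges–Lehmann
  shift estimate (median of pairwise differences) and its rank-based CI;
  the pooled two-sample t test; and Lilliefors-corrected Kolmogorov–Smirnov
  routing that decides rank-based vs parametric handling per variable.
- **Economics layer** — a deterministic single-period model in exact decimal
  arithmetic. With population *N*, uptake *u*, screening interval *i*,
  PDR prevalence *π* and preventive effect *e*:
  screened = *N·u*; screening cost = screened × €76.87 / *i*;
  expected cases = screened × *π*; prevented = round(expected × *e*);
  avoided treatment = prevented × €7207.45 (the annual treated-patient
  bundle: 4 monitoring visits, laser, 5 anti-VEGF injections + drug,
  vitrectomy). Break-even solving and one-way sensitivity sweeps included.

## Worked example

```python
import pdrscreen as p

cohort = p.fixture_cohort()                 # 27 PDR + 31 NPDR patients
rows, blocks = p.compare_groups(cohort)
print(p.table2_frame(blocks)[["factor", "pdr_risk_n", "npdr_risk_n",
                              "or", "or_ci", "chi2"]].to_string(index=False))
```

```
          factor  pdr_risk_n  npdr_risk_n   or     or_ci  chi2
longterm_control          23            9 14.1  3.8-52.3  16.2
 exam_regularity          22            4 29.7 7.1-124.1  24.7
       onset_age          16            4  9.8  2.7-36.1  11.8
        duration          20            9  7.0  2.2-22.2  10.0
```

Reading: 23/27 cases vs 9/31 comparators had poor long-term control, giving
14-fold odds of PDR (95% CI 3.8–52); irregular eye exams carry almost
30-fold odds. The economics:

```python
grid = p.scenario_grid(p.default_scenarios(), p.CostInputs())
print(grid[["scenario", "population_screened", "screening_cost_eur",
            "pdr_cases_prevented", "avoided_treatment_eur"]].to_string(index=False))
```

```
                 scenario  population_screened screening_cost_eur  pdr_cases_prevented avoided_treatment_eur
Annual - Low Uptake (30%)                 3000          230610.00                  987            7113753.15
    Annual - Medium (60%)                 6000          461220.00                 1974           14227506.30
      Annual - High (90%)                 9000          691830.00                 2961           21341259.45
  Biennial - Medium (60%)                 6000          230610.00                 1974           14227506.30
```

At 60% annual uptake, screening 6000 of 10,000 young-onset T1D patients
costs €0.46M per year and avoids ~€14.2M of annual PDR treatment
expenditure; even 30% uptake nets about €6.9M after screening costs.

The same pipeline runs from the shell:

```bash
pdrscreen generate --fixture --out cohort.csv
pdrscreen stats --cohort cohort.csv --outdir out      # table1.csv, table2.csv
pdrscreen econ --prevalence from-cohort --cohort cohort.csv --outdir out
pdrscreen report --outdir out                         # all of the above
```

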
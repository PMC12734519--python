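"""Risk-factor statistics and screening economics for proliferative diabetic
retinopathy (PDR) in young-onset type 1 diabetes.

The module is organised in the order a full analysis runs:

1.  **Cohort** -- the patient record schema, a synthetic cohort generator that
    targets published per-group summary statistics (medians with ranges for
    skewed variables, means with SDs for approximately normal ones), a
    deterministic 58-patient fixture cohort reproducing the published
    categorical risk-factor counts, and CSV round-trip I/O with validation.
2.  **Risk statistics** -- dichotomisation of risk factors into 2x2
    exposure-by-outcome tables, cross-product odds ratios with Woolf
    (log-scale) confidence intervals, Yates continuity-corrected chi-square
    tests, the Mann-Whitney U test with Hodges-Lehmann shift estimate and
    confidence interval, the pooled two-sample t test, Lilliefors-corrected
    Kolmogorov-Smirnov normality routing, and whole-cohort group comparison.
3.  **Economics** -- a deterministic single-period budget-impact model for a
    national diabetic-retinopathy screening programme: per-visit and annual
    treated-patient costs, scenario evaluation over uptake / frequency grids,
    break-even solving and one-way sensitivity sweeps.  All money is exact
    decimal arithmetic.
4.  **Pipeline configuration** -- defaults and YAML loading used by the
    command-line interface in :mod:`pdrscreen.__main__`.

Randomness is always explicit: every stochastic function takes a seed or a
:class:`numpy.random.Generator`; there is no module-level random state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, fields, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    # cohort
    "Group", "Sex", "Control", "ExamRegularity", "PatientRecord",
    "SkewedTarget", "SymmetricTarget", "GroupSpec", "CohortSpec",
    "generate_cohort", "fixture_cohort", "read_cohort", "write_cohort",
    "cohort_to_frame", "cohort_prevalence", "validate_record",
    "CohortSpecError", "CohortSchemaError", "RecordInvariantError",
    # risk statistics
    "FactorDefinition", "BUILTIN_FACTORS", "ContingencyTable2x2",
    "OddsRatioResult", "ChiSquareResult", "ShiftEstimate",
    "GroupComparisonRow", "Normality", "ThresholdTieError",
    "dichotomize", "odds_ratio", "chi_square_corrected",
    "mann_whitney_shift", "t_test", "normality_route", "compare_groups",
    "table1_frame", "table2_frame", "TABLE1_CONTINUOUS", "TABLE1_CATEGORICAL",
    # economics
    "CostInputs", "ScreeningScenario", "ScenarioResult",
    "per_visit_cost", "annual_treated_cost", "run_scenario",
    "scenario_grid", "default_scenarios", "break_even",
    "one_way_sensitivity", "render_table",
    # pipeline config
    "DEFAULT_CONFIG", "load_config", "config_hash",
]

log = logging.getLogger("pdrscreen")

# Two-sided 95% normal critical value used throughout for confidence limits.
Z_95 = 1.959964

CENT = Decimal("0.01")


def _dec(x) -> Decimal:
    """Exact decimal from a number without binary-float cent drift."""
    if isinstance(x, Decimal):
        return x
    return Decimal(str(x))


# ---------------------------------------------------------------------------
# 1. Cohort: schema, synthetic generator, fixture, CSV I/O
# ---------------------------------------------------------------------------


class Group(str, Enum):
    """Retinopathy outcome group: proliferative DR cases vs comparators
    (no retinopathy or non-proliferative retinopathy only)."""

    PDR = "pdr"
    NPDR = "npdr"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Control(str, Enum):
    """Long-term glycaemic control category: 'good' means historical mean
    HbA1c at or below 7% (53 mmol/mol), 'poor' means above."""

    GOOD = "good"
    POOR = "poor"


class ExamRegularity(str, Enum):
    """Adherence to diabetes eye-screening guidelines for eye exams."""

    REGULAR = "regular"
    IRREGULAR = "irregular"


class CohortSpecError(ValueError):
    """A cohort specification violates its invariants; names the field."""


class CohortSchemaError(ValueError):
    """A cohort CSV is structurally invalid (missing column, bad value)."""


class RecordInvariantError(ValueError):
    """A patient record violates a clinical/inclusion invariant."""


@dataclass
class PatientRecord:
    """One subject: demographics, diabetes history, labs and the two
    dichotomous risk-factor categories from the medical record.

    Inclusion rules enforced as invariants: diabetes duration over five
    years, onset at 30 years of age or younger, and internal consistency
    of current age with onset age plus duration (within two years).
    """

    patient_id: str
    group: Group
    sex: Sex
    age_years: float
    onset_age_years: float
    duration_years: float
    hba1c_current_pct: float
    fasting_glucose_mmol_l: float
    sbp_mmhg: float
    dbp_mmhg: float
    total_chol_mmol_l: float
    ldl_mmol_l: float
    tg_mmol_l: float
    longterm_control: Control
    exam_regularity: ExamRegularity


#: Column order of the cohort CSV schema (header names = field names).
COHORT_COLUMNS = [f.name for f in fields(PatientRecord)]

_ENUM_FIELDS = {
    "group": Group,
    "sex": Sex,
    "longterm_control": Control,
    "exam_regularity": ExamRegularity,
}

# Strictly-positive numeric fields; triglycerides only need to be >= 0
# (the published NPDR range bottoms out at 0 mmol/L, reproduced as printed).
_POSITIVE_FIELDS = [
    "age_years", "onset_age_years", "duration_years", "hba1c_current_pct",
    "fasting_glucose_mmol_l", "sbp_mmhg", "dbp_mmhg", "total_chol_mmol_l",
    "ldl_mmol_l",
]


def validate_record(rec: PatientRecord, row: int | None = None) -> None:
    """Raise :class:`RecordInvariantError` naming the offending field."""

    where = f" (row {row})" if row is not None else ""

    def fail(fieldname: str, msg: str):
        raise RecordInvariantError(f"{fieldname}{where}: {msg} [patient {rec.patient_id}]")

    for name in _POSITIVE_FIELDS:
        v = getattr(rec, name)
        if not (v > 0) or not math.isfinite(v):
            fail(name, f"must be strictly positive, got {v}")
    if not (rec.tg_mmol_l >= 0) or not math.isfinite(rec.tg_mmol_l):
        fail("tg_mmol_l", f"must be >= 0, got {rec.tg_mmol_l}")
    if not rec.duration_years > 5:
        fail("duration_years", f"inclusion requires duration > 5 y, got {rec.duration_years}")
    if not rec.onset_age_years <= 30:
        fail("onset_age_years", f"inclusion requires onset <= 30 y, got {rec.onset_age_years}")
    drift = abs(rec.age_years - (rec.onset_age_years + rec.duration_years))
    if drift > 2:
        fail("age_years", f"age inconsistent with onset + duration by {drift:.2f} y (> 2)")


# -- Cohort specification ---------------------------------------------------


@dataclass(frozen=True)
class SkewedTarget:
    """Target for a right/left-skewed bounded variable: the generator draws a
    scaled Beta on [minimum, maximum] whose median equals ``median``."""

    median: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class SymmetricTarget:
    """Target for an approximately normal variable (mean, SD); draws come
    from a normal truncated at physiologic bounds."""

    mean: float
    sd: float


#: Physiologic truncation bounds for the symmetric variables.  Wide enough
#: that truncation bias on means/SDs is negligible at the target values.
PHYSIOLOGIC_BOUNDS: dict[str, tuple[float, float]] = {
    "hba1c_current_pct": (3.0, 20.0),
    "fasting_glucose_mmol_l": (2.0, 30.0),
    "sbp_mmhg": (70.0, 250.0),
    "dbp_mmhg": (40.0, 160.0),
    "total_chol_mmol_l": (1.0, 15.0),
}

SKEWED_VARS = ["duration_years", "onset_age_years", "ldl_mmol_l", "tg_mmol_l"]
SYMMETRIC_VARS = list(PHYSIOLOGIC_BOUNDS)


@dataclass(frozen=True)
class GroupSpec:
    """Distributional targets for one outcome group."""

    n: int
    sex_female_fraction: float
    longterm_poor_fraction: float
    exam_irregular_fraction: float
    #: keys: duration_years, onset_age_years, ldl_mmol_l, tg_mmol_l, plus an
    #: ``age_years`` entry used only to clip the derived age into range.
    skewed: dict[str, SkewedTarget]
    #: keys: the five PHYSIOLOGIC_BOUNDS variables.
    symmetric: dict[str, SymmetricTarget]


@dataclass(frozen=True)
class CohortSpec:
    """Per-group generator targets.  :meth:`default` reproduces the study
    cohort's published summary table (27 PDR vs 31 NPDR patients)."""

    pdr: GroupSpec
    npdr: GroupSpec

    def validate(self) -> None:
        for gname, g in (("pdr", self.pdr), ("npdr", self.npdr)):
            if g.n < 0:
                raise CohortSpecError(f"{gname}.n: must be >= 0, got {g.n}")
            for fname in ("sex_female_fraction", "longterm_poor_fraction",
                          "exam_irregular_fraction"):
                v = getattr(g, fname)
                if not 0 <= v <= 1:
                    raise CohortSpecError(f"{gname}.{fname}: must be in [0,1], got {v}")
            for var, t in g.skewed.items():
                if not (t.minimum < t.median < t.maximum):
                    raise CohortSpecError(
                        f"{gname}.skewed[{var}]: need min < median < max, "
                        f"got {t.minimum}, {t.median}, {t.maximum}")
            for var, t in g.symmetric.items():
                if not t.sd > 0:
                    raise CohortSpecError(f"{gname}.symmetric[{var}].sd: must be > 0, got {t.sd}")

    @classmethod
    def default(cls, scale: float = 1.0) -> "CohortSpec":
        """The study cohort's distribution targets, with group sizes
        optionally scaled (e.g. ``scale=1000`` for parameter-recovery runs)."""

        pdr = GroupSpec(
            n=round(27 * scale),
            sex_female_fraction=12 / 27,
            longterm_poor_fraction=23 / 27,
            exam_irregular_fraction=22 / 27,
            skewed={
                "duration_years": SkewedTarget(31, 15, 40),
                "onset_age_years": SkewedTarget(18, 10, 30),
                "ldl_mmol_l": SkewedTarget(2.6, 1, 4),
                "tg_mmol_l": SkewedTarget(1.9, 0.9, 2.7),
                "age_years": SkewedTarget(49, 28, 58),
            },
            symmetric={
                "hba1c_current_pct": SymmetricTarget(7.9, 1.4),
                "sbp_mmhg": SymmetricTarget(139, 10),
                "dbp_mmhg": SymmetricTarget(86, 4.7),
                "fasting_glucose_mmol_l": SymmetricTarget(7.5, 1.4),
                "total_chol_mmol_l": SymmetricTarget(4.34, 1.10),
            },
        )
        npdr = GroupSpec(
            n=round(31 * scale),
            sex_female_fraction=13 / 31,
            longterm_poor_fraction=9 / 31,
            exam_irregular_fraction=4 / 31,
            skewed={
                "duration_years": SkewedTarget(20, 10, 27),
                "onset_age_years": SkewedTarget(28, 17, 30),
                "ldl_mmol_l": SkewedTarget(1.7, 1, 3),
                # published NPDR triglyceride range includes 0; the Beta lower
                # bound is kept as printed.
                "tg_mmol_l": SkewedTarget(1.5, 0, 2),
                "age_years": SkewedTarget(47, 35, 55),
            },
            symmetric={
                "hba1c_current_pct": SymmetricTarget(5.9, 0.7),
                "sbp_mmhg": SymmetricTarget(129, 10),
                "dbp_mmhg": SymmetricTarget(81, 9.2),
                "fasting_glucose_mmol_l": SymmetricTarget(6.0, 0.7),
                "total_chol_mmol_l": SymmetricTarget(4.14, 0.81),
            },
        )
        return cls(pdr=pdr, npdr=npdr)


def _beta_shapes_for_median(rel_median: float) -> tuple[float, float]:
    """Shape parameters (a, b) of a Beta whose median equals ``rel_median``.

    One shape is fixed at 2 for identifiability and the other solved
    numerically; the fixed shape is chosen on the short side so both shapes
    stay >= 2 and the density is unimodal with zero mass at the bounds.
    """
    if not 0 < rel_median < 1:
        raise ValueError(f"relative median must be in (0,1), got {rel_median}")
    if abs(rel_median - 0.5) < 1e-12:
        return 2.0, 2.0
    if rel_median > 0.5:
        a = optimize.brentq(lambda a: stats.beta.ppf(0.5, a, 2.0) - rel_median,
                            2.0, 1e4, xtol=1e-12)
        return float(a), 2.0
    b = optimize.brentq(lambda b: stats.beta.ppf(0.5, 2.0, b) - rel_median,
                        2.0, 1e4, xtol=1e-12)
    return 2.0, float(b)


def _draw_skewed(rng: np.random.Generator, t: SkewedTarget, n: int) -> np.ndarray:
    a, b = _beta_shapes_for_median((t.median - t.minimum) / (t.maximum - t.minimum))
    return t.minimum + (t.maximum - t.minimum) * rng.beta(a, b, size=n)


def _draw_symmetric(rng: np.random.Generator, t: SymmetricTarget,
                    bounds: tuple[float, float], n: int) -> np.ndarray:
    lo, hi = bounds
    a, b = (lo - t.mean) / t.sd, (hi - t.mean) / t.sd
    return stats.truncnorm.rvs(a, b, loc=t.mean, scale=t.sd, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec, seed: int) -> list[PatientRecord]:
    """Draw a synthetic cohort matching ``spec``; pure function of (spec, seed).

    Skewed bounded variables come from a scaled Beta on [min, max] whose
    median equals the target; symmetric variables from truncated normals.
    Age is derived as onset + duration and clipped toward the target age
    range by at most two years, preserving the internal-consistency
    invariant.  Categorical fields are independent Bernoulli draws at the
    spec fractions.  Durations landing exactly on 22.5 y (the study
    cohort's median split) are nudged off the threshold.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    out: list[PatientRecord] = []
    for group, g in ((Group.PDR, spec.pdr), (Group.NPDR, spec.npdr)):
        n = g.n
        if n == 0:
            continue
        cols: dict[str, np.ndarray] = {}
        for var in SKEWED_VARS:
            cols[var] = _draw_skewed(rng, g.skewed[var], n)
        # avoid exact ties at the conventional duration split
        dur = cols["duration_years"]
        dur[dur == 22.5] += 1e-9
        for var in SYMMETRIC_VARS:
            cols[var] = _draw_symmetric(rng, g.symmetric[var], PHYSIOLOGIC_BOUNDS[var], n)
        raw_age = cols["onset_age_years"] + cols["duration_years"]
        aget = g.skewed["age_years"]
        clipped = np.clip(raw_age, aget.minimum, aget.maximum)
        # never move age more than 2 y from onset + duration
        cols["age_years"] = np.clip(clipped, raw_age - 2, raw_age + 2)
        female = rng.random(n) < g.sex_female_fraction
        poor = rng.random(n) < g.longterm_poor_fraction
        irregular = rng.random(n) < g.exam_irregular_fraction
        for i in range(n):
            rec = PatientRecord(
                patient_id=f"{group.value}-{i:06d}",
                group=group,
                sex=Sex.FEMALE if female[i] else Sex.MALE,
                age_years=float(cols["age_years"][i]),
                onset_age_years=float(cols["onset_age_years"][i]),
                duration_years=float(cols["duration_years"][i]),
                hba1c_current_pct=float(cols["hba1c_current_pct"][i]),
                fasting_glucose_mmol_l=float(cols["fasting_glucose_mmol_l"][i]),
                sbp_mmhg=float(cols["sbp_mmhg"][i]),
                dbp_mmhg=float(cols["dbp_mmhg"][i]),
                total_chol_mmol_l=float(cols["total_chol_mmol_l"][i]),
                ldl_mmol_l=float(cols["ldl_mmol_l"][i]),
                tg_mmol_l=float(cols["tg_mmol_l"][i]),
                longterm_control=Control.POOR if poor[i] else Control.GOOD,
                exam_regularity=(ExamRegularity.IRREGULAR if irregular[i]
                                 else ExamRegularity.REGULAR),
            )
            validate_record(rec)
            out.append(rec)
    return out


# -- Deterministic fixture cohort -------------------------------------------

# Per-group risk-factor counts of the 58-patient study cohort:
# (n, females, poor control, irregular exams, onset <= 18 y, duration > 22.5 y)
_FIXTURE_COUNTS = {
    Group.PDR: dict(n=27, female=12, poor=23, irregular=22, early_onset=16, long_duration=20),
    Group.NPDR: dict(n=31, female=13, poor=9, irregular=4, early_onset=4, long_duration=9),
}

# Plausible continuous fill values per group (PDR, NPDR); the fixture's
# purpose is exact categorical composition, not continuous realism.
_FIXTURE_FILL = {
    Group.PDR: dict(hba1c=(8.5, 6.8), glucose=7.5, sbp=139.0, dbp=86.0, chol=4.3, ldl=2.6, tg=1.9),
    Group.NPDR: dict(hba1c=(7.4, 5.8), glucose=6.0, sbp=129.0, dbp=81.0, chol=4.1, ldl=1.7, tg=1.5),
}


def fixture_cohort() -> list[PatientRecord]:
    """Deterministic 58-patient cohort (27 PDR + 31 NPDR) whose dichotomous
    risk factors reproduce the study's published 2x2 counts exactly.

    Factor categories are assigned by position (the first *k* records of a
    group carry the risk level), which fixes the marginal counts the
    downstream statistics use; joint structure between factors is arbitrary.
    Continuous fields are filled with values consistent with each record's
    categories and the record invariants; durations are 30 or 15 y so the
    cohort-wide median lands exactly on the conventional 22.5 y split with
    no record at the threshold.
    """
    out: list[PatientRecord] = []
    for group, c in _FIXTURE_COUNTS.items():
        fill = _FIXTURE_FILL[group]
        for i in range(c["n"]):
            early = i < c["early_onset"]
            long_dur = i < c["long_duration"]
            poor = i < c["poor"]
            onset = 15.0 if early else 26.0
            duration = 30.0 if long_dur else 15.0
            rec = PatientRecord(
                patient_id=f"fix-{group.value}-{i:03d}",
                group=group,
                sex=Sex.FEMALE if i < c["female"] else Sex.MALE,
                age_years=onset + duration,
                onset_age_years=onset,
                duration_years=duration,
                hba1c_current_pct=fill["hba1c"][0] if poor else fill["hba1c"][1],
                fasting_glucose_mmol_l=fill["glucose"],
                sbp_mmhg=fill["sbp"],
                dbp_mmhg=fill["dbp"],
                total_chol_mmol_l=fill["chol"],
                ldl_mmol_l=fill["ldl"],
                tg_mmol_l=fill["tg"],
                longterm_control=Control.POOR if poor else Control.GOOD,
                exam_regularity=(ExamRegularity.IRREGULAR if i < c["irregular"]
                                 else ExamRegularity.REGULAR),
            )
            validate_record(rec)
            out.append(rec)
    return out


# -- CSV I/O -----------------------------------------------------------------


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in schema column order, enums as lowercase str."""
    rows = []
    for rec in cohort:
        row = {}
        for name in COHORT_COLUMNS:
            v = getattr(rec, name)
            row[name] = v.value if isinstance(v, Enum) else v
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write the cohort CSV (UTF-8, header row, full-precision numbers)."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    Raises :class:`CohortSchemaError` for a missing column or unparseable
    value and :class:`RecordInvariantError` for an invariant violation,
    each reporting the data row number (1-based, excluding header) and field.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort file {path} is missing column(s): {', '.join(missing)}")
    out: list[PatientRecord] = []
    for idx, raw in enumerate(df.itertuples(index=False), start=1):
        kwargs = {}
        for name in COHORT_COLUMNS:
            v = getattr(raw, name)
            if name == "patient_id":
                kwargs[name] = v
            elif name in _ENUM_FIELDS:
                try:
                    kwargs[name] = _ENUM_FIELDS[name](str(v).strip().lower())
                except ValueError:
                    raise CohortSchemaError(
                        f"{name} (row {idx}): invalid value {v!r}") from None
            else:
                try:
                    kwargs[name] = float(v)
                except ValueError:
                    raise CohortSchemaError(
                        f"{name} (row {idx}): cannot parse number from {v!r}") from None
        rec = PatientRecord(**kwargs)
        validate_record(rec, row=idx)
        out.append(rec)
    return out


def cohort_prevalence(cohort: Sequence[PatientRecord]) -> Decimal:
    """Exact PDR fraction of a cohort (cases / total) as a Decimal."""
    if not cohort:
        raise ValueError("empty cohort has no prevalence")
    n_pdr = sum(1 for r in cohort if r.group is Group.PDR)
    return Decimal(n_pdr) / Decimal(len(cohort))


# ---------------------------------------------------------------------------
# 2. Risk statistics
# ---------------------------------------------------------------------------


class ThresholdTieError(ValueError):
    """Records sit exactly on an exclusive dichotomisation threshold; carries
    the offending patient ids so the caller can set an explicit tie policy."""

    def __init__(self, msg: str, ids: list[str]):
        super().__init__(msg)
        self.ids = ids


@dataclass(frozen=True)
class FactorDefinition:
    """A dichotomised risk factor: which record variable, which rule, and the
    display labels for the risk and reference levels.

    ``kind`` is one of ``categorical`` (risk when the enum field equals
    ``risk_value``), ``le`` (risk when value <= threshold, inclusive) or
    ``gt`` (risk when value > threshold, exclusive; ties at the threshold
    raise unless a tie policy is given).  A ``gt`` factor with
    ``threshold=None`` uses the cohort-wide sample median (midpoint
    convention for even n).
    """

    name: str
    variable: str
    kind: Literal["categorical", "le", "gt"]
    risk_level_label: str
    reference_level_label: str
    risk_value: str | None = None
    threshold: float | None = None


#: The four built-in risk factors of the analysis, in reporting order.
BUILTIN_FACTORS: tuple[FactorDefinition, ...] = (
    FactorDefinition("longterm_control", "longterm_control", "categorical",
                     risk_level_label="Poor (HbA1c > 7%)",
                     reference_level_label="Good (HbA1c <= 7%)",
                     risk_value=Control.POOR.value),
    FactorDefinition("exam_regularity", "exam_regularity", "categorical",
                     risk_level_label="Irregular",
                     reference_level_label="Regular",
                     risk_value=ExamRegularity.IRREGULAR.value),
    FactorDefinition("onset_age", "onset_age_years", "le",
                     risk_level_label="<= 18 y",
                     reference_level_label="> 18 y",
                     threshold=18.0),
    FactorDefinition("duration", "duration_years", "gt",
                     risk_level_label="> median",
                     reference_level_label="<= median",
                     threshold=None),
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: ``a`` risk/PDR, ``b`` risk/NPDR,
    ``c`` reference/PDR, ``d`` reference/NPDR."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    level: float
    p_value: float
    continuity_adjusted: bool


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    corrected: bool


@dataclass(frozen=True)
class ShiftEstimate:
    """Hodges-Lehmann between-group shift with Mann-Whitney inference."""

    hl_shift: float
    ci_low: float
    ci_high: float
    level: float
    z: float
    p_value: float
    u_statistic: float


class Normality(str, Enum):
    NORMAL = "normal"
    NON_NORMAL = "non_normal"


@dataclass(frozen=True)
class GroupComparisonRow:
    """One summary-table row: per-group display summaries and the test the
    normality routing selected for the variable."""

    variable: str
    pdr_summary: str
    npdr_summary: str
    test: Literal["mann_whitney", "t_test", "chi_square"]
    statistic: float
    p_value: float


def _resolve_threshold(cohort: Sequence[PatientRecord], factor: FactorDefinition) -> float:
    if factor.threshold is not None:
        return factor.threshold
    values = np.array([getattr(r, factor.variable) for r in cohort], dtype=float)
    return float(np.median(values))


def dichotomize(cohort: Sequence[PatientRecord], factor: FactorDefinition,
                tie_policy: Literal["lower", "upper"] | None = None) -> ContingencyTable2x2:
    """Assign every record to the risk or reference level of ``factor`` and
    count by outcome group.

    For an exclusive (``gt``) rule, records exactly at the threshold raise
    :class:`ThresholdTieError` unless ``tie_policy`` sends them to the
    ``lower`` (reference) or ``upper`` (risk) side.
    """
    if not cohort:
        raise ValueError("cannot dichotomize an empty cohort")
    a = b = c = d = 0
    if factor.kind == "categorical":
        def is_risk(rec):
            return getattr(rec, factor.variable).value == factor.risk_value
    else:
        thr = _resolve_threshold(cohort, factor)
        if factor.kind == "gt":
            ties = [r.patient_id for r in cohort
                    if getattr(r, factor.variable) == thr]
            if ties and tie_policy is None:
                raise ThresholdTieError(
                    f"factor {factor.name}: {len(ties)} record(s) exactly at "
                    f"threshold {thr}; set tie_policy='lower' or 'upper'", ties)

            def is_risk(rec):
                v = getattr(rec, factor.variable)
                if v == thr:
                    return tie_policy == "upper"
                return v > thr
        else:  # 'le': inclusive rule, equality is well-defined
            def is_risk(rec):
                return getattr(rec, factor.variable) <= thr
    for rec in cohort:
        if is_risk(rec):
            if rec.group is Group.PDR:
                a += 1
            else:
                b += 1
        else:
            if rec.group is Group.PDR:
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio(t: ContingencyTable2x2, level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf (log-scale) confidence interval.

    Equals exp(coefficient) of a univariate binary-exposure logistic
    regression of outcome on risk level.  A single zero cell triggers the
    Haldane-Anscombe +0.5 adjustment of all four cells (flagged in the
    result); zero cells on both ends of a diagonal leave the odds ratio
    undefined and raise.  The p value is a two-sided Wald test of ln OR.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise ValueError("odds ratio undefined: zero cells on a diagonal")
    adjusted = 0 in (a, b, c, d)
    if adjusted:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z_crit = stats.norm.ppf(0.5 + level / 2)
    log_or = math.log(or_point)
    ci_low = math.exp(log_or - z_crit * se)
    ci_high = math.exp(log_or + z_crit * se)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(or_point, ci_low, ci_high, level, float(p), adjusted)


def chi_square_corrected(t: ContingencyTable2x2, correction: bool = True) -> ChiSquareResult:
    """Chi-square test of independence for a 2x2 table, Yates-corrected by
    default: each |O - E| is reduced by 0.5 and clamped at zero before
    squaring.  ``correction=False`` gives the plain Pearson statistic.
    """
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square undefined: a zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(0.0, dev - 0.5)
    statistic = float((dev ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic, df=1, p_value=p, corrected=correction)


def mann_whitney_shift(x: Sequence[float], y: Sequence[float],
                       level: float = 0.95,
                       continuity: bool = True) -> ShiftEstimate:
    """Mann-Whitney U test with Hodges-Lehmann shift estimate for x - y.

    U is computed by rank summation with midranks for ties; z uses the
    normal approximation with tie-corrected variance and (by default) a 0.5
    continuity correction toward the null.  The shift estimate is the median
    of all pairwise differences x_i - y_j; its confidence interval comes
    from the ordered pairwise differences at the rank cutoffs implied by the
    normal-approximation critical value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2)
    nm = n * m
    mu = nm / 2
    big_n = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum())
    var = nm / 12 * (big_n + 1 - tie_term / (big_n * (big_n - 1)))
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    hl = float(np.median(diffs))
    if var <= 0:  # every pooled value tied
        return ShiftEstimate(hl, hl, hl, level, 0.0, 1.0, u)
    sd = math.sqrt(var)
    dev = u - mu
    if continuity and dev != 0:
        dev -= math.copysign(0.5, dev)
    z = dev / sd
    p = float(2 * stats.norm.sf(abs(z)))
    z_crit = stats.norm.ppf(0.5 + level / 2)
    k = int(math.floor(mu - z_crit * sd))
    k = min(max(k, 0), (nm - 1) // 2)
    return ShiftEstimate(hl, float(diffs[k]), float(diffs[nm - 1 - k]),
                         level, float(z), min(p, 1.0), u)


def t_test(x: Sequence[float], y: Sequence[float],
           pooled: bool = True) -> tuple[float, float]:
    """Two-sample t test, pooled-variance Student by default (Welch behind
    the flag); returns (statistic, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0:
            raise ValueError("degenerate samples: pooled variance is zero")
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        if v1 == 0 and v2 == 0:
            raise ValueError("degenerate samples: both variances are zero")
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    stat = (m1 - m2) / se
    p = float(2 * stats.t.sf(abs(stat), df))
    return float(stat), p


def normality_route(x: Sequence[float], alpha: float = 0.05) -> Normality:
    """Route a variable to parametric or rank-based analysis.

    Uses the Kolmogorov-Smirnov distance against a normal with estimated
    mean/SD, judged at Lilliefors-corrected critical values (plain KS with
    estimated parameters is anti-conservative).  A zero-spread sample is
    routed non-normal rather than crashing.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("normality routing needs at least 4 observations")
    if np.ptp(x) == 0:
        return Normality.NON_NORMAL
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return Normality.NON_NORMAL if p < alpha else Normality.NORMAL


# -- whole-cohort comparison -------------------------------------------------

#: (record field, display name) in published reporting order.
TABLE1_CONTINUOUS = [
    ("age_years", "Age (years)"),
    ("duration_years", "Duration of diabetes (years)"),
    ("onset_age_years", "Age at onset of diabetes (years)"),
    ("hba1c_current_pct", "Current HbA1c (%)"),
    ("sbp_mmhg", "Systolic BP (mm Hg)"),
    ("dbp_mmhg", "Diastolic BP (mm Hg)"),
    ("fasting_glucose_mmol_l", "Current blood glucose (mmol/L)"),
    ("total_chol_mmol_l", "Total cholesterol (mmol/L)"),
    ("ldl_mmol_l", "LDL (mmol/L)"),
    ("tg_mmol_l", "Triglycerides (mmol/L)"),
]

TABLE1_CATEGORICAL = [
    ("sex", Sex.FEMALE, "Sex (n female)"),
    ("longterm_control", Control.POOR, "Poor long-term control n"),
    ("exam_regularity", ExamRegularity.IRREGULAR, "Irregular examinations n"),
]


def _fmt(v: float) -> str:
    s = f"{v:.1f}"
    return s[:-2] if s.endswith(".0") else s


def compare_groups(cohort: Sequence[PatientRecord], *,
                   alpha: float = 0.05, level: float = 0.95,
                   duration_threshold: float | None = None,
                   tie_policy: Literal["lower", "upper"] | None = None,
                   ) -> tuple[list[GroupComparisonRow],
                              list[tuple[FactorDefinition, ContingencyTable2x2,
                                         OddsRatioResult, ChiSquareResult]]]:
    """Full between-group analysis of a cohort.

    Returns the demographic/laboratory comparison rows (normality-routed
    summaries and tests, in published order) and, for each built-in risk
    factor, its 2x2 table, odds ratio and corrected chi-square.  The
    duration factor splits at ``duration_threshold`` when given, else at
    the cohort-wide median.
    """
    pdr = [r for r in cohort if r.group is Group.PDR]
    npdr = [r for r in cohort if r.group is Group.NPDR]
    if not pdr or not npdr:
        raise ValueError("cohort must contain both PDR and NPDR records")

    rows: list[GroupComparisonRow] = []
    for var, label in TABLE1_CONTINUOUS:
        xs = np.array([getattr(r, var) for r in pdr])
        ys = np.array([getattr(r, var) for r in npdr])
        route = (Normality.NON_NORMAL
                 if Normality.NON_NORMAL in (normality_route(xs, alpha),
                                             normality_route(ys, alpha))
                 else Normality.NORMAL)
        if route is Normality.NON_NORMAL:
            est = mann_whitney_shift(xs, ys, level=level)
            rows.append(GroupComparisonRow(
                label,
                f"{_fmt(np.median(xs))} [{_fmt(xs.min())}-{_fmt(xs.max())}]",
                f"{_fmt(np.median(ys))} [{_fmt(ys.min())}-{_fmt(ys.max())}]",
                "mann_whitney", est.z, est.p_value))
        else:
            stat, p = t_test(xs, ys)
            rows.append(GroupComparisonRow(
                label,
                f"{_fmt(xs.mean())} +/- {_fmt(xs.std(ddof=1))}",
                f"{_fmt(ys.mean())} +/- {_fmt(ys.std(ddof=1))}",
                "t_test", stat, p))
    for var, level_enum, label in TABLE1_CATEGORICAL:
        a = sum(1 for r in pdr if getattr(r, var) is level_enum)
        b = sum(1 for r in npdr if getattr(r, var) is level_enum)
        tab = ContingencyTable2x2(a, b, len(pdr) - a, len(npdr) - b)
        chi = chi_square_corrected(tab)
        rows.append(GroupComparisonRow(
            label, f"{a} ({100 * a / len(pdr):.0f}%)",
            f"{b} ({100 * b / len(npdr):.0f}%)",
            "chi_square", chi.statistic, chi.p_value))

    blocks = []
    for factor in BUILTIN_FACTORS:
        if factor.name == "duration" and duration_threshold is not None:
            factor = replace(factor, threshold=duration_threshold)
        tab = dichotomize(cohort, factor, tie_policy=tie_policy)
        blocks.append((factor, tab, odds_ratio(tab, level=level),
                       chi_square_corrected(tab)))
    return rows, blocks


def table1_frame(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    """Demographic comparison rows as a DataFrame (raw columns included)."""
    return pd.DataFrame({
        "variable": [r.variable for r in rows],
        "pdr": [r.pdr_summary for r in rows],
        "npdr": [r.npdr_summary for r in rows],
        "test": [r.test for r in rows],
        "statistic_raw": [r.statistic for r in rows],
        "p_value_raw": [r.p_value for r in rows],
        "p_value": [f"{r.p_value:.3f}" if r.p_value >= 0.001 else "<0.001" for r in rows],
    })


def table2_frame(blocks) -> pd.DataFrame:
    """Risk-factor analysis as a DataFrame mirroring the published layout:
    counts per level, odds ratio with CI, chi-square; full-precision values
    in ``*_raw`` columns."""
    recs = []
    for factor, tab, orr, chi in blocks:
        n_pdr, n_npdr = tab.a + tab.c, tab.b + tab.d
        recs.append({
            "factor": factor.name,
            "risk_level": factor.risk_level_label,
            "reference_level": factor.reference_level_label,
            "pdr_risk_n": tab.a, "npdr_risk_n": tab.b,
            "pdr_ref_n": tab.c, "npdr_ref_n": tab.d,
            "pdr_risk_pct": round(100 * tab.a / n_pdr),
            "npdr_risk_pct": round(100 * tab.b / n_npdr),
            "or": round(orr.or_point, 1),
            "or_ci": f"{orr.ci_low:.1f}-{orr.ci_high:.1f}",
            "or_raw": orr.or_point,
            "or_ci_low_raw": orr.ci_low, "or_ci_high_raw": orr.ci_high,
            "or_p_raw": orr.p_value,
            "chi2": round(chi.statistic, 1),
            "chi2_raw": chi.statistic, "chi2_p_raw": chi.p_value,
        })
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# 3. Economics: deterministic screening budget-impact model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CostInputs:
    """Unit costs (EUR, national health-insurance tariffs) and annual
    resource-use counts of the screening and treatment pathway.

    A screening visit combines fundus photography and OCT.  The annual cost
    of a treated PDR patient bundles monitoring visits, laser
    photocoagulation, anti-VEGF injections (procedure + drug) and
    vitrectomy; at the defaults it totals EUR 7207.45 per patient-year.
    """

    fundus_eur: Decimal = Decimal("40.16")
    oct_eur: Decimal = Decimal("36.71")
    screening_visits_per_year: int = 4
    laser_eur: Decimal = Decimal("84.32")
    laser_sessions_per_year: int = 1
    injection_procedure_eur: Decimal = Decimal("304.91")
    injections_per_year: int = 5
    drug_eur_per_injection: Decimal = Decimal("655.91")
    vitrectomy_eur: Decimal = Decimal("2011.55")
    vitrectomies_per_year: int = 1

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.type == "Decimal" or isinstance(v, (Decimal, float, str)):
                object.__setattr__(self, f.name, _dec(v))
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")


def per_visit_cost(ci: CostInputs) -> Decimal:
    """Cost of one combined screening visit (fundus + OCT), to the cent."""
    return (ci.fundus_eur + ci.oct_eur).quantize(CENT, ROUND_HALF_UP)


def annual_treated_cost(ci: CostInputs) -> Decimal:
    """Annual cost of one treated PDR patient, exact decimal arithmetic."""
    total = (
        ci.screening_visits_per_year * (ci.fundus_eur + ci.oct_eur)
        + ci.laser_sessions_per_year * ci.laser_eur
        + ci.injections_per_year * (ci.injection_procedure_eur + ci.drug_eur_per_injection)
        + ci.vitrectomies_per_year * ci.vitrectomy_eur
    )
    return total.quantize(CENT, ROUND_HALF_UP)


@dataclass(frozen=True)
class ScreeningScenario:
    """One screening-programme scenario.

    ``preventive_effect`` is the modeled fractional reduction in PDR cases
    among the screened; effectiveness is not attenuated for biennial
    screening (interval only rescales the annualised screening cost).
    """

    name: str = "scenario"
    population: int = 10_000
    uptake: Decimal = Decimal("0.60")
    interval_years: Decimal = Decimal(1)
    pdr_prevalence: Decimal = Decimal("0.47")
    preventive_effect: Decimal = Decimal("0.70")

    def __post_init__(self):
        object.__setattr__(self, "uptake", _dec(self.uptake))
        object.__setattr__(self, "interval_years", _dec(self.interval_years))
        object.__setattr__(self, "pdr_prevalence", _dec(self.pdr_prevalence))
        object.__setattr__(self, "preventive_effect", _dec(self.preventive_effect))
        if self.population < 0:
            raise ValueError(f"population must be >= 0, got {self.population}")
        for f in ("uptake", "pdr_prevalence", "preventive_effect"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ValueError(f"{f} must be in [0,1], got {v}")
        if self.interval_years < 1:
            raise ValueError(f"interval_years must be >= 1, got {self.interval_years}")


@dataclass(frozen=True)
class ScenarioResult:
    """One evaluated scenario; display counts are rounded half-up while the
    ``*_raw`` fields keep the unrounded internals.

    ``avoided_treatment_eur`` is the treatment expenditure avoided by the
    prevented cases (the headline budget-impact quantity);
    ``net_of_screening_eur`` additionally subtracts the annual screening
    programme cost.
    """

    name: str
    screened: int
    annual_screening_cost_eur: Decimal
    expected_pdr_cases: int
    expected_pdr_cases_raw: Decimal
    prevented_cases: int
    prevented_cases_raw: Decimal
    avoided_treatment_eur: Decimal
    net_of_screening_eur: Decimal


def _round_int(x: Decimal) -> int:
    return int(x.quantize(Decimal(1), ROUND_HALF_UP))


def run_scenario(s: ScreeningScenario, ci: CostInputs | None = None) -> ScenarioResult:
    """Evaluate one scenario of the deterministic budget-impact model.

    screened = population x uptake; the programme pays one combined visit
    per screened person per round, annualised by the screening interval.
    Expected PDR cases are screened x prevalence; prevented cases apply the
    preventive effect and are rounded half-up to whole patients before
    multiplying by the annual treated-patient cost.
    """
    ci = ci or CostInputs()
    screened = _round_int(Decimal(s.population) * s.uptake)
    visit = per_visit_cost(ci)
    screening_cost = (screened * visit / s.interval_years).quantize(CENT, ROUND_HALF_UP)
    expected_raw = Decimal(screened) * s.pdr_prevalence
    prevented_raw = expected_raw * s.preventive_effect
    prevented = _round_int(prevented_raw)
    treated = annual_treated_cost(ci)
    avoided = (prevented * treated).quantize(CENT, ROUND_HALF_UP)
    return ScenarioResult(
        name=s.name,
        screened=screened,
        annual_screening_cost_eur=screening_cost,
        expected_pdr_cases=_round_int(expected_raw),
        expected_pdr_cases_raw=expected_raw,
        prevented_cases=prevented,
        prevented_cases_raw=prevented_raw,
        avoided_treatment_eur=avoided,
        net_of_screening_eur=avoided - screening_cost,
    )


def default_scenarios(pdr_prevalence: Decimal | float = Decimal("0.47"),
                      population: int = 10_000) -> list[ScreeningScenario]:
    """The four headline scenarios: annual screening at 30/60/90% uptake and
    biennial screening at 60% uptake."""
    prev = _dec(pdr_prevalence)
    return [
        ScreeningScenario("Annual - Low Uptake (30%)", population, Decimal("0.30"),
                          Decimal(1), prev),
        ScreeningScenario("Annual - Medium (60%)", population, Decimal("0.60"),
                          Decimal(1), prev),
        ScreeningScenario("Annual - High (90%)", population, Decimal("0.90"),
                          Decimal(1), prev),
        ScreeningScenario("Biennial - Medium (60%)", population, Decimal("0.60"),
                          Decimal(2), prev),
    ]


def scenario_grid(scenarios: Sequence[ScreeningScenario],
                  ci: CostInputs | None = None) -> pd.DataFrame:
    """Evaluate scenarios in order; one row per scenario, monetary columns
    serialized with 2 decimals, unrounded internals in ``*_raw`` columns."""
    rows = []
    for s in scenarios:
        r = run_scenario(s, ci)
        rows.append({
            "scenario": r.name,
            "population_screened": r.screened,
            "screening_cost_eur": f"{r.annual_screening_cost_eur:.2f}",
            "expected_pdr_cases": r.expected_pdr_cases,
            "pdr_cases_prevented": r.prevented_cases,
            "avoided_treatment_eur": f"{r.avoided_treatment_eur:.2f}",
            "net_of_screening_eur": f"{r.net_of_screening_eur:.2f}",
            "expected_pdr_cases_raw": float(r.expected_pdr_cases_raw),
            "pdr_cases_prevented_raw": float(r.prevented_cases_raw),
        })
    cols = ["scenario", "population_screened", "screening_cost_eur",
            "expected_pdr_cases", "pdr_cases_prevented",
            "avoided_treatment_eur", "net_of_screening_eur",
            "expected_pdr_cases_raw", "pdr_cases_prevented_raw"]
    return pd.DataFrame(rows, columns=cols)


_BREAKEVEN_RANGES = {
    "uptake": (0.0, 1.0),
    "preventive_effect": (0.0, 1.0),
    "treated_cost": (0.0, 1e9),
}


def _net_continuous(s: ScreeningScenario, ci: CostInputs,
                    overrides: dict[str, float]) -> float:
    """Net-of-screening savings with case rounding disabled, as a float;
    the smooth surface used by break-even and sensitivity mathematics."""
    uptake = overrides.get("uptake", float(s.uptake))
    effect = overrides.get("preventive_effect", float(s.preventive_effect))
    treated = overrides.get("treated_cost", float(annual_treated_cost(ci)))
    screened = s.population * uptake
    avoided = screened * float(s.pdr_prevalence) * effect * treated
    screening = screened * float(per_visit_cost(ci)) / float(s.interval_years)
    return avoided - screening


def break_even(s: ScreeningScenario, ci: CostInputs,
               parameter: Literal["uptake", "preventive_effect", "treated_cost"],
               ) -> float:
    """Smallest value of ``parameter`` at which net-of-screening savings are
    non-negative, holding everything else fixed.

    Solved by bisection to 1e-6 relative tolerance on the continuous model
    (integer case rounding disabled).  Raises if the savings never reach
    zero on the parameter's admissible range.
    """
    if parameter not in _BREAKEVEN_RANGES:
        raise ValueError(f"unknown break-even parameter {parameter!r}")
    lo, hi = _BREAKEVEN_RANGES[parameter]
    f = lambda v: _net_continuous(s, ci, {parameter: v})
    if f(hi) < 0:
        raise ValueError(f"no break-even: net savings stay negative on "
                         f"{parameter} in [{lo}, {hi}]")
    if f(lo) >= 0:
        return lo
    return float(optimize.brentq(f, lo, hi, rtol=1e-6))


_SWEEPABLE = ("uptake", "preventive_effect", "pdr_prevalence",
              "interval_years", "population")


def one_way_sensitivity(s: ScreeningScenario, ci: CostInputs,
                        parameter: str, low: float, high: float,
                        steps: int) -> pd.DataFrame:
    """Sweep one scenario parameter over ``steps`` equally spaced values and
    tabulate the scenario outputs, sorted by parameter value."""
    if parameter not in _SWEEPABLE:
        raise ValueError(f"cannot sweep {parameter!r}; one of {_SWEEPABLE}")
    if not low < high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    if steps < 2:
        raise ValueError(f"need at least 2 steps, got {steps}")
    rows = []
    for v in np.linspace(low, high, steps):
        value = int(round(v)) if parameter == "population" else _dec(round(float(v), 12))
        r = run_scenario(replace(s, **{parameter: value}), ci)
        rows.append({
            "parameter": parameter,
            "value": float(v),
            "screened": r.screened,
            "pdr_cases_prevented": r.prevented_cases,
            "avoided_treatment_eur": float(r.avoided_treatment_eur),
            "net_of_screening_eur": float(r.net_of_screening_eur),
        })
    return pd.DataFrame(rows).sort_values("value", ignore_index=True)


def render_table(df: pd.DataFrame, title: str | None = None) -> str:
    """Aligned plain-text rendering of a result table."""
    body = df.to_string(index=False)
    return f"{title}\n{'=' * len(title)}\n{body}\n" if title else body + "\n"


# ---------------------------------------------------------------------------
# 4. Pipeline configuration (used by the CLI)
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "cohort": {"source": "fixture", "path": None, "seed": 0, "scale": 1.0},
    "statistics": {"alpha": 0.05, "ci_level": 0.95,
                   "duration_threshold": None, "tie_policy": None},
    "economics": {
        "population": 10_000,
        "pdr_prevalence": 0.47,
        "preventive_effect": 0.70,
        "costs": {},          # overrides of CostInputs fields
        "scenarios": None,    # None -> the four default scenarios
    },
    "output": {"dir": "out"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML pipeline config merged over :data:`DEFAULT_CONFIG`."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    """Short stable hash of a config for log provenance lines."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def cost_inputs_from_config(config: dict) -> CostInputs:
    return CostInputs(**{k: _dec(v) for k, v in
                         (config["economics"].get("costs") or {}).items()})


def scenarios_from_config(config: dict,
                          prevalence: Decimal | float | None = None,
                          ) -> list[ScreeningScenario]:
    econ = config["economics"]
    prev = _dec(prevalence if prevalence is not None else econ["pdr_prevalence"])
    raw = econ.get("scenarios")
    if raw is None:
        return [replace(s, preventive_effect=_dec(econ["preventive_effect"]))
                for s in default_scenarios(prev, econ["population"])]
    out = []
    for i, sc in enumerate(raw):
        out.append(ScreeningScenario(
            name=sc.get("name", f"scenario-{i}"),
            population=sc.get("population", econ["population"]),
            uptake=_dec(sc["uptake"]),
            interval_years=_dec(sc.get("interval_years", 1)),
            pdr_prevalence=prev,
            preventive_effect=_dec(sc.get("preventive_effect", econ["preventive_effect"])),
        ))
    return out
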
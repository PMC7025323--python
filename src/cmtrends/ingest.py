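"""Survey ingest: case definitions, coverage classes, summaries and table I/O.

Definitions applied to person-level records
-------------------------------------------
* obesity: BMI >= 30 kg/m2
* raised blood pressure: SBP >= 140 mm Hg or DBP >= 90 mm Hg (both required
  to evaluate; records reporting only one pressure are not evaluable)
* diabetes: FPG >= 7.0 mmol/L, or a history of diabetes, or treatment

All threshold comparisons are inclusive, applied to values exactly as
reported.  A definition returns ``None`` when the record lacks the fields
needed to evaluate it.

Coverage classes
----------------
A study is *national* when flagged as nationally representative,
*subnational* when it covers at least one subnational region or more than
three communities, and *community* when it covers at most three communities.

Sampling variance
-----------------
On the logit scale a study prevalence p with effective sample size n has
delta-method variance 1/(n p (1-p)); p is clamped to [0.5/n, 1 - 0.5/n]
(continuity correction) so degenerate proportions stay finite.  Mean
outcomes use (person-level SD)^2 / n with the per-outcome SDs in
:mod:`cmtrends.outcomes`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import AgeBand, validate_bands
from .hierarchy import RegionHierarchy
from .outcomes import (MEAN_BMI, MEAN_OUTCOME_SD, MEAN_SBP, MIN_AGE,
                       PREV_DIABETES, PREV_OBESITY, PREV_RAISED_BP,
                       is_prevalence, validate_outcome)

NATIONAL = "national"
SUBNATIONAL = "subnational"
COMMUNITY = "community"
COVERAGE_CLASSES = (NATIONAL, SUBNATIONAL, COMMUNITY)

SEXES = ("men", "women")

#: survey table schema, in column order
SURVEY_COLUMNS = ("study_id", "country", "year", "sex", "age_lo", "age_hi",
                  "outcome", "value", "n", "coverage", "urban_fraction",
                  "urban_only", "rural_only")


@dataclass(frozen=True)
class PersonRecord:
    """One person's measurements; any subset of fields may be present."""

    age: float | None = None
    bmi: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    fpg: float | None = None
    diabetes_history: bool | None = None
    diabetes_treatment: bool | None = None

    def __post_init__(self) -> None:
        if all(v is None for v in (self.bmi, self.sbp, self.dbp, self.fpg,
                                   self.diabetes_history, self.diabetes_treatment)):
            raise ValueError("record carries no outcome field")
        for name in ("bmi", "sbp", "dbp", "fpg"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


def classify_coverage(is_national: bool, n_subnational_regions: int,
                      n_communities: int) -> str:
    """Assign the coverage class from the sampling frame description."""
    if n_subnational_regions < 0 or n_communities < 0:
        raise ValueError("region/community counts must be nonnegative")
    if is_national:
        return NATIONAL
    if n_subnational_regions == 0 and n_communities == 0:
        raise ValueError("non-national study must cover at least one "
                         "subnational region or community")
    if n_subnational_regions >= 1 or n_communities > 3:
        return SUBNATIONAL
    return COMMUNITY


def obesity_case(record: PersonRecord) -> bool | None:
    """BMI >= 30; ``None`` when BMI is absent."""
    if record.bmi is None:
        return None
    return record.bmi >= 30.0


def raised_bp_case(record: PersonRecord) -> bool | None:
    """SBP >= 140 or DBP >= 90; ``None`` unless both pressures are present."""
    if record.sbp is None or record.dbp is None:
        return None
    return record.sbp >= 140.0 or record.dbp >= 90.0


def diabetes_case(record: PersonRecord) -> bool | None:
    """FPG >= 7.0, history, or treatment; ``None`` when all three are absent."""
    if record.fpg is None and record.diabetes_history is None \
            and record.diabetes_treatment is None:
        return None
    if record.fpg is not None and record.fpg >= 7.0:
        return True
    return bool(record.diabetes_history) or bool(record.diabetes_treatment)


_CASE_FN = {PREV_OBESITY: obesity_case, PREV_RAISED_BP: raised_bp_case,
            PREV_DIABETES: diabetes_case}


def _record_value(record: PersonRecord, outcome_kind: str) -> float | None:
    """Per-person contribution: the measurement for means, 0/1 for cases."""
    if outcome_kind == MEAN_BMI:
        return record.bmi
    if outcome_kind == MEAN_SBP:
        return record.sbp
    flag = _CASE_FN[outcome_kind](record)
    return None if flag is None else float(flag)


def summarise_study(records: Sequence[PersonRecord], outcome_kind: str,
                    bands: Sequence[AgeBand]) -> list[dict]:
    """Summarise person records into per-band (value, n) entries.

    Prevalence = evaluable case count / evaluable count; mean outcomes use
    the arithmetic mean.  Bands with no evaluable record are omitted.
    Records must carry an age to be binned.
    """
    validate_outcome(outcome_kind)
    bands = validate_bands(bands)
    out = []
    for band in bands:
        hi = np.inf if band.hi is None else band.hi
        vals = []
        for rec in records:
            if rec.age is None or not (band.lo <= rec.age < hi):
                continue
            v = _record_value(rec, outcome_kind)
            if v is not None:
                vals.append(v)
        if vals:
            out.append({"age_band": band, "value": float(np.mean(vals)),
                        "n": len(vals)})
    return out


def clamp_proportion(p: float | np.ndarray, n: float | np.ndarray):
    """Clamp a proportion to [0.5/n, 1 - 0.5/n] (continuity correction)."""
    n = np.asarray(n, dtype=float)
    return np.clip(np.asarray(p, dtype=float), 0.5 / n, 1.0 - 0.5 / n)


def observation_variance(value: float | np.ndarray, n: float | np.ndarray,
                         outcome_kind: str):
    """Sampling variance of a study summary on the modelling scale."""
    validate_outcome(outcome_kind)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("sample size must be positive")
    if is_prevalence(outcome_kind):
        p = clamp_proportion(value, n)
        return 1.0 / (n * p * (1.0 - p))
    sd = MEAN_OUTCOME_SD[outcome_kind]
    return np.full_like(n, sd * sd) / n


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_NATURAL_RANGE = {MEAN_BMI: (10.0, 80.0), MEAN_SBP: (70.0, 250.0)}


def write_survey_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SURVEY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"survey table missing columns {missing}")
    table.loc[:, list(SURVEY_COLUMNS)].to_csv(path, index=False)


def _row_errors(df: pd.DataFrame, years: tuple[int, int],
                known_countries: set[str] | None) -> pd.Series:
    msgs = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, msg: str) -> None:
        nonlocal msgs
        msgs[mask] = msgs[mask].where(msgs[mask] == "", msgs[mask] + "; ") + msg

    flag(~df["outcome"].isin(list(_NATURAL_RANGE) + list(_CASE_FN)),
         "unknown outcome")
    flag(~df["sex"].isin(SEXES), "unknown sex")
    flag(~df["coverage"].isin(COVERAGE_CLASSES), "unknown coverage class")
    flag((df["year"] < years[0]) | (df["year"] > years[1]),
         f"year outside {years[0]}-{years[1]}")
    flag(df["n"] < 1, "sample size < 1")
    prev = df["outcome"].isin(list(_CASE_FN))
    flag(prev & ((df["value"] < 0) | (df["value"] > 1)),
         "prevalence outside [0, 1]")
    for kind, (lo, hi) in _NATURAL_RANGE.items():
        m = df["outcome"] == kind
        flag(m & ((df["value"] <= lo) | (df["value"] >= hi)),
             f"{kind} outside ({lo}, {hi})")
    bmi_kinds = (MEAN_BMI, PREV_OBESITY)
    flag(df["outcome"].isin(bmi_kinds) & (df["age_lo"] < MIN_AGE[MEAN_BMI]),
         "BMI outcome reported below age 20")
    uf = df["urban_fraction"]
    flag(uf.notna() & ((uf < 0) | (uf > 1)), "urban fraction outside [0, 1]")
    if known_countries is not None:
        flag(~df["country"].isin(known_countries), "unknown country id")
    return msgs


def read_survey_table(path: str | Path, *, years: tuple[int, int] = (1980, 2014),
                      hierarchy: RegionHierarchy | None = None,
                      strict: bool = True) -> pd.DataFrame:
    """Read and validate a survey summary table.

    In strict mode any invalid row aborts with an error naming row numbers;
    in lenient mode invalid rows are dropped with a warning per problem.
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey table {path} missing columns {missing}")
    df = df[list(SURVEY_COLUMNS)]
    for col in ("urban_only", "rural_only"):
        df[col] = df[col].astype(bool)
    known = set(hierarchy.countries) if hierarchy is not None else None
    msgs = _row_errors(df, years, known)
    bad = msgs != ""
    if bad.any():
        detail = "; ".join(f"row {i}: {m}" for i, m in msgs[bad].head(20).items())
        if strict:
            raise ValueError(f"{int(bad.sum())} invalid survey rows: {detail}")
        warnings.warn(f"dropping {int(bad.sum())} invalid survey rows: {detail}")
        df = df[~bad].reset_index(drop=True)
    return df


def read_hierarchy(hierarchy_path: str | Path, population_path: str | Path,
                   urban_path: str | Path,
                   age_bands: Sequence[AgeBand] | None = None) -> RegionHierarchy:
    """Assemble a :class:`RegionHierarchy` from its three delimited tables."""
    memb = pd.read_csv(hierarchy_path)
    for col in ("country", "region"):
        if col not in memb.columns:
            raise ValueError(f"hierarchy table missing column {col!r}")
    pop = pd.read_csv(population_path)
    need = {"country", "year", "age_lo", "age_hi", "population"}
    if not need.issubset(pop.columns):
        raise ValueError(f"population table missing {sorted(need - set(pop.columns))}")
    urb = pd.read_csv(urban_path)
    if not {"country", "year", "urban_fraction"}.issubset(urb.columns):
        raise ValueError("urban fraction table needs country, year, urban_fraction")
    years = np.arange(int(pop["year"].min()), int(pop["year"].max()) + 1)
    if age_bands is None:
        pairs = (pop[["age_lo", "age_hi"]].drop_duplicates()
                 .sort_values("age_lo").itertuples(index=False))
        age_bands = tuple(AgeBand(int(lo), None if pd.isna(hi) else int(hi))
                          for lo, hi in pairs)
    return RegionHierarchy(tuple(memb["country"]),
                           dict(zip(memb["country"], memb["region"])),
                           years, tuple(age_bands), pop, urb)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Long covariate table (country, year, covariate, value)."""
    df = pd.read_csv(path)
    need = {"country", "year", "covariate", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"covariate table missing {sorted(need - set(df.columns))}")
    return df
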
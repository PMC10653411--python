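"""Loading, validation and harmonization of respondent-level survey tables.

Survey microdata arrives as coded columns (integers standing for labelled
categories, with designated codes for "refused"/"don't know") spread over
2-year cycles.  This module decodes columns through declarative codebooks,
concatenates cycles with the standard weight adjustment (each weight divided
by the number of combined cycles, so weighted totals estimate the average
population over the period), derives the analysis covariates (insurance
class, income-to-poverty category, harmonized education), and applies the
cohort inclusion filters, keeping a provenance log of row counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Codebook",
    "SurveyDesign",
    "AnalysisTable",
    "CodebookError",
    "load_codebooks",
    "read_table",
    "combine_cycles",
    "derive_insurance",
    "derive_insurance_column",
    "categorize_pir",
    "harmonize_education",
    "filter_cohort",
    "drop_missing",
    "EDUCATION_LEVELS",
    "PIR_CATEGORIES",
    "INSURANCE_CLASSES",
]

EDUCATION_LEVELS = (
    "less than 9th grade",
    "9-11th grade",
    "high school graduate",
    "some college or AA degree",
    "college graduate or above",
)

PIR_CATEGORIES = ("poor", "near poor", "middle income", "higher income")

INSURANCE_CLASSES = ("private", "Medicare", "Medicaid", "other non-private", "uninsured")

#: Priority order used to resolve respondents reporting several plans.
DEFAULT_INSURANCE_PRIORITY = ("private", "medicare", "medicaid", "other")


class CodebookError(ValueError):
    """A value outside a variable's declared code domain."""


@dataclass(frozen=True)
class Codebook:
    """Declarative codebook for one coded variable.

    Attributes
    ----------
    variable : str
        Column name the codebook governs.
    codes : mapping of code -> label
        Valid value codes (ints or text) and their decoded labels.
    missing : frozenset
        Codes (e.g. refused / don't know) decoded to an absent value.
    groups : mapping of label -> coarser label, optional
        Hierarchical grouping onto analysis levels (e.g. fine education
        codes onto the five analysis levels).
    """

    variable: str
    codes: Mapping
    missing: frozenset = frozenset()
    groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        overlap = set(self.codes) & set(self.missing)
        if overlap:
            raise ValueError(
                f"codebook {self.variable!r}: codes {sorted(overlap, key=repr)} "
                "declared both valid and missing"
            )

    def decode(self, code):
        """Code -> label; missing codes -> None; unknown codes raise."""
        code = _canonical_code(code)
        if code in self.missing:
            return None
        if code in self.codes:
            return self.codes[code]
        raise CodebookError(
            f"variable {self.variable!r}: code {code!r} outside the declared domain"
        )

    def group(self, label: str) -> str:
        if self.groups is None:
            return label
        if label not in self.groups:
            raise CodebookError(
                f"variable {self.variable!r}: label {label!r} has no group mapping"
            )
        return self.groups[label]


def _canonical_code(code):
    """Collapse 3.0 -> 3 so numeric codes agree across CSV/XPT round trips."""
    if isinstance(code, float) and code.is_integer():
        return int(code)
    if isinstance(code, (np.integer,)):
        return int(code)
    if isinstance(code, np.floating) and float(code).is_integer():
        return int(code)
    return code


def load_codebooks(path) -> dict[str, Codebook]:
    """Load a YAML file of codebooks keyed by variable name.

    Each entry carries ``codes`` (code -> label), optional ``missing`` (list
    of codes) and optional ``groups`` (label -> coarser label).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    books = {}
    for var, entry in raw.items():
        books[var] = Codebook(
            variable=var,
            codes={_canonical_code(k): v for k, v in entry["codes"].items()},
            missing=frozenset(_canonical_code(c) for c in entry.get("missing", ())),
            groups=entry.get("groups"),
        )
    return books


@dataclass(frozen=True)
class SurveyDesign:
    """Column bindings for design-based estimation."""

    weight: str = "weight"
    stratum: str = "stratum"
    psu: str = "psu"
    cycles_combined: int = 1

    def __post_init__(self) -> None:
        if self.cycles_combined < 1:
            raise ValueError("cycles_combined must be >= 1")

    def validate(self, df: pd.DataFrame) -> None:
        for col in (self.weight, self.stratum, self.psu):
            if col not in df.columns:
                raise KeyError(f"design column {col!r} missing from table")
        if (df[self.weight] <= 0).any():
            raise ValueError("all sample weights must be strictly positive")


@dataclass
class AnalysisTable:
    """Harmonized respondent table + design + provenance log."""

    df: pd.DataFrame
    design: SurveyDesign
    provenance: list[dict] = field(default_factory=list)

    def record(self, operation: str, rows_before: int, rows_after: int, **detail) -> None:
        if rows_after > rows_before:
            raise ValueError("filters cannot increase row counts")
        self.provenance.append(
            {
                "operation": operation,
                "rows_before": int(rows_before),
                "rows_after": int(rows_after),
                **detail,
            }
        )

    def with_df(self, df: pd.DataFrame, operation: str, **detail) -> "AnalysisTable":
        out = AnalysisTable(df=df, design=self.design, provenance=list(self.provenance))
        out.record(operation, len(self.df), len(df), **detail)
        return out

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, indent=2)


def read_table(path, format: str = "csv", codebooks: Mapping[str, Codebook] | None = None) -> pd.DataFrame:
    """Read a respondent table from CSV or SAS transport (XPT) and decode it.

    Coded columns named in ``codebooks`` are validated (a code outside the
    declared domain raises :class:`CodebookError` naming variable, row and
    code) and decoded to labels; declared missing codes become NaN.
    """
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "xpt":
        df = pd.read_sas(path, format="xport")
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].map(
                    lambda v: v.decode() if isinstance(v, bytes) else v
                )
            elif df[col].dtype.kind == "f":
                # the transport format's all-zero word decodes to ~2^-260;
                # snap it back to an exact zero
                df[col] = df[col].mask(df[col].abs() < 1e-70, 0.0)
        df.columns = [c.lower() for c in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'xpt'")

    for var, book in (codebooks or {}).items():
        if var not in df.columns:
            continue
        decoded = []
        for row_idx, code in enumerate(df[var]):
            if pd.isna(code):
                decoded.append(None)
                continue
            try:
                decoded.append(book.decode(code))
            except CodebookError:
                raise CodebookError(
                    f"variable {var!r}, row {row_idx}: code {code!r} outside "
                    "the declared domain"
                ) from None
        df[var] = pd.Series(decoded, index=df.index, dtype=object)
    return df


def combine_cycles(
    tables: Sequence[pd.DataFrame],
    design: SurveyDesign,
    *,
    id_col: str = "id",
    cycle_col: str = "cycle",
) -> tuple[pd.DataFrame, SurveyDesign]:
    """Concatenate per-cycle tables, dividing weights by the cycle count.

    Dividing each 2-year cycle weight by the number of combined cycles makes
    the combined weighted total estimate the (average) population over the
    whole period rather than k times it.
    """
    if not tables:
        raise ValueError("no tables to combine")
    schemas = {tuple(t.columns) for t in tables}
    if len(schemas) != 1:
        raise ValueError("all cycle tables must share an identical schema")
    cycles = [set(t[cycle_col].unique()) for t in tables if cycle_col in t.columns]
    if cycles:
        flat = [c for s in cycles for c in s]
        if len(flat) != len(set(flat)):
            raise ValueError("cycle labels must be distinct across tables")
    combined = pd.concat(tables, ignore_index=True)
    if id_col in combined.columns and combined[id_col].duplicated().any():
        dupes = combined.loc[combined[id_col].duplicated(), id_col].unique()[:5]
        raise ValueError(f"duplicate respondent ids across cycles, e.g. {list(dupes)!r}")
    k = len(tables)
    combined = combined.copy()
    combined[design.weight] = combined[design.weight] / k
    return combined, replace(design, cycles_combined=k)


def derive_insurance(
    flags: Mapping[str, bool | None],
    priority: Sequence[str] = DEFAULT_INSURANCE_PRIORITY,
) -> str | None:
    """Resolve per-plan coverage flags to one mutually exclusive class.

    Multiple reported plans resolve by priority (default private > Medicare >
    Medicaid > other non-private).  "uninsured" requires every flag to be
    explicitly False; if no flag is True and any is absent the class is
    unknown (None).
    """
    label_of = {
        "private": "private",
        "medicare": "Medicare",
        "medicaid": "Medicaid",
        "other": "other non-private",
    }
    for plan in priority:
        if flags.get(plan) is True:
            return label_of.get(plan, plan)
    values = [flags.get(p) for p in priority]
    if all(v is False for v in values):
        return "uninsured"
    return None


def derive_insurance_column(
    df: pd.DataFrame,
    flag_cols: Mapping[str, str] | None = None,
    priority: Sequence[str] = DEFAULT_INSURANCE_PRIORITY,
) -> pd.Series:
    """Vectorized insurance derivation; absent class becomes NaN."""
    cols = flag_cols or {p: f"ins_{p}" for p in DEFAULT_INSURANCE_PRIORITY}

    def _row(row) -> str | None:
        flags = {}
        for plan, col in cols.items():
            v = row[col]
            flags[plan] = None if pd.isna(v) else bool(v)
        return derive_insurance(flags, priority)

    return df.apply(_row, axis=1).astype(object)


def categorize_pir(pir: float) -> str:
    """Income-to-poverty ratio category on half-open bands.

    poor [0, 1), near poor [1, 2), middle income [2, 4), higher income [4, inf).
    """
    if pir < 0:
        raise ValueError(f"poverty income ratio cannot be negative; got {pir!r}")
    if pir < 1.0:
        return "poor"
    if pir < 2.0:
        return "near poor"
    if pir < 4.0:
        return "middle income"
    return "higher income"


def harmonize_education(code, codebook: Codebook) -> str:
    """Decode an education code and map it onto the five analysis levels."""
    label = codebook.decode(code)
    if label is None:
        return None
    return codebook.group(label)


def _truthy(series: pd.Series) -> pd.Series:
    """Interpret a flag column that may hold booleans, 0/1 codes, or
    yes/no labels; missing values count as False."""
    return series.map(lambda v: v is True or v == 1 or v == "yes")


def filter_cohort(
    table: AnalysisTable,
    cohort: str,
    *,
    age_col: str = "age",
    pregnancy_col: str = "pregnant",
    t2dm_col: str = "diagnosed_t2dm",
    adult_age_inclusive: bool = True,
) -> AnalysisTable:
    """Apply a study cohort's inclusion criteria.

    ``hav_hbv``: adults (age >= 20 completed years by default) who are not
    pregnant.  ``hpv``: ages 20-59, not pregnant.  ``t2dm``: diagnosed type-2
    diabetics, adult, not pregnant.  Pregnancy excludes only an explicit
    positive flag (the pregnancy test is administered only to a subset).
    """
    df = table.df
    age = df[age_col]
    adult = age >= 20 if adult_age_inclusive else age > 20
    not_pregnant = ~_truthy(df[pregnancy_col]) if pregnancy_col in df else True
    if cohort == "hav_hbv":
        keep = adult & not_pregnant
    elif cohort == "hpv":
        keep = (age >= 20) & (age <= 59) & not_pregnant
    elif cohort == "t2dm":
        if t2dm_col not in df.columns:
            raise KeyError(f"t2dm cohort requires column {t2dm_col!r}")
        keep = _truthy(df[t2dm_col]) & adult & not_pregnant
    else:
        raise ValueError(f"unknown cohort {cohort!r}; use hav_hbv, hpv or t2dm")
    return table.with_df(df.loc[keep].copy(), f"filter_cohort:{cohort}")


def drop_missing(table: AnalysisTable, required: Iterable[str]) -> AnalysisTable:
    """Complete-case filter on the listed columns."""
    required = list(required)
    for col in required:
        if col not in table.df.columns:
            raise KeyError(f"required column {col!r} not present")
    kept = table.df.dropna(subset=required)
    return table.with_df(
        kept.copy(), "drop_missing", columns=required, dropped=len(table.df) - len(kept)
    )
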
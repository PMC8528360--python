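"""Patient-level cohort table: schema, CSV I/O, random splitting, baseline summary.

A cohort is one row per hospitalized heart-failure patient, with demographic
and clinical covariates and a binary one-year post-discharge mortality
outcome.  The schema is a list of :class:`VariableSpec` entries declaring each
variable's kind (continuous or binary flag) and role (candidate risk factor,
outcome, id, or auxiliary column such as a missingness indicator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableSpec",
    "CohortTable",
    "CohortError",
    "default_schema",
    "read_cohort",
    "write_cohort",
    "split_cohort",
    "baseline_summary",
]

#: CSV cells accepted as missing on input; empty string is written on output.
NA_SENTINELS = ("", "NA")


class CohortError(ValueError):
    """Schema or value violation in a cohort table, with row/column context."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one cohort variable.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    kind : {"continuous", "binary"}
        Binary variables take values in {0, 1} or missing.
    role : {"candidate", "outcome", "id", "auxiliary"}
        Exactly one variable per schema carries the ``outcome`` role.
    units : str
        Free-text units (years, mm, kg/m2, flag).
    """

    name: str
    kind: str = "continuous"
    role: str = "candidate"
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise CohortError(f"{self.name}: unknown kind {self.kind!r}")
        if self.role not in ("candidate", "outcome", "id", "auxiliary"):
            raise CohortError(f"{self.name}: unknown role {self.role!r}")


def default_schema() -> list[VariableSpec]:
    """Schema of the hospitalized heart-failure cohort.

    Demographics, echocardiographic and clinical findings, history and
    lifestyle flags, and the one-year all-cause mortality outcome.
    """
    c, b = "continuous", "binary"
    return [
        VariableSpec("age", c, "candidate", "years"),
        VariableSpec("female", b, "candidate", "flag"),
        VariableSpec("bmi", c, "candidate", "kg/m2"),
        VariableSpec("la_diam", c, "candidate", "mm"),
        VariableSpec("heart_rate", c, "candidate", "bpm"),
        VariableSpec("lvef_lt40", b, "candidate", "flag"),
        VariableSpec("nyha_gt3", b, "candidate", "flag"),
        VariableSpec("hf_history", b, "candidate", "flag"),
        VariableSpec("ami_history", b, "candidate", "flag"),
        VariableSpec("chd", b, "candidate", "flag"),
        VariableSpec("diabetes", b, "candidate", "flag"),
        VariableSpec("hypertension", b, "candidate", "flag"),
        VariableSpec("valve_surgery", b, "candidate", "flag"),
        VariableSpec("smoking", b, "candidate", "flag"),
        VariableSpec("alcohol", b, "candidate", "flag"),
        VariableSpec("death_1y", b, "outcome", "flag"),
    ]


@dataclass
class CohortTable:
    """A validated patient-level table plus its schema.

    ``df`` holds one row per patient with ``NaN`` as the missing marker.
    The outcome column must be fully observed.
    """

    df: pd.DataFrame
    schema: list[VariableSpec] = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        self.validate()

    # -- schema helpers -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def outcome(self) -> str:
        out = [v.name for v in self.schema if v.role == "outcome"]
        if len(out) != 1:
            raise CohortError(f"schema must have exactly one outcome, found {out}")
        return out[0]

    @property
    def candidates(self) -> list[str]:
        return [v.name for v in self.schema if v.role == "candidate"]

    def spec(self, name: str) -> VariableSpec:
        for v in self.schema:
            if v.name == name:
                return v
        raise CohortError(f"unknown variable {name!r}")

    def validate(self) -> None:
        names = [v.name for v in self.schema]
        if len(set(names)) != len(names):
            raise CohortError("duplicate variable names in schema")
        if self.n < 1:
            raise CohortError("cohort must contain at least one row")
        _ = self.outcome  # exactly-one check
        missing_cols = set(names) - set(self.df.columns)
        if missing_cols:
            raise CohortError(f"columns absent from table: {sorted(missing_cols)}")
        extra = set(self.df.columns) - set(names)
        if extra:
            raise CohortError(f"columns not in schema: {sorted(extra)}")
        for v in self.schema:
            col = self.df[v.name]
            if not pd.api.types.is_numeric_dtype(col):
                bad = col[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
                row = bad.index[0] if len(bad) else "?"
                raise CohortError(f"non-numeric value in column {v.name!r} (row {row})")
            if v.kind == "binary":
                obs = col.dropna()
                bad = obs[~obs.isin((0, 1))]
                if len(bad):
                    raise CohortError(
                        f"binary variable {v.name!r} takes value {bad.iloc[0]!r} "
                        f"outside {{0,1}} (row {bad.index[0]})"
                    )
        if self.df[self.outcome].isna().any():
            row = int(self.df[self.outcome].isna().idxmax())
            raise CohortError(f"missing outcome value (row {row})")

    # -- conveniences ----------------------------------------------------
    def with_columns(self, extra: pd.DataFrame, specs: Iterable[VariableSpec]) -> "CohortTable":
        """Return a new table with additional columns appended."""
        df = pd.concat([self.df, extra], axis=1)
        return CohortTable(df, list(self.schema) + list(specs))

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), list(self.schema))


def read_cohort(path, schema: Sequence[VariableSpec] | None = None) -> CohortTable:
    """Read a cohort CSV and validate it against *schema*.

    Blank cells and the literal ``NA`` become missing markers.  The header
    must consist exactly of the schema variable names (any order).
    """
    schema = list(schema) if schema is not None else default_schema()
    df = pd.read_csv(path, na_values=list(NA_SENTINELS), keep_default_na=False)
    names = [v.name for v in schema]
    unknown = set(df.columns) - set(names)
    if unknown:
        raise CohortError(f"unknown column(s) in {path}: {sorted(unknown)}")
    absent = set(names) - set(df.columns)
    if absent:
        raise CohortError(f"column(s) missing from {path}: {sorted(absent)}")
    for name in names:
        df[name] = pd.to_numeric(df[name], errors="raise")
    return CohortTable(df[names], schema)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort to CSV, UTF-8, empty cell as the missing marker."""
    table.df.to_csv(path, index=False, na_rep="")


def split_cohort(table: CohortTable, seed: int) -> tuple[CohortTable, CohortTable]:
    """Randomly partition a cohort into derivation and test halves.

    A seeded uniform permutation assigns ceil(n/2) rows to the derivation
    sample and the remainder to the test sample, emulating a random-number
    table allocation with near-equal group sizes.
    """
    if table.n < 2:
        raise CohortError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n)
    k = math.ceil(table.n / 2)
    deriv = table.df.iloc[np.sort(perm[:k])].reset_index(drop=True)
    test = table.df.iloc[np.sort(perm[k:])].reset_index(drop=True)
    return CohortTable(deriv, table.schema), CohortTable(test, table.schema)


def baseline_summary(derivation: CohortTable, test: CohortTable) -> pd.DataFrame:
    """Between-group baseline comparison of the derivation and test samples.

    Continuous variables are summarized as mean (SD) per group and compared
    with an unpaired t-test; binary variables as percent per group compared
    with a Pearson chi-square on the 2x2 table without continuity
    correction.  A variable constant in both groups gets an undefined
    (NaN) p-value.

    Returns a DataFrame with one row per non-outcome variable plus the
    outcome itself, columns: variable, kind, deriv_stat, deriv_sd,
    test_stat, test_sd, p_value, test_name.  For binary variables the
    *stat* columns carry percents in [0, 100] and the SD columns are NaN.
    """
    if [v.name for v in derivation.schema] != [v.name for v in test.schema]:
        raise CohortError("derivation and test samples must share a schema")
    rows = []
    for v in derivation.schema:
        if v.role in ("id", "auxiliary"):
            continue
        a = derivation.df[v.name].dropna().to_numpy(float)
        b = test.df[v.name].dropna().to_numpy(float)
        if v.kind == "continuous":
            const = np.ptp(a) == 0 and np.ptp(b) == 0
            if const:
                p = np.nan
                name = "undefined"
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
                name = "t-test"
            rows.append(
                dict(variable=v.name, kind=v.kind,
                     deriv_stat=a.mean(), deriv_sd=a.std(ddof=1),
                     test_stat=b.mean(), test_sd=b.std(ddof=1),
                     p_value=p, test_name=name)
            )
        else:
            tab = np.array([
                [(a == 1).sum(), (a == 0).sum()],
                [(b == 1).sum(), (b == 0).sum()],
            ])
            if (tab.sum(axis=0) == 0).any():  # constant in both groups
                p, name = np.nan, "undefined"
            else:
                p = float(stats.chi2_contingency(tab, correction=False).pvalue)
                name = "chi-square"
            rows.append(
                dict(variable=v.name, kind=v.kind,
                     deriv_stat=100 * a.mean(), deriv_sd=np.nan,
                     test_stat=100 * b.mean(), test_sd=np.nan,
                     p_value=p, test_name=name)
            )
    return pd.DataFrame(rows)
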